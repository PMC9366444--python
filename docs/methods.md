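# Methods

## Model

A phylogenetic tree is an acyclic graph whose degree-1 nodes (leaves) carry
unique labels; internal nodes have degree ≥ 3 after suppression of degree-2
nodes, except that a rooted tree may have a degree-2 root.  Every internal
edge of an unrooted tree induces a split A|B of the leaf set; a split is
informative when both blocks hold at least two leaves.  The majority-rule
consensus of a tree set contains exactly the splits occurring in *strictly
more* than a threshold fraction (default 0.5) of the trees; strictness
guarantees pairwise compatibility of the retained splits, so they assemble
into a unique (possibly multifurcating) tree.  A split present in exactly
half of the trees is therefore excluded.

Counting is the backbone of the scores.  On n leaves there are
U(n) = (2n−5)!! unrooted and R(n) = (2n−3)!! rooted binary topologies.  A
split A|B is displayed by U_{A|B} = R(|A|)·R(|B|) unrooted topologies — the
two blocks resolve independently as rooted subtrees joined by the split
edge.  This product form is verified against exhaustive enumeration of all
topologies for every n ≤ 7 (and per-split containment counts for every
block-size combination that arises there); the n = 4 case is the quickest
sanity check: exactly 1 of the 3 quartet trees displays 12|34, and
R(2)·R(2) = 1.  A clade of a leaves occurs in R(a)·R(n−a+1) of the R(n)
rooted topologies, verified the same way via rooted enumeration.

Treating a split's support p (frequency in the tree set) as the probability
that the split is true — literal for a Bayesian posterior sample, generous
for bootstrap proportions, doubtful for most-parsimonious sets — and
spreading p uniformly over the U_{A|B} displaying topologies, the
phylogenetic information content of the supported split is the entropy
reduction

PIC(A|B, p) = log₂U(n) + p(log₂p − log₂U_{A|B}) + q(log₂q − log₂U_{A∤B}),

with q = 1 − p, U_{A∤B} = U(n) − U_{A|B}, and q·log₂q → 0 at p = 1.  PIC is
non-negative, zero exactly at the prior p = U_{A|B}/U(n), and monotone in p
above it.  The derivation is cross-checked numerically against the direct
entropy difference computed over enumerated 5-leaf tree sets.

SPIC, the splitwise phylogenetic information content of a consensus, is the
sum of PIC over its supported splits (clades under the rooted convention).
Splits are not independent, so SPIC double-counts hierarchically shared
information; it remains a polynomial-time proxy that the heuristics
optimize, and the known alternatives (hierarchy-aware corrections) are out
of scope here.  RBIC — the plain sum of supports — is implemented only as a
comparator.

### Rooted versus unrooted scoring

All computations default to unrooted split conventions.  A `rooted` flag
switches consensus construction and scoring to clades.  The worked examples
involving a fixed rooted 6-leaf base (the two-position rogue and the rogue
cherry) reproduce their documented preferences only under clade scoring —
under split scoring the plenary consensus of the 67/33 two-position
configuration already outscores the reduced one (9.656 vs 9.159 bits) —
so those examples and the threshold experiment run rooted; the wandering
single-rogue example is scored unrooted.

## Instability

The instability of a leaf pair is ln(MAD/mean), where MAD is the median
absolute deviation (from the median) of the pair's graph geodesic — edge
count on the leaf-to-leaf path, with any degree-2 root suppressed — across
the trees, and mean is the arithmetic mean of those geodesics.  Three
interpretive choices, fixed here once: "divergence" is deviation from the
pair's median; the mean normalizes *inside* the logarithm, keeping the
statistic scale-free; and a MAD of zero (perfectly stable pair) is floored
at ε = 1/(2·n_trees) — half the smallest observable nonzero deviation — so
the logarithm stays finite without disturbing the ranking.  Only the
ranking feeds H1, and any monotone-equivalent reading produces the same
order in the planted-rogue tests.  A leaf's instability is the mean over
its n−1 pairs.

## Search heuristics

H1 computes the instability ranking once on the input trees (recomputation
after each deletion is available behind `recompute_instability`, at extra
cost), deletes the least stable remaining leaf, scores the majority
consensus of the survivors, and repeats until an admissible bound says no
smaller leaf set can beat the best SPIC seen, or only 4 leaves remain.  The
bound used is (k−3)·max_a PIC(a, k−a, 1) for k leaves ((k−1)·max clade PIC
when rooted): a consensus on k leaves has at most k−3 informative splits,
each worth at most the best fully supported block size.  Any admissible
bound only changes how soon the scan stops, never the scores of visited
states.  The best-scoring leaf set is adopted; deleted leaves outside it
are then reconsidered from most- to least-recently deleted and reinstated
when doing so strictly increases SPIC.

H2 starts from the plenary consensus and repeatedly evaluates every
dropset of 1..d leaves drawn from the currently kept set, removing the
dropset with the largest strict SPIC gain until none improves.  Dropsets
that would leave fewer than four leaves are skipped rather than rejected,
so d may be as large as the leaf count (an exhaustive first sweep).  Ties
are broken by smallest dropset, then lexicographically smallest leaf
tuple; "strict" means an increase above 1e−9 bits, the absolute tolerance
used for all score comparisons.  Earlier removals stay removed: dropsets
are always scored against the original trees restricted to kept − dropset.

Tree sets are pre-encoded as per-tree sets of split bitmasks over a fixed
alphabetical leaf order, so restricting a tree to a candidate leaf set is
mask arithmetic and a consensus SPIC evaluation costs O(n_trees · splits).

## Evaluation

`info_retained` credits, for each tree restricted to the consensus leaf
set, the p = 1 information of splits shared with the consensus, debits
splits pairwise-incompatible with any consensus split, and normalizes by
the total splitwise information of the *unrestricted* tree set — so leaf
removal always carries an intrinsic cost, and a leaf removed from a
polytomy is not free (unlike under RBIC).  `tree_signal` matches consensus
splits to reference splits one-to-one (scipy's linear-sum assignment on
the pairwise shared-information matrix; incompatible pairs share zero) and
reports signal (matched sum), noise (total − signal), and accuracy
(signal − noise): a star tree scores zero, wrong resolution scores
negative.  Quartet counts (s same, d different, u unresolved in at least
one tree; s+d+u = C(n,4)) are classified from path-length distances via the
four-point condition, with an independent split-containment classifier used
as a test oracle; brute-force O(n⁴) counting is intended for desk scale,
roughly n ≤ 60.  All evaluation is topology-only: supports never enter.

## Synthetic data

`planted_rogue_set` draws one uniform random backbone on the stable leaves
(sequential leaf insertion into a uniformly chosen edge, which induces the
uniform distribution over topologies — checked by chi-square over 30,000
quartet draws), copies it per tree, applies `nni_noise` random NNI moves,
and attaches each rogue to a uniformly random edge.  Defaults — 20 stable
leaves, 1 rogue, 100 trees, no NNI noise — define the standard recovery
experiment: over 20 seeded replicates, the rogue must top the instability
ranking and both heuristics must recover exactly the planted set in at
least 18, with random deletion retaining strictly less information in at
least 19.  The generator emulates positional wandering only: it does not
model character-level noise, correlated rogues, or the support erosion
produced by finite-data bootstrap resampling, so passing recovery tests
demonstrate behaviour under clean positional conflict, not performance on
empirical bootstrap sets.

The `figure2_fixture` configurations are deterministic: fixture c realizes
attachment frequencies as exact counts (round(p₁·n_trees) of 1000 trees by
default), making consensus supports and hence SPIC an exact step function
of p₁.  The threshold search brackets the sign change of
SPIC(plenary) − SPIC(reduced) by bisection to within half a tree count and
reports the bracket midpoint; with 1000 trees the step sits between
p₁ = 0.585 (gap −0.0298 bits) and 0.586 (+0.00022 bits), giving 58.55%.
The base topology is (((1,2),3),(4,(5,6))) with the cherry attached to the
pendant edge of leaf 1 or leaf 6 — the two symmetric extremes of the
balanced shape.

## Numerical choices and limitations

All information arithmetic is in log₂ space (cumulative double-factorial
tables), so leaf counts in the thousands are safe.  Score comparisons use
absolute tolerance 1e−9 bits.  Leaf labels compare as exact,
case-sensitive strings.  Supports parsed from internal-node labels are
taken as frequencies; a file whose values exceed 1 is assumed
percentage-scaled.  Polytomous input trees are accepted and simply
contribute fewer splits.  Known limitations: SPIC double-counts dependent
splits; H2 is exponential in the dropset bound d; quartet counting is
O(n⁴); consensus across trees with differing leaf sets (supertrees) and
branch-length-aware scoring are out of scope.
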