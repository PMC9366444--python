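"""Information-theoretic scores for splits, clades, and consensus trees.

There are ``R(n) = (2n-3)!!`` rooted and ``U(n) = (2n-5)!!`` unrooted binary
topologies on *n* labeled leaves.  A split A|B is displayed by
``U_{A|B} = R(|A|) * R(|B|)`` of the U(n) unrooted topologies.  Treating a
split's support *p* (its frequency in a tree set) as the probability that
the split occurs in the unknown true tree, and spreading that probability
uniformly over the topologies that do (and do not) display it, the
*phylogenetic information content* of the supported split is the entropy
reduction it imposes on the uniform distribution over the U(n) topologies:

    PIC(A|B, p) = log2 U(n) + p (log2 p - log2 U_{A|B})
                            + q (log2 q - log2 (U(n) - U_{A|B}))

with q = 1 - p and q log2 q -> 0 as p -> 1.  PIC is zero exactly when p
equals the prior probability U_{A|B} / U(n) and grows to
log2 U(n) - log2 U_{A|B} at p = 1.

The *splitwise phylogenetic information content* (SPIC) of a consensus tree
is the sum of PIC over its supported splits; splits are not independent, so
SPIC double-counts some information, but it is computable in polynomial
time and is the objective maximized by the rogue-detection heuristics.  The
rooted analogue scores clades instead: a clade of a leaves out of n sits in
``R(a) * R(n - a + 1)`` of the R(n) rooted topologies.

All computation is in log space (base 2), so leaf counts in the thousands
are unproblematic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

import numpy as np
from scipy.optimize import linear_sum_assignment

from .trees import ConsensusTree, Split, Tree, splits_compatible

__all__ = [
    "log2_num_trees",
    "log2_split_count",
    "log2_clade_count",
    "split_pic",
    "clade_pic",
    "split_self_info",
    "spic",
    "rbic",
    "ScoredConsensus",
    "score_consensus",
    "shared_split_info",
    "SignalNoise",
    "tree_signal",
]

SCORE_TOL = 1e-9   # absolute tolerance for comparing scores in bits


# cumulative log2 double factorials, grown on demand
_ROOTED_CACHE = [0.0, 0.0, 0.0]     # R(0) unused, R(1) = R(2) = 1
_UNROOTED_CACHE = [0.0, 0.0, 0.0, 0.0]


def _log2_rooted(n: int) -> float:
    # R(n) = (2n-3)!!, R(1) = R(2) = 1
    if n < 1:
        raise ValueError("leaf count must be >= 1")
    while len(_ROOTED_CACHE) <= n:
        k = len(_ROOTED_CACHE)
        _ROOTED_CACHE.append(_ROOTED_CACHE[-1] + log2(2 * k - 3))
    return _ROOTED_CACHE[n]


def _log2_unrooted(n: int) -> float:
    # U(n) = (2n-5)!!, U(1) = U(2) = U(3) = 1
    if n < 1:
        raise ValueError("leaf count must be >= 1")
    while len(_UNROOTED_CACHE) <= n:
        k = len(_UNROOTED_CACHE)
        _UNROOTED_CACHE.append(_UNROOTED_CACHE[-1] + log2(2 * k - 5))
    return _UNROOTED_CACHE[n]


def log2_num_trees(n: int, rooted: bool = False) -> float:
    """log2 of the number of binary topologies on n labeled leaves."""
    return _log2_rooted(n) if rooted else _log2_unrooted(n)


def log2_split_count(a: int, b: int) -> float:
    """log2 of the number of unrooted binary (a+b)-leaf trees displaying a
    split with block sizes (a, b): log2(R(a) * R(b))."""
    if a < 1 or b < 1:
        raise ValueError("block sizes must be >= 1")
    return _log2_rooted(a) + _log2_rooted(b)


def log2_clade_count(a: int, n: int) -> float:
    """log2 of the number of rooted binary n-leaf trees containing a clade of
    size a: log2(R(a) * R(n - a + 1))."""
    if not 1 <= a <= n - 1:
        raise ValueError("clade size must lie in [1, n - 1]")
    return _log2_rooted(a) + _log2_rooted(n - a + 1)


def _pic(log2_total: float, log2_with: float, p: float) -> float:
    if not 0.0 < p <= 1.0:
        raise ValueError("support must lie in (0, 1]")
    q = 1.0 - p
    val = log2_total + p * (log2(p) - log2_with)
    if q > 0.0:
        log2_without = log2_total + log2(1.0 - 2.0 ** (log2_with - log2_total))
        val += q * (log2(q) - log2_without)
    return max(val, 0.0)


def split_pic(a: int, b: int, p: float) -> float:
    """Phylogenetic information content, in bits, of a split with block sizes
    (a, b) supported at frequency p (unrooted convention)."""
    if a < 2 or b < 2:
        raise ValueError("informative splits need both blocks >= 2")
    return _pic(_log2_unrooted(a + b), log2_split_count(a, b), p)


def clade_pic(a: int, n: int, p: float) -> float:
    """Information content of a clade of size a in an n-leaf rooted tree,
    supported at frequency p (rooted convention)."""
    if not 2 <= a <= n - 1:
        raise ValueError("nontrivial clades need 2 <= a <= n - 1")
    return _pic(_log2_rooted(n), log2_clade_count(a, n), p)


def split_self_info(split: Split) -> float:
    """-log2 of the prior probability that a random binary tree displays the
    split; equals PIC at p = 1."""
    a, b = split.sizes
    return _log2_unrooted(a + b) - log2_split_count(a, b)


def spic(consensus: ConsensusTree) -> float:
    """Splitwise phylogenetic information content of a consensus tree, in
    bits: the sum of PIC over its supported splits (clades in rooted mode).
    A star tree scores 0."""
    total = 0.0
    if consensus.rooted:
        n = len(consensus.leaf_labels)
        for clade, p in consensus.supports.items():
            total += clade_pic(len(clade), n, p)
    else:
        for split, p in consensus.supports.items():
            a, b = split.sizes
            total += split_pic(a, b, p)
    return total


def rbic(consensus: ConsensusTree) -> float:
    """Relative bipartition information content: the plain sum of support
    values over the consensus splits (the RogueNaRok comparator score)."""
    return float(sum(consensus.supports.values()))


@dataclass
class ScoredConsensus:
    consensus: ConsensusTree
    spic_bits: float
    rbic: float


def score_consensus(consensus: ConsensusTree) -> ScoredConsensus:
    return ScoredConsensus(consensus=consensus, spic_bits=spic(consensus),
                           rbic=rbic(consensus))


# -- shared information between splits -------------------------------------

def _log2_joint_count(s1: Split, s2: Split) -> float:
    """log2 of the number of binary trees displaying both (compatible) splits.

    The tree displaying exactly both splits has its binary resolutions
    counted as a product of U(degree) over internal nodes; for two distinct
    compatible splits this reduces to U(|X|+1) U(|Y|+1) U(c+2) where X, Y
    are disjoint blocks of the two splits and c counts the leaves in
    neither.
    """
    if s1 == s2:
        a, b = s1.sizes
        return log2_split_count(a, b)
    n = len(s1.leaves)
    for x in (s1.block_a, s1.block_b):
        for y in (s2.block_a, s2.block_b):
            if not x & y:
                c = n - len(x) - len(y)
                return (_log2_unrooted(len(x) + 1)
                        + _log2_unrooted(len(y) + 1)
                        + _log2_unrooted(c + 2))
    raise ValueError("splits are incompatible")


def shared_split_info(s1: Split, s2: Split) -> float:
    """Shared phylogenetic information of two splits, in bits.

    For compatible splits this is h(s1) + h(s2) - h(s1 and s2), where h is
    the self-information of displaying the split(s) in a uniformly random
    binary tree.  Incompatible splits share no information (0 by
    convention): they cannot both hold in one tree.
    """
    if s1.leaves != s2.leaves:
        raise ValueError("shared_split_info requires a shared leaf set")
    if not splits_compatible(s1, s2):
        return 0.0
    log2_u = _log2_unrooted(len(s1.leaves))
    h1 = log2_u - log2_split_count(*s1.sizes)
    h2 = log2_u - log2_split_count(*s2.sizes)
    h_joint = log2_u - _log2_joint_count(s1, s2)
    return max(h1 + h2 - h_joint, 0.0)


# -- signal and noise against a reference tree -----------------------------

@dataclass
class SignalNoise:
    signal_bits: float
    noise_bits: float
    total_bits: float

    @property
    def accuracy_bits(self) -> float:
        return self.signal_bits - self.noise_bits


def tree_signal(consensus, reference: Tree) -> SignalNoise:
    """Split the information of a consensus topology into signal and noise
    against a reference tree.

    The reference is restricted to the consensus leaf set; consensus and
    reference splits are then matched one-to-one so as to maximize the
    summed pairwise shared information (only compatible pairs can share
    any).  Signal is the matched sum; total is the splitwise information of
    the consensus topology with all supports treated as 1; noise is their
    difference.  An unresolved (star) consensus has zero signal and zero
    accuracy.
    """
    tree = consensus.tree if isinstance(consensus, ConsensusTree) else consensus
    shared = tree.leaf_labels & reference.leaf_labels
    if len(shared) < 4:
        raise ValueError("tree_signal requires at least 4 shared leaves")
    if not tree.leaf_labels <= reference.leaf_labels:
        raise ValueError("reference must contain every consensus leaf")
    ref = reference.restrict(tree.leaf_labels)
    cons_splits = sorted(tree.splits(), key=repr)
    ref_splits = sorted(ref.splits(), key=repr)
    total = sum(split_self_info(s) for s in cons_splits)
    if not cons_splits or not ref_splits:
        return SignalNoise(0.0, total, total)
    w = np.array([[shared_split_info(c, r) for r in ref_splits]
                  for c in cons_splits])
    rows, cols = linear_sum_assignment(w, maximize=True)
    signal = float(w[rows, cols].sum())
    return SignalNoise(signal, total - signal, total)
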