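"""Rogue-taxon detection by maximizing consensus SPIC.

Two heuristics search for the leaf subset whose majority-rule consensus
carries the most splitwise phylogenetic information:

* H1 ranks leaves once by instability, deletes them from least to most
  stable while an admissible upper bound says a better consensus might
  still be reachable, adopts the best-scoring leaf set visited, then tries
  to reinstate deleted leaves from most- to least-recently removed.
  Instability is not recomputed after deletions (keeping H1 at
  O(n_leaves^2 + n_trees^2) work); pass ``recompute_instability=True`` to
  re-rank after every deletion.

* H2 (the dropset strategy of RogueNaRok, rescored with SPIC) repeatedly
  evaluates every dropset of 1..d leaves against the current kept set,
  removes the dropset giving the largest strict SPIC gain, and stops when
  none improves.

Ties are broken deterministically: smallest dropset first, then the
lexicographically smallest leaf tuple.  "Strictly increases" means by more
than 1e-9 bits.  Dropsets that would leave fewer than 4 leaves are never
evaluated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from .info import (SCORE_TOL, ScoredConsensus, clade_pic, score_consensus,
                   spic, split_pic)
from .instability import leaf_instability
from .trees import Tree, TreeSet, _popcount

__all__ = ["IterationRecord", "RogueReport", "spic_upper_bound",
           "h1_search", "h2_search"]


@dataclass
class IterationRecord:
    action: str            # "drop" | "reinstate" | "stop"
    leaves: tuple          # leaves affected (empty for "stop")
    spic_bits: float       # SPIC of the consensus after the action
    n_leaves: int          # leaf count of that consensus


@dataclass
class RogueReport:
    method: str
    iterations: list = field(default_factory=list)
    dropped_final: frozenset = frozenset()
    best_consensus: ScoredConsensus | None = None
    plenary_spic: float = 0.0

    def to_rows(self) -> list:
        return [
            {"iteration": i, "action": r.action,
             "leaves": ",".join(map(str, r.leaves)),
             "spic_bits": r.spic_bits, "n_leaves": r.n_leaves}
            for i, r in enumerate(self.iterations)
        ]


def spic_upper_bound(k: int, rooted: bool = False) -> float:
    """Admissible bound on the SPIC of any consensus on k leaves.

    A consensus on k leaves has at most k - 3 informative splits (k - 1
    clades when rooted), each worth at most the fully supported information
    of the best block size, so no consensus on k or fewer leaves can exceed
    the bound.
    """
    if k < 3:
        raise ValueError("spic_upper_bound requires k >= 3")
    if k == 3:
        return 0.0
    if rooted:
        best = max(clade_pic(a, k, 1.0) for a in range(2, k))
        return (k - 1) * best
    best = max(split_pic(a, k - a, 1.0) for a in range(2, k // 2 + 1))
    return (k - 3) * best


def _consensus_spic(ts: TreeSet, keep_mask: int, threshold: float,
                    rooted: bool) -> float:
    maj = ts.majority_masks(keep_mask, threshold=threshold, rooted=rooted)
    k = _popcount(keep_mask)
    if rooted:
        return sum(clade_pic(_popcount(m), k, p) for m, p in maj.items())
    return sum(split_pic(_popcount(m), k - _popcount(m), p)
               for m, p in maj.items())


def _finalize(report: RogueReport, ts: TreeSet, keep_mask: int,
              threshold: float, rooted: bool) -> RogueReport:
    cons = ts.consensus(keep=ts.labels_of(keep_mask), threshold=threshold,
                        rooted=rooted)
    scored = score_consensus(cons)
    report.best_consensus = scored
    report.dropped_final = frozenset(ts.labels) - cons.leaf_labels
    report.iterations.append(IterationRecord(
        action="stop", leaves=(), spic_bits=scored.spic_bits,
        n_leaves=_popcount(keep_mask)))
    return report


def h1_search(trees: Sequence[Tree], threshold: float = 0.5,
              rooted: bool = False,
              recompute_instability: bool = False) -> RogueReport:
    """Instability-guided rogue search (heuristic H1)."""
    if len(trees) < 2:
        raise ValueError("h1_search requires at least 2 trees")
    ts = TreeSet(trees)
    if ts.n_leaves < 4:
        raise ValueError("h1_search requires at least 4 shared leaves")
    report = RogueReport(method="H1")

    keep = ts.full_mask
    best = _consensus_spic(ts, keep, threshold, rooted)
    report.plenary_spic = best
    best_keep = keep

    ranking = leaf_instability(trees).ranking()
    deletion_order: list = []
    current = trees
    while _popcount(keep) > 4:
        k_next = _popcount(keep) - 1
        if spic_upper_bound(k_next, rooted=rooted) <= best + SCORE_TOL:
            break
        if recompute_instability:
            ranking = leaf_instability(current).ranking()
        victim = next(l for l in ranking
                      if keep & (1 << ts.index[l]) and l not in deletion_order)
        keep &= ~(1 << ts.index[victim])
        deletion_order.append(victim)
        s = _consensus_spic(ts, keep, threshold, rooted)
        report.iterations.append(IterationRecord(
            action="drop", leaves=(victim,), spic_bits=s, n_leaves=k_next))
        if s > best + SCORE_TOL:
            best, best_keep = s, keep
        if recompute_instability:
            current = [t.restrict(ts.labels_of(keep)) for t in current]

    keep = best_keep
    for leaf in reversed(deletion_order):
        bit = 1 << ts.index[leaf]
        if keep & bit:
            continue
        s = _consensus_spic(ts, keep | bit, threshold, rooted)
        if s > best + SCORE_TOL:
            keep |= bit
            best = s
            report.iterations.append(IterationRecord(
                action="reinstate", leaves=(leaf,), spic_bits=s,
                n_leaves=_popcount(keep)))
    return _finalize(report, ts, keep, threshold, rooted)


def h2_search(trees: Sequence[Tree], max_dropset: int = 1,
              threshold: float = 0.5, rooted: bool = False) -> RogueReport:
    """Greedy dropset rogue search (heuristic H2).

    Every combination of 1..max_dropset of the currently kept leaves is a
    candidate dropset; the one whose removal most increases consensus SPIC
    is adopted, and the search repeats until no dropset improves.  Dropsets
    that would leave fewer than 4 leaves are skipped.
    """
    if len(trees) < 2:
        raise ValueError("h2_search requires at least 2 trees")
    if max_dropset < 1:
        raise ValueError("max_dropset must be >= 1")
    ts = TreeSet(trees)
    if ts.n_leaves < 4:
        raise ValueError("h2_search requires at least 4 shared leaves")
    report = RogueReport(method="H2")

    keep = ts.full_mask
    current = _consensus_spic(ts, keep, threshold, rooted)
    report.plenary_spic = current

    while True:
        kept_labels = sorted(ts.labels_of(keep))
        best_gain_spic = current
        best_drop: tuple | None = None
        max_size = min(max_dropset, len(kept_labels) - 4)
        for size in range(1, max_size + 1):
            for combo in itertools.combinations(kept_labels, size):
                m = keep
                for lab in combo:
                    m &= ~(1 << ts.index[lab])
                s = _consensus_spic(ts, m, threshold, rooted)
                if s > best_gain_spic + SCORE_TOL:
                    best_gain_spic = s
                    best_drop = combo
        if best_drop is None:
            break
        for lab in best_drop:
            keep &= ~(1 << ts.index[lab])
        current = best_gain_spic
        report.iterations.append(IterationRecord(
            action="drop", leaves=best_drop, spic_bits=current,
            n_leaves=_popcount(keep)))
    return _finalize(report, ts, keep, threshold, rooted)
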