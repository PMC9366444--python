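"""Scoring a consensus tree against the tree set it summarizes and against
a reference ("true") tree.

``info_retained`` asks how much of the tree set's splitwise information the
consensus reflects: for each tree, restricted to the consensus leaf set,
splits shared with the consensus count for them, splits explicitly
contradicted (pairwise-incompatible with a consensus split) count against
it, and the signed total is normalized by the splitwise information of the
*unrestricted* tree set — so dropping leaves carries an intrinsic cost.

``tree_signal`` (from :mod:`.info`) splits a consensus topology's
information into signal and noise against a reference; accuracy = signal -
noise, so an unresolved tree has zero accuracy and wrongly resolved splits
make it negative.

``quartet_counts`` classifies every four-leaf subset as resolved the same
way in both trees (s), resolved differently (d), or unresolved in at least
one (u); s + d + u = C(n, 4).  Counting is brute force over quadruples,
suitable for trees up to roughly 60 leaves.

All evaluation here is topology-only: split supports never enter, and PIC
is always taken at p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .info import SignalNoise, split_self_info, tree_signal, _log2_unrooted, \
    log2_split_count
from .trees import ConsensusTree, Tree, TreeSet, _popcount

__all__ = ["EvaluationResult", "info_retained", "quartet_counts", "evaluate"]


def _mask_h(m: int, k: int) -> float:
    a = _popcount(m)
    return _log2_unrooted(k) - log2_split_count(a, k - a)


def _masks_incompatible(m1: int, m2: int, keep: int) -> bool:
    return bool(m1 & m2 and m1 & ~m2 & keep and
                ~m1 & m2 & keep and ~m1 & ~m2 & keep)


def info_retained(consensus: ConsensusTree, trees: Sequence[Tree]) -> float:
    """Percentage of the tree set's splitwise information reflected by the
    consensus (may be negative if contradiction dominates)."""
    if not trees:
        raise ValueError("info_retained requires a non-empty tree set")
    ts = TreeSet(trees)
    cons_leaves = consensus.leaf_labels
    if not cons_leaves <= frozenset(ts.labels):
        raise ValueError("consensus leaf set must be a subset of the tree leaf set")
    keep = ts.mask_of(cons_leaves)
    k = _popcount(keep)
    anchor = keep & -keep
    cons_masks = set()
    for s in consensus.splits():
        m = ts.mask_of(s.block_a)
        if m & anchor:
            m = keep & ~m
        cons_masks.add(m)

    n = ts.n_leaves
    numerator = 0.0
    denominator = 0.0
    for tree_masks in ts._splits:
        for m in tree_masks:
            a = _popcount(m)
            denominator += _log2_unrooted(n) - log2_split_count(a, n - a)
        # restrict this tree to the consensus leaf set
        seen = set()
        for m in tree_masks:
            m &= keep
            pc = _popcount(m)
            if pc < 2 or k - pc < 2:
                continue
            if m & anchor:
                m = keep & ~m
            seen.add(m)
        for m in seen:
            if m in cons_masks:
                numerator += _mask_h(m, k)
            elif any(_masks_incompatible(m, c, keep) for c in cons_masks):
                numerator -= _mask_h(m, k)
    if denominator == 0.0:
        return 0.0
    return 100.0 * numerator / denominator


def _quartet_codes(dist: np.ndarray, n: int):
    """Classify each 4-leaf subset by its induced quartet topology.

    Uses the four-point condition on path-length distances: with unit
    branch lengths the two largest pairing sums are equal, the quartet is
    resolved toward the strictly smallest sum, and a star quartet has all
    three sums equal (code -1).
    """
    codes = {}
    for quad in combinations(range(n), 4):
        a, b, c, d = quad
        sums = (dist[a, b] + dist[c, d],
                dist[a, c] + dist[b, d],
                dist[a, d] + dist[b, c])
        lo = min(sums)
        if sums.count(lo) > 1:
            codes[quad] = -1
        else:
            codes[quad] = sums.index(lo)
    return codes


def quartet_counts(t1: Tree, t2: Tree) -> tuple:
    """(s, d, u): quartets resolved identically, resolved differently, and
    unresolved in at least one of the two trees (on their common leaves)."""
    common = t1.leaf_labels & t2.leaf_labels
    if len(common) < 4:
        raise ValueError("quartet_counts requires >= 4 common leaves")
    r1 = t1.restrict(common) if common != t1.leaf_labels else t1
    r2 = t2.restrict(common) if common != t2.leaf_labels else t2
    order = sorted(common)
    n = len(order)
    d1 = r1.geodesic_matrix().loc[order, order].to_numpy()
    d2 = r2.geodesic_matrix().loc[order, order].to_numpy()
    c1 = _quartet_codes(d1, n)
    c2 = _quartet_codes(d2, n)
    s = d = u = 0
    for quad, code1 in c1.items():
        code2 = c2[quad]
        if code1 == -1 or code2 == -1:
            u += 1
        elif code1 == code2:
            s += 1
        else:
            d += 1
    return s, d, u


@dataclass
class EvaluationResult:
    info_retained_pct: float
    inf_total_bits: float
    inf_signal_bits: float | None = None
    inf_noise_bits: float | None = None
    accuracy_bits: float | None = None
    quartets_s: int | None = None
    quartets_d: int | None = None
    quartets_u: int | None = None

    def minus(self, baseline: "EvaluationResult") -> "EvaluationResult":
        """Differences from a baseline (typically the plenary consensus)."""
        def sub(x, y):
            return None if x is None or y is None else x - y
        return EvaluationResult(
            info_retained_pct=self.info_retained_pct - baseline.info_retained_pct,
            inf_total_bits=self.inf_total_bits - baseline.inf_total_bits,
            inf_signal_bits=sub(self.inf_signal_bits, baseline.inf_signal_bits),
            inf_noise_bits=sub(self.inf_noise_bits, baseline.inf_noise_bits),
            accuracy_bits=sub(self.accuracy_bits, baseline.accuracy_bits),
            quartets_s=sub(self.quartets_s, baseline.quartets_s),
            quartets_d=sub(self.quartets_d, baseline.quartets_d),
            quartets_u=sub(self.quartets_u, baseline.quartets_u),
        )


def evaluate(consensus: ConsensusTree, trees: Sequence[Tree],
             reference: Tree | None = None,
             baseline: "EvaluationResult | None" = None) -> EvaluationResult:
    """Assemble the full evaluation of a consensus tree.

    Precision (``inf_total_bits``) is the splitwise information of the
    consensus topology with all supports treated as 1.  When a reference
    tree is supplied, signal/noise/accuracy and quartet counts against it
    are added; when a baseline result is supplied, all scores are returned
    as differences from it.
    """
    retained = info_retained(consensus, trees)
    total = sum(split_self_info(s) for s in consensus.splits())
    result = EvaluationResult(info_retained_pct=retained, inf_total_bits=total)
    if reference is not None:
        if not consensus.leaf_labels <= reference.leaf_labels:
            raise ValueError("reference leaf set must contain the consensus leaf set")
        sn = tree_signal(consensus, reference)
        s, d, u = quartet_counts(consensus.tree,
                                 reference.restrict(consensus.leaf_labels))
        result = replace(result, inf_signal_bits=sn.signal_bits,
                         inf_noise_bits=sn.noise_bits,
                         accuracy_bits=sn.accuracy_bits,
                         quartets_s=s, quartets_d=d, quartets_u=u)
    if baseline is not None:
        result = result.minus(baseline)
    return result
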