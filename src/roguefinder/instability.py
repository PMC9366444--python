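"""Leaf instability from graph geodesics across a set of trees.

The instability of a pair of leaves is ln(MAD / mean), where MAD is the
median absolute deviation (from the median) of the pair's graph geodesic
across the trees and mean is the arithmetic mean of those geodesics.  The
log emphasizes leaves that travel far over incidental changes in tree
shape; dividing by the mean makes the statistic scale-free.  A perfectly
stable pair has MAD = 0; to keep the statistic finite the MAD is floored at
eps = 1 / (2 * n_trees), half the smallest nonzero deviation observable in
the set, which preserves the ranking.

A leaf's instability is the mean over the n - 1 pairs containing it; higher
values mark leaves whose position varies more between trees.  Only the
ranking feeds the H1 rogue search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trees import Tree, _check_shared_leaves

__all__ = ["InstabilityScores", "pair_instability", "leaf_instability"]


@dataclass
class InstabilityScores:
    per_pair: dict   # frozenset({leaf1, leaf2}) -> float
    per_leaf: dict   # leaf -> float

    def ranking(self) -> list:
        """Leaves from least to most stable (ties broken by label)."""
        return sorted(self.per_leaf, key=lambda l: (-self.per_leaf[l], l))


def pair_instability(distances: Sequence[float]) -> float:
    """Instability of one leaf pair from its geodesics across trees."""
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("pair_instability requires distances from >= 2 trees")
    eps = 1.0 / (2.0 * d.size)
    mad = float(np.median(np.abs(d - np.median(d))))
    return float(np.log(max(mad, eps) / d.mean()))


def leaf_instability(trees: Sequence[Tree]) -> InstabilityScores:
    """Per-pair and per-leaf instability over a set of trees on one leaf set."""
    if len(trees) < 2:
        raise ValueError("leaf_instability requires at least 2 trees")
    _check_shared_leaves(trees)
    labels = sorted(trees[0].leaf_labels)
    n = len(labels)
    if n < 4:
        raise ValueError("leaf_instability requires at least 4 leaves")
    stack = np.stack([t.geodesic_matrix().loc[labels, labels].to_numpy()
                      for t in trees])          # (T, n, n)
    eps = 1.0 / (2.0 * len(trees))
    med = np.median(stack, axis=0)
    mad = np.median(np.abs(stack - med), axis=0)
    mean = stack.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log(np.maximum(mad, eps) / mean)
    per_pair = {}
    per_leaf = {}
    off_diag = ~np.eye(n, dtype=bool)
    for i, a in enumerate(labels):
        per_leaf[a] = float(vals[i, off_diag[i]].mean())
        for j in range(i + 1, n):
            per_pair[frozenset((a, labels[j]))] = float(vals[i, j])
    return InstabilityScores(per_pair=per_pair, per_leaf=per_leaf)
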