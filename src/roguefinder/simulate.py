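"""Seeded generators for random trees, planted-rogue tree sets, and small
worked-example fixtures.

The planted-rogue generator emulates the situation rogue detection targets:
a tree set (think bootstrap or posterior sample) in which most leaves keep
a stable position while a known subset of rogue leaves re-attaches at a
uniformly random edge in every tree.  Optional random NNI moves perturb the
stable backbone to mimic residual topological noise.  Everything is driven
by a single :class:`numpy.random.Generator`, so outputs are a pure function
of the seed.

``figure2_fixture`` builds three tiny hand-analyzable configurations:

a) five 5-leaf trees in which rogue leaf X takes each possible position on
   the tree ((1,2),(3,4)) — their strict consensus is a star, yet the trees
   agree unanimously about leaves 1-4;
b) 100 rooted trees on a fixed 6-leaf base in which X is sister to leaf 3
   in 67 trees and to leaf 4 in 33;
c) rooted trees on a balanced 6-leaf base plus a rogue cherry (X,Y)
   attached sister to leaf 1 in a fraction p1 of trees and sister to leaf 6
   otherwise, with deterministic counts so split supports are an exact
   function of p1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trees import Tree, majority_consensus
from .info import spic

__all__ = ["SyntheticSpec", "random_binary_tree", "planted_rogue_set",
           "figure2_fixture", "figure2c_crossover"]


@dataclass
class SyntheticSpec:
    """Conditions for a planted-rogue tree set.

    Defaults describe the standard recovery experiment: 20 stable leaves,
    one rogue, 100 trees, a noise-free backbone.
    """
    n_stable: int = 20
    n_rogues: int = 1
    n_trees: int = 100
    nni_noise: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_stable < 4:
            raise ValueError("n_stable must be >= 4")
        if self.n_trees < 2:
            raise ValueError("n_trees must be >= 2")
        if self.n_rogues < 0 or self.nni_noise < 0:
            raise ValueError("counts must be non-negative")


class _EditableTree:
    """Minimal unrooted tree editor: leaf insertion and NNI on adjacency lists."""

    def __init__(self, labels: Sequence[str]):
        if len(labels) < 3:
            raise ValueError("need at least 3 labels")
        self.adj: dict = {}
        self.leaf_of: dict = {}          # node id -> label
        self._next = 0
        hub = self._new()
        for lab in labels[:3]:
            self._add_pendant(hub, lab)

    def _new(self) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        return nid

    def _link(self, u, v):
        self.adj[u].add(v)
        self.adj[v].add(u)

    def _add_pendant(self, node, label):
        leaf = self._new()
        self.leaf_of[leaf] = label
        self._link(node, leaf)

    def copy(self) -> "_EditableTree":
        out = _EditableTree.__new__(_EditableTree)
        out.adj = {k: set(v) for k, v in self.adj.items()}
        out.leaf_of = dict(self.leaf_of)
        out._next = self._next
        return out

    def edges(self) -> list:
        return sorted((u, v) for u in self.adj for v in self.adj[u] if u < v)

    def add_leaf_on_edge(self, label: str, edge: tuple):
        u, v = edge
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        mid = self._new()
        self._link(u, mid)
        self._link(mid, v)
        self._add_pendant(mid, label)

    def internal_edges(self) -> list:
        return [(u, v) for u, v in self.edges()
                if u not in self.leaf_of and v not in self.leaf_of]

    def nni(self, rng: np.random.Generator):
        """One random nearest-neighbour interchange (no-op if no internal edge)."""
        cands = self.internal_edges()
        if not cands:
            return
        u, v = cands[rng.integers(len(cands))]
        a = sorted(w for w in self.adj[u] if w != v)[rng.integers(2)]
        bs = sorted(w for w in self.adj[v] if w != u)
        b = bs[rng.integers(len(bs))]
        self.adj[u].discard(a); self.adj[a].discard(u)
        self.adj[v].discard(b); self.adj[b].discard(v)
        self._link(u, b)
        self._link(v, a)

    def newick(self) -> str:
        # root at the neighbour of the alphabetically first leaf
        first = min(self.leaf_of.values())
        leaf = next(k for k, lab in self.leaf_of.items() if lab == first)
        start = next(iter(self.adj[leaf]))

        def render(node, parent) -> str:
            if node in self.leaf_of:
                return self.leaf_of[node]
            parts = sorted(render(ch, node)
                           for ch in self.adj[node] if ch != parent)
            return "(" + ",".join(parts) + ")"

        parts = sorted(render(ch, start) for ch in self.adj[start])
        return "(" + ",".join(parts) + ");"

    def to_tree(self) -> Tree:
        return Tree.from_newick(self.newick(), rooted=False)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_binary_tree(labels: Sequence[str], seed) -> Tree:
    """A uniform random unrooted binary topology on ``labels``.

    Leaves are added sequentially, each to a uniformly chosen edge of the
    growing tree, which induces the uniform distribution over topologies.
    ``seed`` may be an integer or a numpy Generator.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    rng = _as_rng(seed)
    et = _build_random(labels, rng)
    return et.to_tree()


def _build_random(labels: Sequence[str], rng: np.random.Generator) -> _EditableTree:
    et = _EditableTree(labels)
    for lab in labels[3:]:
        edges = et.edges()
        et.add_leaf_on_edge(lab, edges[rng.integers(len(edges))])
    return et


def planted_rogue_set(spec: SyntheticSpec):
    """Generate (trees, rogue_labels, backbone) for a planted-rogue study.

    One random backbone is drawn on the stable labels; each output tree is
    the backbone perturbed by ``nni_noise`` random NNI moves, with every
    rogue leaf then attached to a uniformly random edge.
    """
    rng = _as_rng(spec.seed)
    stable = [f"t{i:02d}" for i in range(1, spec.n_stable + 1)]
    rogues = [f"ROGUE{i}" for i in range(1, spec.n_rogues + 1)]
    backbone_et = _build_random(stable, rng)
    trees = []
    for _ in range(spec.n_trees):
        et = backbone_et.copy()
        for _ in range(spec.nni_noise):
            et.nni(rng)
        for rog in rogues:
            edges = et.edges()
            et.add_leaf_on_edge(rog, edges[rng.integers(len(edges))])
        trees.append(et.to_tree())
    return trees, rogues, backbone_et.to_tree()


_FIG2A = [
    "(((1,X),2),(3,4));",
    "((1,(2,X)),(3,4));",
    "((1,2),((3,X),4));",
    "((1,2),(3,(4,X)));",
    "(((1,2),X),(3,4));",
]
_FIG2B_X3 = "[&R] (((1,2),(3,X)),(4,(5,6)));"
_FIG2B_X4 = "[&R] (((1,2),3),((4,X),(5,6)));"
_FIG2C_X1 = "[&R] ((((1,(X,Y)),2),3),(4,(5,6)));"
_FIG2C_X6 = "[&R] (((1,2),3),(4,(5,(6,(X,Y)))));"


def figure2_fixture(which: str, p1: float = 0.6, n_trees: int = 1000) -> list:
    """Tiny worked-example tree sets (see module docstring).

    ``p1`` and ``n_trees`` apply to fixture ``c`` only; the number of trees
    carrying the (X,Y) cherry next to leaf 1 is ``round(p1 * n_trees)``.
    """
    if which == "a":
        return [Tree.from_newick(s) for s in _FIG2A]
    if which == "b":
        return ([Tree.from_newick(_FIG2B_X3, rooted=True)] * 67
                + [Tree.from_newick(_FIG2B_X4, rooted=True)] * 33)
    if which == "c":
        if not 0.0 < p1 < 1.0:
            raise ValueError("p1 must lie in (0, 1)")
        k = round(p1 * n_trees)
        return ([Tree.from_newick(_FIG2C_X1, rooted=True)] * k
                + [Tree.from_newick(_FIG2C_X6, rooted=True)] * (n_trees - k))
    raise ValueError(f"unknown fixture {which!r}; expected 'a', 'b' or 'c'")


def figure2c_crossover(n_trees: int = 1000, rooted: bool = True):
    """Support frequency (in percent) at which the plenary consensus of the
    rogue-cherry configuration starts to outscore the reduced consensus.

    For each candidate p1 the fixture-c tree set is generated with
    deterministic counts, the SPIC of the plenary 8-leaf majority consensus
    and of the consensus restricted to leaves 1-6 are compared, and the
    sign change is located by bisection (to within half a tree count).
    Returns None if no crossover exists in (50, 100).
    """
    base_keep = {"1", "2", "3", "4", "5", "6"}

    def gap(p: float) -> float:
        trees = figure2_fixture("c", p1=p, n_trees=n_trees)
        plenary = majority_consensus(trees, rooted=rooted)
        reduced = majority_consensus(trees, keep=base_keep, rooted=rooted)
        return spic(plenary) - spic(reduced)

    lo, hi = 0.5 + 1.0 / n_trees, 1.0 - 1.0 / n_trees
    if gap(lo) >= 0 or gap(hi) <= 0:
        return None
    while hi - lo > 1.0 / (4 * n_trees):
        mid = 0.5 * (lo + hi)
        if gap(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 100.0 * 0.5 * (lo + hi)
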