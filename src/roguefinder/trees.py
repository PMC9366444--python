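"""Tree and split data model, I/O, restriction, and majority-rule consensus.

Trees are leaf-labeled topologies; branch lengths are parsed but ignored by
every computation (all scores here are functions of topology and split
support only).  Unless stated otherwise, trees are treated as unrooted and
an edge is identified with the bipartition (*split*) of the leaf set it
induces.  A split is *informative* when both of its blocks contain at least
two leaves.  In rooted mode an internal node is instead identified with the
*clade* (leaf subset) below it.

Internally, split and clade computations run on integer bitmasks over a
fixed alphabetical leaf ordering; the public surface exposes label-based
:class:`Split` objects.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "Split",
    "Tree",
    "ConsensusTree",
    "TreeSet",
    "splits_compatible",
    "read_trees",
    "trees_from_string",
    "write_trees",
    "majority_consensus",
    "tree_from_splits",
]


@dataclass(frozen=True)
class Split:
    """A bipartition A|B of a leaf-label set.

    Canonical orientation: ``block_a`` holds the lexicographically smallest
    label of the ambient leaf set, so equal bipartitions compare equal
    regardless of construction order.
    """

    block_a: frozenset
    block_b: frozenset

    def __post_init__(self):
        a = frozenset(self.block_a)
        b = frozenset(self.block_b)
        if not a or not b:
            raise ValueError("both blocks of a split must be non-empty")
        if a & b:
            raise ValueError(f"split blocks overlap: {sorted(a & b)}")
        if min(min(b), min(a)) not in a:
            a, b = b, a
        object.__setattr__(self, "block_a", a)
        object.__setattr__(self, "block_b", b)

    @property
    def leaves(self) -> frozenset:
        return self.block_a | self.block_b

    @property
    def sizes(self) -> tuple:
        return (len(self.block_a), len(self.block_b))

    @property
    def is_informative(self) -> bool:
        return len(self.block_a) >= 2 and len(self.block_b) >= 2

    def restricted(self, keep: Iterable) -> "Split | None":
        """Induced split on ``keep``, or None if no longer informative."""
        keep = frozenset(keep)
        a = self.block_a & keep
        b = self.block_b & keep
        if len(a) < 2 or len(b) < 2:
            return None
        return Split(a, b)

    def __repr__(self):
        fmt = lambda s: ",".join(map(str, sorted(s)))
        return f"{fmt(self.block_a)}|{fmt(self.block_b)}"


def splits_compatible(s1: Split, s2: Split) -> bool:
    """True iff one tree can display both splits.

    Two splits on the same leaf set are incompatible exactly when all four
    pairwise block intersections are non-empty.
    """
    if s1.leaves != s2.leaves:
        raise ValueError("splits_compatible requires a shared ambient leaf set")
    return not (
        s1.block_a & s2.block_a
        and s1.block_a & s2.block_b
        and s1.block_b & s2.block_a
        and s1.block_b & s2.block_b
    )


def _popcount(x: int) -> int:
    return x.bit_count()


class Tree:
    """A leaf-labeled phylogenetic tree backed by a dendropy topology.

    ``split_supports`` optionally maps informative :class:`Split` objects to
    support frequencies in (0, 1], as parsed from internal-node labels.
    """

    def __init__(self, dtree: dendropy.Tree, rooted: bool | None = None,
                 split_supports: Mapping | None = None):
        self._dtree = dtree
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if not labels:
            raise ValueError("tree has no leaves")
        self.leaf_labels = frozenset(labels)
        if rooted is None:
            rooted = bool(dtree.is_rooted)
        self.rooted = rooted
        self.split_supports = dict(split_supports) if split_supports else {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True)
        tree = cls(dt, rooted=rooted)
        tree.split_supports = tree._parse_node_label_supports()
        return tree

    def newick(self, include_supports: bool = True) -> str:
        if include_supports and self.split_supports:
            self._write_supports_to_labels()
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=not self.rooted,
            suppress_edge_lengths=True,
            unquoted_underscores=True,
        ).strip()
        if self.rooted and not s.startswith("[&R]"):
            s = "[&R] " + s
        return s

    def copy(self) -> "Tree":
        return Tree.from_newick(self.newick(), rooted=self.rooted)

    # -- basic properties --------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def _ordered_labels(self) -> list:
        return sorted(self.leaf_labels)

    def _node_masks(self, index: Mapping | None = None):
        """Yield (node, leaf-bitmask) for nodes that have a parent."""
        if index is None:
            index = {lab: i for i, lab in enumerate(self._ordered_labels())}
        masks = {}
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                masks[node] = 1 << index[node.taxon.label]
            else:
                m = 0
                for ch in node.child_nodes():
                    m |= masks[ch]
                masks[node] = m
        return [(n, m) for n, m in masks.items() if n.parent_node is not None]

    def split_masks(self, index: Mapping) -> frozenset:
        """Canonical informative split bitmasks (side without bit 0)."""
        n = len(index)
        full = (1 << n) - 1
        out = set()
        for _, m in self._node_masks(index):
            pc = _popcount(m)
            if pc < 2 or pc > n - 2:
                continue
            if m & 1:
                m = full & ~m
            out.add(m)
        return frozenset(out)

    def clade_masks(self, index: Mapping) -> frozenset:
        """Nontrivial clade bitmasks (rooted reading): sizes 2 .. n-1."""
        n = len(index)
        out = set()
        for _, m in self._node_masks(index):
            pc = _popcount(m)
            if 2 <= pc <= n - 1:
                out.add(m)
        return frozenset(out)

    def splits(self) -> frozenset:
        """The informative splits, one per internal edge (empty for n < 4)."""
        order = self._ordered_labels()
        index = {lab: i for i, lab in enumerate(order)}
        out = set()
        for m in self.split_masks(index):
            a = frozenset(order[i] for i in range(len(order)) if m >> i & 1)
            out.add(Split(a, self.leaf_labels - a))
        return frozenset(out)

    def clades(self) -> frozenset:
        """Nontrivial clades as frozensets of labels (requires rooted tree)."""
        if not self.rooted:
            raise ValueError("clades() requires a rooted tree")
        order = self._ordered_labels()
        out = set()
        for m in self.clade_masks({lab: i for i, lab in enumerate(order)}):
            out.add(frozenset(order[i] for i in range(len(order)) if m >> i & 1))
        return frozenset(out)

    # -- supports ----------------------------------------------------------

    def _parse_node_label_supports(self) -> dict:
        vals = {}
        order = self._ordered_labels()
        n = len(order)
        for node, m in self._node_masks():
            if node.is_leaf() or node.label is None:
                continue
            try:
                p = float(node.label)
            except ValueError:
                continue
            pc = _popcount(m)
            if pc < 2 or pc > n - 2:
                continue
            a = frozenset(order[i] for i in range(n) if m >> i & 1)
            vals[Split(a, self.leaf_labels - a)] = p
        if vals and max(vals.values()) > 1.0:   # percentage-scaled supports
            vals = {s: p / 100.0 for s, p in vals.items()}
        return vals

    def _write_supports_to_labels(self):
        order = self._ordered_labels()
        n = len(order)
        for node, m in self._node_masks():
            if node.is_leaf():
                continue
            pc = _popcount(m)
            if pc < 2 or pc > n - 2:
                continue
            a = frozenset(order[i] for i in range(n) if m >> i & 1)
            split = Split(a, self.leaf_labels - a)
            if split in self.split_supports:
                node.label = f"{self.split_supports[split]:.6f}"

    # -- operations --------------------------------------------------------

    def restrict(self, keep: Iterable) -> "Tree":
        """Induced topology on ``keep`` with degree-2 nodes suppressed."""
        keep = frozenset(keep)
        if not keep <= self.leaf_labels:
            raise ValueError(f"keep set contains unknown labels: "
                             f"{sorted(keep - self.leaf_labels)}")
        if len(keep) < 3:
            raise ValueError("restriction requires at least 3 leaves")
        if keep == self.leaf_labels:
            return self.copy()
        sub = self._dtree.extract_tree_with_taxa_labels(labels=keep)
        return Tree(sub, rooted=self.rooted)

    def _adjacency(self) -> dict:
        """Node adjacency with any degree-2 root suppressed (unrooted view)."""
        adj: dict = {}

        def link(u, v):
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)

        for node in self._dtree.preorder_node_iter():
            for ch in node.child_nodes():
                link(node, ch)
        seed = self._dtree.seed_node
        if seed in adj and len(adj[seed]) == 2:
            u, v = adj.pop(seed)
            adj[u].discard(seed)
            adj[v].discard(seed)
            link(u, v)
        return adj

    def geodesic_matrix(self) -> pd.DataFrame:
        """Leaf-to-leaf path lengths in edges (symmetric, zero diagonal)."""
        order = self._ordered_labels()
        adj = self._adjacency()
        leaf_nodes = {lf.taxon.label: lf for lf in self._dtree.leaf_node_iter()}
        rows = []
        for lab in order:
            dist = {leaf_nodes[lab]: 0}
            frontier = [leaf_nodes[lab]]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj.get(u, ()):
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            rows.append([dist[leaf_nodes[o]] for o in order])
        return pd.DataFrame(rows, index=order, columns=order)

    def __repr__(self):
        return f"Tree(n_leaves={self.n_leaves}, rooted={self.rooted})"


# -- I/O -------------------------------------------------------------------

def _check_shared_leaves(trees: Sequence[Tree]):
    ref = trees[0].leaf_labels
    for i, t in enumerate(trees[1:], start=1):
        if t.leaf_labels != ref:
            missing = sorted(ref - t.leaf_labels)
            extra = sorted(t.leaf_labels - ref)
            raise ValueError(
                f"tree {i} leaf set differs from tree 0: "
                f"missing {missing}, extra {extra}"
            )


def _trees_from_dendropy(tl: dendropy.TreeList) -> list:
    out = []
    for dt in tl:
        t = Tree(dt)
        t.split_supports = t._parse_node_label_supports()
        out.append(t)
    if not out:
        raise ValueError("no trees found in input")
    _check_shared_leaves(out)
    return out


def read_trees(path, format: str = "newick") -> list:
    """Read a multi-tree newick or nexus file; all trees must share one leaf set."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported format: {format!r}")
    try:
        tl = dendropy.TreeList.get(path=str(path), schema=format,
                                   suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"could not parse {path!s} as {format}: {exc}") from exc
    return _trees_from_dendropy(tl)


def trees_from_string(text: str, format: str = "newick") -> list:
    try:
        tl = dendropy.TreeList.get(data=text, schema=format,
                                   suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"could not parse tree data as {format}: {exc}") from exc
    return _trees_from_dendropy(tl)


def write_trees(trees: Sequence[Tree], path, format: str = "newick"):
    """Write trees, carrying split supports as internal-node labels."""
    if format == "newick":
        with open(path, "w") as fh:
            for t in trees:
                fh.write(t.newick() + "\n")
    elif format == "nexus":
        tl = dendropy.TreeList()
        for t in trees:
            if t.split_supports:
                t._write_supports_to_labels()
            tl.append(dendropy.Tree.get(data=t.newick(), schema="newick",
                                        taxon_namespace=tl.taxon_namespace,
                                        suppress_internal_node_taxa=True))
        tl.write(path=str(path), schema="nexus", suppress_rooting=False)
    else:
        raise ValueError(f"unsupported format: {format!r}")


# -- consensus -------------------------------------------------------------

@dataclass
class ConsensusTree:
    """A majority-rule consensus: topology plus per-split support frequencies.

    In rooted mode ``supports`` is keyed by clade frozensets rather than
    :class:`Split` objects.
    """

    tree: Tree
    supports: dict
    rooted: bool = False
    n_trees: int = 0
    threshold: float = 0.5

    @property
    def leaf_labels(self) -> frozenset:
        return self.tree.leaf_labels

    def splits(self) -> frozenset:
        return self.tree.splits()


def _masks_to_labelsets(masks, order):
    n = len(order)
    return {
        m: frozenset(order[i] for i in range(n) if m >> i & 1) for m in masks
    }


class TreeSet:
    """A set of trees on one shared leaf set, pre-encoded as split bitmasks.

    The encoding makes repeated leaf-subset restriction (the hot operation
    of the dropset searches) a matter of mask arithmetic.
    """

    def __init__(self, trees: Sequence[Tree]):
        if not trees:
            raise ValueError("TreeSet requires at least one tree")
        _check_shared_leaves(trees)
        self.trees = list(trees)
        self.labels = tuple(sorted(trees[0].leaf_labels))
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self.full_mask = (1 << len(self.labels)) - 1
        self._splits = [t.split_masks(self.index) for t in trees]
        self._clades = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def mask_of(self, labels: Iterable) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self.index[lab]
        return m

    def labels_of(self, mask: int) -> frozenset:
        return frozenset(l for i, l in enumerate(self.labels) if mask >> i & 1)

    def _clade_sets(self):
        if self._clades is None:
            for t in self.trees:
                if not t.rooted:
                    raise ValueError("rooted consensus requires rooted input trees")
            self._clades = [t.clade_masks(self.index) for t in self.trees]
        return self._clades

    def split_counts(self, keep_mask: int | None = None) -> Counter:
        """Occurrence counts of informative splits after restriction to keep_mask."""
        if keep_mask is None:
            keep_mask = self.full_mask
        k = _popcount(keep_mask)
        anchor = keep_mask & -keep_mask
        counts: Counter = Counter()
        for masks in self._splits:
            seen = set()
            for m in masks:
                m &= keep_mask
                pc = _popcount(m)
                if pc < 2 or k - pc < 2:
                    continue
                if m & anchor:
                    m = keep_mask & ~m
                seen.add(m)
            counts.update(seen)
        return counts

    def clade_counts(self, keep_mask: int | None = None) -> Counter:
        if keep_mask is None:
            keep_mask = self.full_mask
        k = _popcount(keep_mask)
        counts: Counter = Counter()
        for masks in self._clade_sets():
            seen = set()
            for m in masks:
                m &= keep_mask
                pc = _popcount(m)
                if pc < 2 or pc > k - 1:
                    continue
                seen.add(m)
            counts.update(seen)
        return counts

    def majority_masks(self, keep_mask: int | None = None,
                       threshold: float = 0.5, rooted: bool = False) -> dict:
        """Map of majority split (or clade) masks to support frequencies.

        A split is retained only when it occurs in *strictly more* than
        ``threshold`` of the trees; at the default 0.5 this guarantees the
        retained splits are pairwise compatible.
        """
        if threshold < 0.5:
            raise ValueError("majority threshold below 0.5 does not guarantee "
                             "mutually compatible splits")
        if not 0.5 <= threshold < 1.0:
            raise ValueError("threshold must lie in [0.5, 1)")
        counts = (self.clade_counts(keep_mask) if rooted
                  else self.split_counts(keep_mask))
        T = self.n_trees
        return {m: c / T for m, c in counts.items() if c / T > threshold}

    def consensus(self, keep: Iterable | None = None, threshold: float = 0.5,
                  rooted: bool = False) -> ConsensusTree:
        keep_mask = self.full_mask if keep is None else self.mask_of(keep)
        if _popcount(keep_mask) < 3:
            raise ValueError("consensus requires at least 3 retained leaves")
        maj = self.majority_masks(keep_mask, threshold, rooted)
        keep_labels = self.labels_of(keep_mask)
        blocks = _masks_to_labelsets(maj, self.labels)
        if rooted:
            supports = {blocks[m]: p for m, p in maj.items()}
            tree = tree_from_clades(keep_labels, supports)
        else:
            supports = {
                Split(blocks[m], keep_labels - blocks[m]): p
                for m, p in maj.items()
            }
            tree = tree_from_splits(keep_labels, supports)
        return ConsensusTree(tree=tree, supports=supports, rooted=rooted,
                             n_trees=self.n_trees, threshold=threshold)


def majority_consensus(trees: Sequence[Tree], keep: Iterable | None = None,
                       threshold: float = 0.5, rooted: bool = False) -> ConsensusTree:
    """Majority-rule consensus of ``trees`` restricted to ``keep``.

    Each input tree is first restricted to ``keep``; splits occurring in
    strictly more than ``threshold`` of the restricted trees are assembled
    into one tree, with supports attached as frequencies.
    """
    return TreeSet(trees).consensus(keep=keep, threshold=threshold, rooted=rooted)


# -- assembling a tree from compatible splits ------------------------------

def _assemble(universe: frozenset, clades: dict, anchor=None, rooted=False) -> str:
    """Build a newick string from a laminar family of clades.

    ``clades`` maps frozenset -> label string ('' for none).  For the
    unrooted case ``anchor`` is the leaf used to orient blocks; it hangs
    directly off the basal node.
    """
    ordered = sorted(clades, key=lambda c: (-len(c), sorted(c)))
    children: dict = {None: []}   # parent clade (None = basal node) -> children
    parent: dict = {}
    for i, c in enumerate(ordered):
        par = None
        for cand in reversed(ordered[:i]):   # smallest strict superset wins
            if c < cand:
                par = cand
                break
            if c & cand:
                raise ValueError("splits are not mutually compatible")
        parent[c] = par
        children.setdefault(c, [])
        children.setdefault(par, []).append(c)

    def direct_leaves(c, members):
        cov = set()
        for ch in children.get(c, []):
            cov |= ch
        return sorted(members - cov)

    def render(c) -> str:
        parts = [render(ch) for ch in children.get(c, [])]
        parts += direct_leaves(c, c)
        parts.sort()
        return "(" + ",".join(parts) + ")" + clades[c]

    top = [render(c) for c in children[None]]
    top += direct_leaves(None, set(universe) - ({anchor} if anchor else set()))
    if anchor is not None:
        top.append(str(anchor))
    top.sort()
    body = "(" + ",".join(top) + ");"
    return ("[&R] " + body) if rooted else body


def tree_from_splits(leaves: Iterable, splits) -> Tree:
    """Assemble the (unique, possibly multifurcating) unrooted tree displaying
    a mutually compatible set of splits; supports become node labels."""
    leaves = frozenset(leaves)
    if isinstance(splits, Mapping):
        items = dict(splits)
    else:
        items = {s: None for s in splits}
    anchor = min(leaves)
    clades = {}
    for s, p in items.items():
        if s.leaves != leaves:
            raise ValueError("split leaf set does not match the tree leaf set")
        block = s.block_b if anchor in s.block_a else s.block_a
        clades[frozenset(block)] = "" if p is None else f"{p:.6f}"
    nwk = _assemble(leaves, clades, anchor=anchor, rooted=False)
    return Tree.from_newick(nwk, rooted=False)


def tree_from_clades(leaves: Iterable, clades) -> Tree:
    """Assemble a rooted tree from a nested family of clades."""
    leaves = frozenset(leaves)
    if isinstance(clades, Mapping):
        items = dict(clades)
    else:
        items = {c: None for c in clades}
    fam = {frozenset(c): ("" if p is None else f"{p:.6f}")
           for c, p in items.items()}
    nwk = _assemble(leaves, fam, anchor=None, rooted=True)
    return Tree.from_newick(nwk, rooted=True)
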