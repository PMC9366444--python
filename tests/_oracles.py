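"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and independent of the package
internals: topologies are enumerated by explicit recursive leaf insertion
on adjacency lists, splits are recovered by rooting each enumerated tree at
leaf 0, and optimal split matchings are found by exhaustive permutation.
"""

from functools import lru_cache
from itertools import combinations, permutations


def _enumerate_edge_lists(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal node ids start at n.  Built by inserting leaf k into every
    edge of every topology on leaves 0..k-1.
    """
    def rec(k, next_id):
        if k == 3:
            hub = next_id
            yield [(0, hub), (1, hub), (2, hub)], next_id + 1
            return
        for edges, nxt in rec(k - 1, next_id):
            for i, (u, v) in enumerate(edges):
                mid = nxt
                yield (edges[:i] + edges[i + 1:]
                       + [(u, mid), (mid, v), (k - 1, mid)]), nxt + 1
    if n < 3:
        raise ValueError("need n >= 3")
    for edges, _ in rec(n, n):
        yield edges


def _subtree_masks(edges, n):
    """Leaf bitmask below every edge, directed away from leaf 0."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    masks = []

    def walk(node, parent):
        if node < n:
            return 1 << node
        m = 0
        for nb in adj[node]:
            if nb != parent:
                m |= walk(nb, node)
        masks.append(m)
        return m

    start = adj[0][0]
    walk(start, 0)
    return masks


def splits_of_topology(edges, n):
    """Canonical informative split masks (side not containing leaf 0)."""
    full = (1 << n) - 1
    out = set()
    for m in _subtree_masks(edges, n):
        pc = m.bit_count()
        if pc < 2 or pc > n - 2:
            continue
        if m & 1:
            m = full & ~m
        out.add(m)
    return frozenset(out)


@lru_cache(maxsize=None)
def all_unrooted_split_sets(n):
    """Split sets of every unrooted binary topology on n leaves."""
    return tuple(splits_of_topology(e, n) for e in _enumerate_edge_lists(n))


@lru_cache(maxsize=None)
def all_rooted_clade_sets(n):
    """Clade sets (masks over leaves 0..n-1) of every rooted binary topology.

    A rooted tree on n leaves is an unrooted tree on n+1 leaves where the
    extra leaf (index n) marks the root; clades are the subtree masks not
    containing the handle.
    """
    out = []
    for edges in _enumerate_edge_lists(n + 1):
        adj = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        clades = set()

        def walk(node, parent):
            if node <= n:
                return 1 << node
            m = 0
            for nb in adj[node]:
                if nb != parent:
                    m |= walk(nb, node)
            clades.add(m)
            return m

        walk(adj[n][0], n)
        out.append(frozenset(m for m in clades
                             if 2 <= m.bit_count() <= n - 1))
    return tuple(out)


def count_trees_with_splits(n, *split_masks):
    """How many unrooted binary n-leaf topologies display all given splits."""
    full = (1 << n) - 1
    canon = []
    for m in split_masks:
        canon.append((full & ~m) if m & 1 else m)
    return sum(1 for s in all_unrooted_split_sets(n)
               if all(c in s for c in canon))


def count_rooted_trees_with_clade(n, clade_mask):
    return sum(1 for c in all_rooted_clade_sets(n) if clade_mask in c)


def best_matching_bruteforce(weight_rows):
    """Max-weight one-to-one assignment by exhaustive permutation.

    weight_rows: list of lists (rows x cols).  Returns the best total.
    """
    nr = len(weight_rows)
    nc = len(weight_rows[0]) if nr else 0
    best = 0.0
    k = min(nr, nc)
    for rows in combinations(range(nr), k):
        for cols in permutations(range(nc), k):
            tot = sum(weight_rows[r][c] for r, c in zip(rows, cols))
            best = max(best, tot)
    return best


def quartet_code_from_splits(splits, quad):
    """Resolve a 4-leaf subset from a tree's Split objects (independent of
    the distance-based classification in the package).

    Returns 0/1/2 for ab|cd, ac|bd, ad|bc, or -1 if unresolved.
    """
    a, b, c, d = quad
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    for code, ((x, y), (z, w)) in enumerate(pairings):
        for s in splits:
            if ({x, y} <= s.block_a and {z, w} <= s.block_b) or \
               ({x, y} <= s.block_b and {z, w} <= s.block_a):
                return code
    return -1
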