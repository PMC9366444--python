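"""Information scores: tree counts, split/clade PIC, SPIC, RBIC, shared
information, and signal/noise — checked against enumeration oracles."""

import math
from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from roguefinder import (Split, Tree, clade_pic, log2_clade_count,
                         log2_num_trees, log2_split_count, majority_consensus,
                         random_binary_tree, rbic, score_consensus,
                         shared_split_info, spic, split_pic, split_self_info,
                         tree_signal, trees_from_string)
from _oracles import (all_rooted_clade_sets, all_unrooted_split_sets,
                      best_matching_bruteforce, count_rooted_trees_with_clade,
                      count_trees_with_splits)


def split(a, b):
    return Split(frozenset(a), frozenset(b))


class TestTreeCounts:
    @pytest.mark.parametrize("n,expected", [(3, 1), (4, 3), (5, 15),
                                            (6, 105), (7, 945)])
    def test_unrooted_counts_match_enumeration(self, n, expected):
        assert len(all_unrooted_split_sets(n)) == expected
        assert 2 ** log2_num_trees(n) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_rooted_counts_match_enumeration(self, n):
        enumerated = len(all_rooted_clade_sets(n))
        assert 2 ** log2_num_trees(n, rooted=True) == pytest.approx(enumerated)

    def test_rooted_base_cases(self):
        assert log2_num_trees(1, rooted=True) == 0.0
        assert log2_num_trees(2, rooted=True) == 0.0
        assert log2_num_trees(4, rooted=True) == pytest.approx(math.log2(15))

    def test_no_overflow_at_large_n(self):
        val = log2_num_trees(10_000)
        assert val > 0 and math.isfinite(val)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            log2_num_trees(0)


class TestSplitCounts:
    @pytest.mark.parametrize("a,b,expected", [(2, 2, 1), (2, 3, 3), (3, 5, 315)])
    def test_block_size_counts_match_bruteforce(self, a, b, expected):
        n = a + b
        mask = (1 << a) - 1  # split {0..a-1} | rest
        assert count_trees_with_splits(n, mask) == expected
        assert 2 ** log2_split_count(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_every_split_count_matches_enumeration(self, n):
        # all block partitions of n leaves, every distinct split mask
        seen = set()
        for s in all_unrooted_split_sets(n):
            seen |= s
        for mask in seen:
            a = mask.bit_count()
            assert 2 ** log2_split_count(a, n - a) == pytest.approx(
                count_trees_with_splits(n, mask))

    @pytest.mark.parametrize("n,a", [(4, 2), (5, 2), (5, 3), (6, 2), (6, 4)])
    def test_clade_counts_match_rooted_enumeration(self, n, a):
        mask = (1 << a) - 1
        assert 2 ** log2_clade_count(a, n) == pytest.approx(
            count_rooted_trees_with_clade(n, mask))


class TestSplitPic:
    def test_certain_quartet_split(self):
        assert split_pic(2, 2, 1.0) == pytest.approx(math.log2(3))

    def test_zero_at_prior_support(self):
        # 3 of the 15 five-leaf trees contain a (2,3) split
        assert split_pic(2, 3, 3 / 15) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value_2_3_at_60pct(self):
        assert split_pic(2, 3, 0.6) == pytest.approx(0.5509775, abs=1e-6)

    def test_matches_entropy_difference_over_enumerated_trees(self):
        # support 0.6 spread uniformly over the 3 five-leaf trees containing
        # the split, 0.4 over the other 12: PIC = H(uniform) - H(posterior)
        p, n_with, n_tot = 0.6, 3, 15
        h_post = -(n_with * (p / n_with) * math.log2(p / n_with)
                   + (n_tot - n_with) * ((1 - p) / (n_tot - n_with))
                   * math.log2((1 - p) / (n_tot - n_with)))
        assert split_pic(2, 3, p) == pytest.approx(math.log2(n_tot) - h_post)

    def test_invalid_support_rejected(self):
        for p in (0.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                split_pic(2, 2, p)

    @given(st.integers(2, 6), st.integers(2, 6),
           st.floats(1e-6, 1.0, exclude_max=False))
    @settings(max_examples=200, derandomize=True)
    def test_nonnegative_everywhere(self, a, b, p):
        assert split_pic(a, b, p) >= 0.0

    def test_monotone_above_prior(self):
        prior = 2 ** (log2_split_count(3, 4) - log2_num_trees(7))
        grid = [prior + i * (1 - prior) / 50 for i in range(51)]
        vals = [split_pic(3, 4, p) for p in grid]
        assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vals, vals[1:]))

    def test_full_support_is_self_information(self):
        s = split("123", "4567")
        assert split_pic(3, 4, 1.0) == pytest.approx(split_self_info(s))


class TestSpicRbic:
    def test_fig2a_plenary_and_reduced(self, fig2a_trees):
        plenary = majority_consensus(fig2a_trees)
        reduced = majority_consensus(fig2a_trees, keep={"1", "2", "3", "4"})
        assert spic(plenary) == pytest.approx(2 * split_pic(2, 3, 0.6))
        assert spic(reduced) == pytest.approx(math.log2(3))
        assert spic(reduced) > spic(plenary)

    def test_star_scores_zero_on_both(self):
        trees = trees_from_string("((A,B),(C,D));\n((A,C),(B,D));")
        cons = majority_consensus(trees)
        assert spic(cons) == 0.0 and rbic(cons) == 0.0

    def test_rbic_sums_supports(self, fig2a_trees):
        assert rbic(majority_consensus(fig2a_trees)) == pytest.approx(1.2)

    def test_rbic_of_unanimous_binary_tree_is_n_minus_3(self):
        t = random_binary_tree(list("ABCDEFGH"), 7)
        cons = majority_consensus([t.copy(), t.copy()])
        assert rbic(cons) == pytest.approx(len(t.leaf_labels) - 3)

    def test_adding_compatible_split_never_decreases_spic(self):
        # every PIC term is nonnegative, so a richer consensus scores >=
        t = random_binary_tree(list("ABCDEFG"), 11)
        full = majority_consensus([t.copy(), t.copy()])
        partial_supports = dict(list(sorted(full.supports.items(),
                                            key=lambda kv: repr(kv[0])))[:2])
        partial = majority_consensus([t.copy(), t.copy()])
        partial.supports = partial_supports
        assert spic(full) >= spic(partial) - 1e-12

    def test_score_consensus_bundles_both(self, fig2a_trees):
        scored = score_consensus(majority_consensus(fig2a_trees))
        assert scored.spic_bits == pytest.approx(1.1019550, abs=1e-6)
        assert scored.rbic == pytest.approx(1.2)

    def test_rooted_spic_uses_clade_information(self):
        trees = trees_from_string("[&R] ((A,B),(C,D));\n[&R] ((A,B),(C,D));")
        cons = majority_consensus(trees, rooted=True)
        assert spic(cons) == pytest.approx(2 * clade_pic(2, 4, 1.0))


class TestSharedSplitInfo:
    def test_identical_split_shares_self_information(self):
        s = split("12", "3456")
        assert shared_split_info(s, s) == pytest.approx(split_self_info(s))

    def test_incompatible_pair_shares_nothing(self):
        assert shared_split_info(split("12", "345"), split("13", "245")) == 0.0

    def test_nested_pair_matches_joint_enumeration(self):
        # trees containing both 12|3456 and 123|456, out of 105
        n_both = count_trees_with_splits(6, 0b000011, 0b000111)
        h1 = split_self_info(split("12", "3456"))
        h2 = split_self_info(split("123", "456"))
        h_joint = math.log2(105) - math.log2(n_both)
        got = shared_split_info(split("12", "3456"), split("123", "456"))
        assert got == pytest.approx(h1 + h2 - h_joint)

    @pytest.mark.parametrize("n", [6, 7])
    def test_all_compatible_pairs_match_enumeration(self, n):
        # exhaustive check of the joint-count formula on small leaf sets
        labels = [str(i) for i in range(n)]
        seen = set()
        for s in all_unrooted_split_sets(n):
            seen |= s
        masks = sorted(seen)

        def to_split(m):
            a = frozenset(labels[i] for i in range(n) if m >> i & 1)
            return Split(a, frozenset(labels) - a)

        total = len(all_unrooted_split_sets(n))
        for m1, m2 in combinations(masks[:12], 2):
            s1, s2 = to_split(m1), to_split(m2)
            n_both = count_trees_with_splits(n, m1, m2)
            got = shared_split_info(s1, s2)
            if n_both == 0:
                assert got == 0.0
            else:
                expected = (split_self_info(s1) + split_self_info(s2)
                            - (math.log2(total) - math.log2(n_both)))
                assert got == pytest.approx(expected)

    def test_symmetry_and_bounds(self):
        s1, s2 = split("12", "34567"), split("123", "4567")
        assert shared_split_info(s1, s2) == shared_split_info(s2, s1)
        assert shared_split_info(s1, s2) <= min(split_self_info(s1),
                                                split_self_info(s2)) + 1e-12


class TestTreeSignal:
    def test_identical_trees_are_pure_signal(self):
        t = random_binary_tree(list("ABCDEFGH"), 3)
        sn = tree_signal(t, t)
        assert sn.noise_bits == pytest.approx(0.0, abs=1e-9)
        assert sn.signal_bits == pytest.approx(sn.total_bits)

    def test_star_consensus_has_zero_accuracy(self):
        star = Tree.from_newick("(A,B,C,D,E);")
        ref = random_binary_tree(list("ABCDE"), 4)
        sn = tree_signal(star, ref)
        assert sn.signal_bits == 0.0 and sn.accuracy_bits == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_assignment_matches_bruteforce_matching(self, seed):
        cons = random_binary_tree(list("ABCDEFGHI"), seed)
        ref = random_binary_tree(list("ABCDEFGHI"), seed + 100)
        cs = sorted(cons.splits(), key=repr)
        rs = sorted(ref.splits(), key=repr)
        w = [[shared_split_info(c, r) for r in rs] for c in cs]
        sn = tree_signal(cons, ref)
        assert sn.signal_bits == pytest.approx(best_matching_bruteforce(w))

    def test_too_few_shared_leaves_rejected(self):
        t1 = Tree.from_newick("((A,B),(C,X));")
        t2 = Tree.from_newick("((A,B),(Y,Z));")
        with pytest.raises(ValueError):
            tree_signal(t1, t2)
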