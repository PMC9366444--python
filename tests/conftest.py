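import pytest

from roguefinder import Tree, figure2_fixture, random_binary_tree


@pytest.fixture
def fig2a_trees():
    """Five 5-leaf trees: rogue X on each edge of ((1,2),(3,4))."""
    return figure2_fixture("a")


@pytest.fixture
def quartet_tree():
    return Tree.from_newick("((1,2),(3,4));")


@pytest.fixture
def random_tree_factory():
    def make(n, seed, prefix="t"):
        return random_binary_tree([f"{prefix}{i:02d}" for i in range(n)], seed)
    return make
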