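import numpy as np
import pytest

from treeplace.treemodel import read_newick
from treeplace.simulate import _random_tree


@pytest.fixture
def four_tip_tree():
    """((A,B),(C,D)) with unit branch lengths."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def eight_tip_tree():
    return read_newick("(((A,B),(C,D)),((E,F),(G,H)));")


def branch_by_clade(tree, names):
    """Branch id whose clade is exactly the given leaf set."""
    target = set(names)
    for b in tree.branches:
        if tree.clade_leaves(b) == target:
            return b
    raise AssertionError(f"no branch with clade {target}")


def random_tree(seed, n_leaves):
    rng = np.random.default_rng(seed)
    return read_newick(_random_tree(rng, n_leaves))


def random_genotypes(rng, tree, p_missing=0.2):
    out = {}
    for leaf in tree.leaf_names:
        u = rng.random()
        if u < p_missing:
            out[leaf] = -1
        elif u < p_missing + (1 - p_missing) / 2:
            out[leaf] = 0
        else:
            out[leaf] = 1
    return out
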