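import random

import pytest

import mrsupertree as m

# worked example: supertree (a) and input tree (b), given by their split sets
# {AB|CDEFGH, ABC|DEFGH, ABCD|EFGH, FGH|ABCDE, GH|ABCDEF} and {DF|CGH, GH|CDF}
FIG_SUPERTREE_NEWICK = "(((A,B),C),(D,(E,(F,(G,H)))));"
FIG_INPUT_NEWICK = "((D,F),(C,(G,H)));"


@pytest.fixture
def fig_pair():
    sup = m.parse_newick(FIG_SUPERTREE_NEWICK)
    g = m.parse_newick(FIG_INPUT_NEWICK, index=sup.index)
    return sup, g


@pytest.fixture
def split_of():
    """Split constructor from label strings: split_of(tree, "GH")."""

    def build(tree, side):
        return m.Split(tree.index.mask_of(list(side)), tree.taxa_mask, tree.index)

    return build


def random_index(n, prefix="x"):
    return m.TaxonIndex(["%s%02d" % (prefix, i) for i in range(n)])


def random_pair(rng, n_super, n_input_min=4, n_input_max=None):
    """Random bifurcating (supertree, input tree) pair on overlapping taxa."""
    idx = random_index(n_super)
    S = m.random_bifurcating_tree(idx, idx.full_mask, rng)
    hi = min(n_input_max, n_super) if n_input_max is not None else n_super
    k = rng.randint(n_input_min, hi)
    sub = rng.sample(range(n_super), k)
    G = m.random_bifurcating_tree(idx, sum(1 << i for i in sub), rng)
    return S, G


def random_instance(rng, n, k_trees, min_taxa=4, perturb=0.0):
    """k random input trees whose taxa cover an n-taxon union."""
    idx = random_index(n)
    while True:
        inputs = []
        union = 0
        for _ in range(k_trees):
            sub = rng.sample(range(n), rng.randint(min_taxa, n))
            mask = sum(1 << i for i in sub)
            G = m.random_bifurcating_tree(idx, mask, rng)
            if perturb > 0:
                G = m.nni_perturb(G, perturb, rng)
            inputs.append(G)
            union |= mask
        if union == idx.full_mask:
            return idx, inputs


def split_labels(tree):
    """Set of 'ABC|DEF'-style strings (lexicographically smaller side first)."""
    out = set()
    for s in tree.splits():
        a, b = ("".join(x) for x in s.sides())
        out.add("|".join(sorted([a, b])))
    return out
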