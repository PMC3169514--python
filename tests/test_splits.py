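import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mrsupertree as m
from mrsupertree.oracles import enumerate_bifurcating_trees

from conftest import random_index, split_labels


class TestParseNewick:
    def test_example_input_tree(self, fig_pair):
        _, g = fig_pair
        assert split_labels(g) == {"CGH|DF", "CDF|GH"}

    def test_star_has_no_inner_splits(self):
        t = m.parse_newick("(A,B,C);")
        assert t.n_taxa == 3
        assert t.inner_splits == frozenset()

    def test_root_as_taxon(self):
        t = m.parse_newick("((A,B),(C,D));", treat_root_as_taxon=True, root_label="R")
        assert t.n_taxa == 5
        assert "AB|CDR" in split_labels(t)

    def test_duplicate_labels_error(self):
        with pytest.raises(m.NewickError):
            m.parse_newick("((A,B),(A,C));")

    def test_too_few_taxa_error(self):
        with pytest.raises(m.NewickError):
            m.parse_newick("(A,B);")

    def test_branch_lengths_and_labels_ignored(self):
        t1 = m.parse_newick("((A:1,B:2)x:0.5,(C:1,D:1)y:2);")
        t2 = m.parse_newick("((A,B),(C,D));", index=t1.index)
        assert t1 == t2

    def test_multifurcation_allowed(self):
        t = m.parse_newick("((A,B),C,D,E);")
        assert t.multifurcation_count == 1
        assert len(t.inner_splits) == 1

    def test_read_trees_drops_uninformative(self):
        with pytest.warns(UserWarning):
            trees = m.read_trees("((A,B),(C,D));\n\n(A,B,C);\n")
        assert len(trees) == 1


class TestWriteNewick:
    def test_roundtrip_example(self, fig_pair):
        sup, g = fig_pair
        for t in (sup, g):
            back = m.parse_newick(m.write_newick(t), index=t.index)
            assert back == t

    def test_star_four_taxa(self):
        t = m.parse_newick("(A,B,C,D);")
        assert m.parse_newick(m.write_newick(t), index=t.index) == t

    def test_split_label_emitted(self, fig_pair, split_of):
        _, g = fig_pair
        s = split_of(g, "GH")
        text = m.write_newick(g, labels={s: "7/5"})
        assert "7/5" in text
        assert m.parse_newick(text, index=g.index) == g

    def test_roundtrip_random(self):
        rng = random.Random(1)
        for _ in range(500):
            n = rng.randint(4, 64)
            idx = random_index(n)
            t = m.random_bifurcating_tree(idx, idx.full_mask, rng)
            assert m.parse_newick(m.write_newick(t), index=idx) == t

    def test_quoted_labels(self):
        idx = m.TaxonIndex(["a b", "c(d", "e:f", "plain"])
        rng = random.Random(0)
        t = m.random_bifurcating_tree(idx, idx.full_mask, rng)
        assert m.parse_newick(m.write_newick(t), index=idx) == t


class TestRestriction:
    def test_restrict_split_examples(self, fig_pair, split_of):
        sup, g = fig_pair
        sub = sup.index.mask_of(list("CDFGH"))
        r = m.restrict_split(split_of(sup, "ABCD"), sub)
        assert set(sup.index.labels_of(r.mask)) in ({"C", "D"}, {"F", "G", "H"})
        assert m.restrict_split(split_of(sup, "AB"), sub) is None
        r = m.restrict_split(split_of(sup, "GH"), sub)
        sides = [set(sup.index.labels_of(r.mask)), set(sup.index.labels_of(r.other_side))]
        assert {"G", "H"} in sides and {"C", "D", "F"} in sides

    def test_restrict_tree_example(self, fig_pair):
        sup, _ = fig_pair
        pruned = m.restrict_tree(sup, list("CDFGH"))
        assert split_labels(pruned) == {"CD|FGH", "CDF|GH"}

    def test_restrict_identity(self, fig_pair):
        sup, _ = fig_pair
        assert m.restrict_tree(sup, sup.taxa_mask) == sup

    def test_restriction_stays_bifurcating(self):
        rng = random.Random(2)
        for _ in range(50):
            idx = random_index(8)
            t = m.random_bifurcating_tree(idx, idx.full_mask, rng)
            sub = sum(1 << i for i in rng.sample(range(8), 5))
            r = m.restrict_tree(t, sub)
            assert len(r.inner_splits) <= 2
            assert r.is_bifurcating

    def test_restriction_commutes(self):
        rng = random.Random(3)
        for _ in range(100):
            idx = random_index(12)
            t = m.random_bifurcating_tree(idx, idx.full_mask, rng)
            a = sum(1 << i for i in rng.sample(range(12), 8))
            bbits = [i for i in range(12) if a & (1 << i)]
            b = sum(1 << i for i in rng.sample(bbits, 5))
            assert m.restrict_tree(m.restrict_tree(t, a), b) == m.restrict_tree(t, b)

    def test_too_few_shared_taxa(self, fig_pair):
        sup, _ = fig_pair
        with pytest.raises(ValueError):
            m.restrict_tree(sup, list("AB"))


class TestCompatibility:
    def test_cross_set_incompatible(self, fig_pair, split_of):
        sup, g = fig_pair
        assert not m.are_compatible(split_of(g, "DF"), split_of(sup, "ABCD"))

    def test_terminal_always_compatible(self, fig_pair, split_of):
        sup, g = fig_pair
        for t in "ABCDEFGH":
            term = m.Split(sup.index.mask_of([t]), sup.taxa_mask, sup.index)
            for s in sup.splits() + g.splits():
                assert m.are_compatible(term, s)

    def test_subsplit_is_compatible(self, fig_pair, split_of):
        sup, g = fig_pair
        assert m.are_compatible(split_of(g, "GH"), split_of(sup, "GH"))

    def test_symmetry_and_reflexivity(self):
        rng = random.Random(4)
        idx = random_index(10)
        for _ in range(300):
            u1 = sum(1 << i for i in rng.sample(range(10), rng.randint(4, 10)))
            u2 = sum(1 << i for i in rng.sample(range(10), rng.randint(4, 10)))
            bits1 = [i for i in range(10) if u1 >> i & 1]
            bits2 = [i for i in range(10) if u2 >> i & 1]
            m1 = sum(1 << i for i in rng.sample(bits1, rng.randint(1, len(bits1) - 1)))
            m2 = sum(1 << i for i in rng.sample(bits2, rng.randint(1, len(bits2) - 1)))
            s1 = m.Split(m1, u1, idx)
            s2 = m.Split(m2, u2, idx)
            assert m.are_compatible(s1, s2) == m.are_compatible(s2, s1)
            assert m.are_compatible(s1, s1)


class TestSubsplit:
    def test_documented_examples(self):
        idx = m.TaxonIndex(list("ABCDEF"))
        full = idx.full_mask
        partial = m.Split(idx.mask_of("ABC"), idx.mask_of("ABCF"), idx)
        plenary = m.Split(idx.mask_of("ABC"), full, idx)
        assert m.is_subsplit(partial, plenary)

    def test_fig_examples(self, fig_pair, split_of):
        sup, g = fig_pair
        assert m.is_subsplit(split_of(g, "GH"), split_of(sup, "GH"))
        assert not m.is_subsplit(split_of(g, "DF"), split_of(sup, "ABCD"))

    def test_taxa_superset_error(self, fig_pair, split_of):
        sup, g = fig_pair
        with pytest.raises(ValueError):
            m.is_subsplit(split_of(sup, "AB"), split_of(g, "GH"))


class TestRFDistance:
    def test_pruned_example(self, fig_pair):
        sup, g = fig_pair
        pruned = m.restrict_tree(sup, g.taxa_mask)
        assert m.rf_distance(pruned, g) == 2

    def test_self_distance_zero(self, fig_pair):
        sup, _ = fig_pair
        assert m.rf_distance(sup, sup) == 0

    def test_upper_bound(self):
        rng = random.Random(5)
        for _ in range(100):
            n = rng.randint(4, 20)
            idx = random_index(n)
            t1 = m.random_bifurcating_tree(idx, idx.full_mask, rng)
            t2 = m.random_bifurcating_tree(idx, idx.full_mask, rng)
            d = m.rf_distance(t1, t2)
            assert d % 2 == 0
            assert 0 <= d <= 2 * n - 6

    def test_taxon_mismatch_error(self, fig_pair):
        sup, g = fig_pair
        with pytest.raises(ValueError):
            m.rf_distance(sup, g)

    def test_metric_on_all_six_taxon_trees(self):
        idx = random_index(6)
        trees = list(enumerate_bifurcating_trees(idx))
        assert len(trees) == 105
        k = len(trees)
        D = np.zeros((k, k), dtype=np.int16)
        for i in range(k):
            for j in range(i + 1, k):
                D[i, j] = D[j, i] = m.rf_distance(trees[i], trees[j])
        assert (np.diag(D) == 0).all()
        # identity of indiscernibles: distinct trees have positive distance
        assert (D[~np.eye(k, dtype=bool)] > 0).all()
        # triangle inequality over all ordered triples
        for mid in range(k):
            assert (D <= D[:, mid : mid + 1] + D[mid : mid + 1, :]).all()


class TestInvariants:
    def test_bifurcating_split_count(self):
        rng = random.Random(6)
        for n in (4, 7, 12, 30):
            idx = random_index(n)
            t = m.random_bifurcating_tree(idx, idx.full_mask, rng)
            assert len(t.inner_splits) == n - 3
            assert t.is_bifurcating

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=4, max_value=32), st.integers(min_value=0, max_value=10**6))
    def test_canonical_roundtrip_property(self, n, seed):
        rng = random.Random(seed)
        idx = random_index(n)
        t = m.random_bifurcating_tree(idx, idx.full_mask, rng)
        assert m.parse_newick(m.write_newick(t), index=idx) == t

    def test_taxon_index_validation(self):
        with pytest.raises(ValueError):
            m.TaxonIndex(["A", "A"])
        with pytest.raises(ValueError):
            m.TaxonIndex(["A", ""])
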