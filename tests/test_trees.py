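"""Tree inference against closed forms, brute-force oracles, and the
dendropy/scikit-bio reference implementations."""
import io

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_upgma_heights, random_additive_matrix
from phylopan import simulate, trees


def _df(m, labels):
    return pd.DataFrame(np.asarray(m, dtype=float), index=labels, columns=labels)


def _dendropy_rf(t1, t2):
    tns = dendropy.TaxonNamespace()
    buf1, buf2 = io.StringIO(), io.StringIO()
    t1.write(buf1, format="newick")
    t2.write(buf2, format="newick")
    d1 = dendropy.Tree.get(data=buf1.getvalue(), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=buf2.getvalue(), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestJcDistance:
    def test_identical_sequences_zero(self):
        d = trees.jc_distance_matrix({"A": "ACGTACGT", "B": "ACGTACGT"})
        assert d.loc["A", "B"] == 0.0

    def test_formula_value(self):
        # 15 mismatches over 400 sites: p = 0.0375 -> d ~ 0.03847
        a = "A" * 400
        b = "C" * 15 + "A" * 385
        d = trees.jc_distance_matrix({"A": a, "B": b})
        assert d.loc["A", "B"] == pytest.approx(-0.75 * np.log(1 - 0.05), rel=1e-12)
        assert d.loc["A", "B"] == pytest.approx(0.03846, abs=1e-4)

    def test_saturation_capped_with_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            d = trees.jc_distance_matrix({"A": "AAAA", "B": "CCCA"})
        assert d.loc["A", "B"] == trees.JC_SATURATION_CAP

    def test_gap_columns_excluded(self):
        d = trees.jc_distance_matrix({"A": "AC-T", "B": "ACTT"})
        assert d.loc["A", "B"] == 0.0

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError):
            trees.jc_distance_matrix({"A": "--AA", "B": "CC--"})


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        d = _df([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], list("ABCD"))
        t = trees.nj_tree(d)
        assert {tip.name: tip.length for tip in t.tips()} == {
            "A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0}
        internal = [n for n in t.non_tips(include_self=False)]
        assert len(internal) == 1
        assert internal[0].length == pytest.approx(4.0)
        assert {x.name for x in internal[0].tips()} in ({"A", "B"}, {"C", "D"})

    def test_three_taxa_three_point_formulas(self):
        d = _df([[0, 3, 5], [3, 0, 6], [5, 6, 0]], list("ABC"))
        t = trees.nj_tree(d)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["A"] == pytest.approx((3 + 5 - 6) / 2)
        assert lengths["B"] == pytest.approx((3 + 6 - 5) / 2)
        assert lengths["C"] == pytest.approx((5 + 6 - 3) / 2)

    @pytest.mark.parametrize("n,seed", [(5, 1), (8, 2), (10, 3)])
    def test_consistency_on_additive_matrices(self, n, seed):
        gen, d = random_additive_matrix(n, seed)
        t = trees.nj_tree(d)
        assert trees.rf_distance(t, gen) == 0
        # and recovered patristic distances equal the input (additivity)
        rec = trees.patristic_matrix(t).loc[d.index, d.columns]
        assert np.allclose(rec.to_numpy(), d.to_numpy(), atol=1e-8)

    def test_matches_scikit_bio_topology(self):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix
        rng = np.random.default_rng(9)
        labels = [f"T{i}" for i in range(6)]
        m = rng.uniform(0.2, 1.0, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ours = trees.nj_tree(_df(m, labels))
        theirs = skbio_nj(DistanceMatrix(m, labels))
        assert trees.rf_distance(ours, theirs) == 0

    def test_asymmetric_input_rejected(self):
        d = _df([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], list("ABC"))
        with pytest.raises(ValueError):
            trees.nj_tree(d)


class TestUpgma:
    def test_worked_example(self):
        d = _df([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], list("ABCD"))
        t = trees.upgma_tree(d)
        assert {tip.name: tip.length for tip in t.tips()} == {
            "A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0}
        for node in t.children:
            assert node.length == pytest.approx(1.0)  # root height 2

    def test_equal_distances_tie_break_deterministic(self):
        d = _df(np.ones((4, 4)) - np.eye(4), list("ABCD"))
        t1 = trees.upgma_tree(d)
        t2 = trees.upgma_tree(d)
        assert str(t1) == str(t2)
        # lowest-index pair merges first
        first = min((n for n in t1.non_tips(include_self=False)),
                    key=lambda n: len(list(n.tips())))
        assert {x.name for x in first.tips()} == {"A", "B"}

    def test_ultrametric_invariant(self, yule8):
        msa = simulate.evolve_alignment(yule8, 500, 1.0, seed=40)
        t = trees.upgma_tree(trees.jc_distance_matrix(msa))
        depths = {}
        for node in t.preorder(include_self=True):
            depths[id(node)] = (0.0 if node.parent is None
                                else depths[id(node.parent)] + (node.length or 0.0))
        tip_depths = [depths[id(tip)] for tip in t.tips()]
        assert np.allclose(tip_depths, tip_depths[0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 1.0, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"T{i}" for i in range(5)]
        t = trees.upgma_tree(_df(m, labels))
        heights, merges = brute_force_upgma_heights(m)
        # compare merge heights: root-to-node heights of internal nodes
        node_heights = []
        depths = {}
        for node in t.preorder(include_self=True):
            depths[id(node)] = (0.0 if node.parent is None
                                else depths[id(node.parent)] + (node.length or 0.0))
        total = max(depths[id(tip)] for tip in t.tips())
        for node in t.non_tips(include_self=True):
            node_heights.append(total - depths[id(node)])
        assert np.allclose(sorted(node_heights), sorted(heights), atol=1e-9)
        # and the merge clusters agree
        our_clusters = {frozenset(int(x.name[1:]) for x in n.tips())
                        for n in t.non_tips(include_self=True)}
        assert our_clusters == set(merges)


def _path(tree, tip):
    out = []
    node = tip
    while node.parent is not None:
        out.append(node)
        node = node.parent
    return out


class TestJaccard:
    def test_examples(self):
        pa = pd.DataFrame(
            [[1, 1, 1, 0], [0, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 1]],
            index=list("ABCD"), columns=["f1", "f2", "f3", "f4"]).astype(bool)
        d = trees.jaccard_distance_matrix(pa)
        assert d.loc["A", "B"] == pytest.approx(0.5)
        assert d.loc["A", "C"] == 0.0
        assert d.loc["A", "D"] == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.frozensets(st.integers(0, 8), max_size=8), min_size=3, max_size=6))
    def test_metric_axioms(self, sets):
        universe = sorted(set().union(*sets)) or [0]
        pa = pd.DataFrame(
            [[u in s for u in universe] for s in sets],
            index=[f"S{i}" for i in range(len(sets))], columns=universe)
        d = trees.jaccard_distance_matrix(pa).to_numpy()
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestBootstrap:
    def test_fully_congruent_columns_support_100(self):
        # every column supports the split {A,B} | {C,D}
        msa = {"A": "AAAA" * 10, "B": "AAAA" * 10,
               "C": "CCCC" * 10, "D": "CCCC" * 10}
        t = trees.bootstrap_support(msa, method="nj", n_reps=20, seed=1)
        supports = [n.support for n in t.non_tips(include_self=False)
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_rep_granularity(self, yule8):
        msa = simulate.evolve_alignment(yule8, 300, 1.0, seed=41)
        t = trees.bootstrap_support(msa, method="nj", n_reps=1, seed=2)
        for n in t.non_tips(include_self=False):
            if hasattr(n, "support"):
                assert n.support in (0.0, 100.0)

    def test_same_seed_identical_supports(self, small_pangenome):
        t1 = trees.bootstrap_support(small_pangenome.pa, method="upgma",
                                     n_reps=10, seed=3)
        t2 = trees.bootstrap_support(small_pangenome.pa, method="upgma",
                                     n_reps=10, seed=3)
        assert str(t1) == str(t2)


class TestScaledPatristic:
    def test_worked_example(self):
        t = trees.read_newick("((A:1,B:1):1,C:2);")
        d = trees.scaled_patristic(t)
        assert d.loc["A", "B"] == pytest.approx(0.5)
        assert d.loc["A", "C"] == pytest.approx(1.0)
        assert d.loc["B", "C"] == pytest.approx(1.0)

    def test_max_is_one_and_scale_invariant(self, yule8):
        d1 = trees.scaled_patristic(yule8)
        assert d1.to_numpy().max() == pytest.approx(1.0)
        doubled = yule8.copy()
        for node in doubled.traverse(include_self=False):
            node.length = (node.length or 0.0) * 3.7
        d2 = trees.scaled_patristic(doubled)
        assert np.allclose(d1.to_numpy(), d2.loc[d1.index, d1.columns].to_numpy())


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, yule8):
        assert trees.rf_distance(yule8, yule8.copy()) == 0

    def test_four_taxon_alternative_splits(self):
        t1 = trees.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = trees.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert trees.rf_distance(t1, t2) == 2

    def test_bound_and_dendropy_agreement(self):
        for seed in range(6):
            t1 = simulate.simulate_species_tree(8, seed=seed)
            t2 = simulate.simulate_species_tree(8, seed=seed + 100)
            rf = trees.rf_distance(t1, t2)
            assert 0 <= rf <= 2 * (8 - 3)
            assert rf == _dendropy_rf(t1, t2)

    def test_tip_mismatch_rejected(self):
        t1 = trees.read_newick("((A:1,B:1):1,C:1);")
        t2 = trees.read_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError):
            trees.rf_distance(t1, t2)


class TestRecoveryProperty:
    def test_nj_recovers_generating_topology_from_long_alignments(self):
        # consistency: at 10,000 sites on 8 taxa, RF = 0 in >= 9/10 seeds
        hits = 0
        for seed in range(10):
            t = simulate.simulate_species_tree(8, seed=seed, depth=0.1)
            msa = simulate.evolve_alignment(t, 10_000, 1.0, seed=seed + 500)
            est = trees.nj_tree(trees.jc_distance_matrix(msa))
            hits += trees.rf_distance(est, t) == 0
        assert hits >= 9
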