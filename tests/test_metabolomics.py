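"""Metabolite-table rules: replicate filter, ion-mode merge, missingness,
glog/autoscaling, ANOVA + BH FDR, score normalisation, Ward ordering."""
import numpy as np
import pandas as pd
import pytest

from phylopan import metabolomics as mb
from phylopan import simulate


def _table(rows):
    return pd.DataFrame(
        rows, columns=["strain", "replicate", "ion_mode", "metabolite",
                       "abundance", "is_control"])


@pytest.fixture()
def toy_table():
    """Two strains, one metabolite detected 3/5 (kept) and one 2/5 (dropped),
    with pos/neg sums 40/90 for the kept strain A metabolite."""
    rows = []
    # media controls: tiny abundances, threshold = mean + 3sd
    for mode in ("pos", "neg"):
        for met in ("m_keep", "m_drop"):
            for rep in range(1, 6):
                rows.append(("media_control", rep, mode, met, 1.0, True))
    # m_keep in strain A: detected in replicates 1-3, pos sums 40, neg sums 90
    for rep, ab in zip(range(1, 4), (10.0, 10.0, 20.0)):
        rows.append(("A", rep, "pos", "m_keep", ab, False))
    for rep, ab in zip(range(1, 4), (30.0, 30.0, 30.0)):
        rows.append(("A", rep, "neg", "m_keep", ab, False))
    # m_drop in strain A: only 2 replicates above control
    for rep in (1, 2):
        rows.append(("A", rep, "pos", "m_drop", 50.0, False))
    # strain B: m_keep detected in all 5 replicates (one mode)
    for rep in range(1, 6):
        rows.append(("B", rep, "pos", "m_keep", 8.0, False))
    return _table(rows)


class TestBuildTraitMatrix:
    def test_replicate_filter_and_ion_mode_max(self, toy_table):
        m = mb.build_trait_matrix(toy_table, min_replicates=3, total_replicates=5)
        assert m.stage == "raw"
        # kept: 3 of 5 replicates; value = max(pos sum 40, neg sum 90) = 90
        assert m.values.loc["A", "m_keep"] == pytest.approx(90.0)
        # dropped: 2 of 5 replicates -> missing
        assert np.isnan(m.values.loc["A", "m_drop"])
        assert m.values.loc["B", "m_keep"] == pytest.approx(40.0)

    def test_detection_is_relative_to_controls(self):
        # abundances below mean(control)+3sd(control) never count as detected
        rows = [("media_control", r, "pos", "m", 100.0, True) for r in range(1, 6)]
        rows += [("A", r, "pos", "m", 50.0, False) for r in range(1, 6)]
        m = mb.build_trait_matrix(_table(rows), 3, 5)
        assert np.isnan(m.values.loc["A", "m"])

    def test_min_exceeding_total_rejected(self, toy_table):
        with pytest.raises(ValueError):
            mb.build_trait_matrix(toy_table, min_replicates=6, total_replicates=5)


class TestImpute:
    def test_column_removed_above_missing_limit(self):
        vals = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"],
                            index=[f"S{i}" for i in range(10)])
        vals.loc[vals.index[:6], "b"] = np.nan  # 60% missing
        out = mb.impute_and_filter_missing(mb.TraitMatrix(vals, "raw"), 0.5)
        assert list(out.values.columns) == ["a"]
        assert out.stage == "imputed"

    def test_half_minimum_imputation(self):
        vals = pd.DataFrame({"a": [2.0, 4.0, np.nan], "b": [8.0, np.nan, 6.0]},
                            index=list("xyz"))
        out = mb.impute_and_filter_missing(mb.TraitMatrix(vals, "raw"), 0.5)
        assert out.values.loc["z", "a"] == 1.0  # half of the matrix minimum 2
        assert out.values.loc["y", "b"] == 1.0

    def test_no_missing_is_identity(self):
        vals = pd.DataFrame({"a": [1.0, 2.0]}, index=["x", "y"])
        out = mb.impute_and_filter_missing(mb.TraitMatrix(vals, "raw"))
        pd.testing.assert_frame_equal(out.values, vals)

    def test_everything_dropped_is_error(self):
        vals = pd.DataFrame({"a": [np.nan, np.nan, 1.0]}, index=list("xyz"))
        with pytest.raises(ValueError):
            mb.impute_and_filter_missing(mb.TraitMatrix(vals, "raw"), 0.5)

    def test_stage_enforced(self):
        vals = pd.DataFrame({"a": [1.0, 2.0]}, index=["x", "y"])
        with pytest.raises(ValueError):
            mb.impute_and_filter_missing(mb.TraitMatrix(vals, "imputed"))


class TestGlogAutoscale:
    def test_glog_closed_form_values(self):
        assert mb.glog(0.0, 1.0) == pytest.approx(-1.0)  # log2(1/2)
        # lambda -> 0 recovers log2(x) for x > 0
        assert mb.glog(8.0, 1e-12) == pytest.approx(3.0, abs=1e-6)

    def test_autoscaled_columns_standardised(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.uniform(1, 100, (12, 4)),
                            index=[f"S{i}" for i in range(12)],
                            columns=list("abcd"))
        out = mb.glog_autoscale(mb.TraitMatrix(vals, "imputed"))
        assert out.stage == "autoscaled"
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_column_dropped(self):
        vals = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]},
                            index=list("xyz"))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = mb.glog_autoscale(mb.TraitMatrix(vals, "imputed"))
        assert list(out.values.columns) == ["a"]


class TestAnovaFdr:
    def test_bh_worked_example(self):
        q = mb.bh_qvalues([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_group_difference_detected_and_constant_skipped(self):
        rng = np.random.default_rng(4)
        rows = [f"g1_{i}" for i in range(5)] + [f"g2_{i}" for i in range(5)]
        groups = {r: r.split("_")[0] for r in rows}
        vals = pd.DataFrame({
            "separated": np.r_[rng.normal(0, 0.1, 5), rng.normal(5, 0.1, 5)],
            "null": rng.normal(0, 1, 10),
            "constant": np.ones(10),
        }, index=rows)
        with pytest.warns(UserWarning, match="skipped"):
            res = mb.anova_fdr(mb.TraitMatrix(vals, "raw"), groups, alpha=0.05)
        assert set(res["metabolite"]) == {"separated", "null"}
        sep = res.set_index("metabolite")
        assert bool(sep.loc["separated", "significant"])
        assert sep.loc["separated", "p"] < 1e-6

    def test_small_group_skipped(self):
        vals = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["a1", "a2", "b1"])
        groups = {"a1": "a", "a2": "a", "b1": "b"}
        with pytest.warns(UserWarning, match="skipped"):
            res = mb.anova_fdr(mb.TraitMatrix(vals, "raw"), groups)
        assert res.empty

    def test_fdr_controlled_under_null(self):
        # no group effect: average fraction of q < 0.05 discoveries <= 0.05
        rng = np.random.default_rng(5)
        rows = [f"g{g}_{i}" for g in range(4) for i in range(3)]
        groups = {r: r.split("_")[0] for r in rows}
        fractions = []
        for _ in range(300):
            vals = pd.DataFrame(rng.normal(size=(12, 20)), index=rows)
            vals.columns = [f"m{j}" for j in range(20)]
            res = mb.anova_fdr(mb.TraitMatrix(vals, "raw"), groups, alpha=0.05)
            fractions.append(res["significant"].mean())
        assert np.mean(fractions) <= 0.05 + 0.01

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(6)
        rows = [f"g{g}_{i}" for g in range(2) for i in range(5)]
        groups = {r: r.split("_")[0] for r in rows}
        power = []
        for effect in (0.0, 1.0, 3.0):
            hits = 0
            for _ in range(60):
                base = rng.normal(size=(10, 1))
                base[5:] += effect
                vals = pd.DataFrame(base, index=rows, columns=["m"])
                res = mb.anova_fdr(mb.TraitMatrix(vals, "raw"), groups)
                hits += int(res["significant"].iloc[0])
            power.append(hits / 60)
        assert power[0] < power[2]
        assert power[1] <= power[2]


class TestNormalizeScores:
    def test_worked_example_and_invariants(self):
        scores = pd.DataFrame({"m1": [2.0, 4.0, 8.0], "m2": [0.5, 1.0, 0.25]},
                              index=list("xyz"))
        out = mb.normalize_scores(scores)
        assert out.stage == "normalized_score"
        assert list(out.values["m1"]) == [0.25, 0.5, 1.0]
        assert out.values["m2"].max() == 1.0
        # ordering preserved (monotone transform)
        assert list(out.values["m1"].rank()) == list(scores["m1"].rank())

    def test_all_zero_column_dropped(self):
        scores = pd.DataFrame({"m1": [1.0, 2.0], "dead": [0.0, 0.0]}, index=["x", "y"])
        with pytest.warns(UserWarning):
            out = mb.normalize_scores(scores)
        assert list(out.values.columns) == ["m1"]


class TestWardOrder:
    def test_planted_blocks_stay_contiguous(self):
        rng = np.random.default_rng(7)
        block1 = rng.normal(0, 0.2, (5, 6))
        block2 = rng.normal(10, 0.2, (5, 6))
        vals = pd.DataFrame(np.vstack([block1, block2]),
                            index=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)])
        order = mb.ward_cluster_order(mb.TraitMatrix(vals, "autoscaled"))["row_order"]
        labels = ["A" if s.startswith("A") else "B" for s in order]
        # each planted block contiguous in the leaf order
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_duplicate_rows_merge_first_and_order_is_permutation(self):
        vals = pd.DataFrame([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]],
                            index=list("xyz"), columns=["a", "b"])
        out = mb.ward_cluster_order(mb.TraitMatrix(vals, "raw"))
        assert out["row_linkage"][0, 2] == 0.0  # first merge at distance 0
        assert sorted(out["row_order"]) == ["x", "y", "z"]


class TestPipelineComposition:
    def test_stages_compose_on_simulated_lcms(self):
        t = simulate.simulate_species_tree(6, seed=30)
        traits = simulate.simulate_traits(t, 4, 4, 1.0, seed=31)
        lcms = simulate.simulate_lcms(traits, missing_rate=0.2, seed=32)
        raw = mb.build_trait_matrix(lcms)
        imputed = mb.impute_and_filter_missing(raw)
        scaled = mb.glog_autoscale(imputed)
        assert scaled.values.shape[0] == 6
        assert not scaled.values.isna().any().any()
        # re-application at the wrong stage errors
        with pytest.raises(ValueError):
            mb.glog_autoscale(scaled)
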