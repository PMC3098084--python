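"""Grid enumeration, execution, variance decomposition and elimination."""

import numpy as np
import pandas as pd
import pytest

import maclust as mc
from maclust.grid import NORMALIZATIONS
from maclust.simulate import synthetic_result_table


class TestEnumeration:
    def test_grid_sizes(self):
        unsup = mc.enumerate_specs()
        assert len(unsup) == 2780
        assert len(mc.enumerate_specs(include_supervised=True)) == 2780 + 1280
        assert len(mc.enumerate_specs(reduced=True)) == 288

    def test_extra_std_sizes(self):
        # STD 300/500 valid everywhere (+220 each); STD 1500 excludes mclust (+200)
        specs = mc.enumerate_specs(extra_std_sizes=(300, 500, 1500))
        assert len(specs) == 2780 + 220 + 220 + 200

    def test_no_invalid_mclust_combinations(self):
        for spec in mc.enumerate_specs(include_supervised=True):
            if spec.clustering == "mclust":
                assert spec.selection.method != "NONE"
                assert spec.selection.n <= 500

    def test_unsupervised_selection_registry_has_13_members(self):
        labels = {s.selection.label for s in mc.enumerate_specs()}
        assert len(labels) == 13

    def test_validity_predicate(self):
        bad = mc.AnalysisSpec("no.norm", "ROW", False,
                              mc.SelectionSpec("STD", 1000), "mclust")
        good = mc.AnalysisSpec("no.norm", "ROW", False,
                               mc.SelectionSpec("PC", 15), "mclust")
        assert not bad.valid and good.valid

    def test_pairwise_comparison_counts(self):
        counts = mc.pairwise_comparison_counts({
            "selection": sorted({s.selection.label for s in mc.enumerate_specs()}),
            "clustering": mc.CLUSTERING_METHODS,
            "normalization": NORMALIZATIONS,
        })
        assert counts == {"selection": 78, "clustering": 55,
                          "normalization": 10}


@pytest.fixture(scope="module")
def mini_specs():
    return [
        mc.AnalysisSpec(norm, "ROW", std, mc.SelectionSpec("STD", 50), cl)
        for norm in ("no.norm", "norm.glob")
        for std in (False, True)
        for cl in ("hclust.eucl.ward", "kmeans")
    ]


class TestRunGrid:
    def test_one_record_per_dataset_spec(self, small_experiment, mini_specs):
        rt, prov = mc.run_grid({"D1": small_experiment}, mini_specs,
                               master_seed=3)
        assert len(rt) == len(mini_specs)
        assert (rt["error"] == "").all()
        assert rt["arand"].between(-1, 1).all()
        assert prov["seed"] == 3 and "config_sha256" in prov

    def test_rerun_and_uncached_are_bit_identical(self, small_experiment,
                                                  mini_specs):
        rt1, _ = mc.run_grid({"D1": small_experiment}, mini_specs, 3)
        rt2, _ = mc.run_grid({"D1": small_experiment}, mini_specs, 3)
        rt3, _ = mc.run_grid({"D1": small_experiment}, mini_specs, 3,
                             cache=False)
        pd.testing.assert_frame_equal(rt1, rt2)
        pd.testing.assert_frame_equal(rt1, rt3)

    def test_invalid_spec_recorded_not_raised(self, small_experiment):
        bad = mc.AnalysisSpec("no.norm", "ROW", False,
                              mc.SelectionSpec("NONE"), "mclust")
        rt, _ = mc.run_grid({"D1": small_experiment}, [bad], 0)
        assert len(rt) == 1
        assert np.isnan(rt["arand"].iloc[0])
        assert "invalid" in rt["error"].iloc[0]


class TestVarianceDecomposition:
    def test_planted_factor_dominates(self):
        rt = synthetic_result_table(
            {("selection", "STD 100"): 0.3}, noise_sd=0.02, seed=1)
        vd = mc.variance_decomposition(rt)
        explained = vd.loc[vd["term"] != "residual", "ss"].sum()
        sel_ss = float(vd.loc[vd["term"] == "selection", "ss"].iloc[0])
        assert sel_ss / explained >= 0.9
        assert bool(vd.loc[vd["term"] == "selection", "significant"].iloc[0])

    def test_percents_sum_to_100(self):
        rt = synthetic_result_table({("clustering", "som"): -0.1}, seed=2)
        vd = mc.variance_decomposition(rt)
        assert vd["percent"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (vd["ss"] >= 0).all()

    def test_pure_noise_rarely_significant(self):
        hits = 0
        for seed in range(30):
            rt = synthetic_result_table({}, noise_sd=0.05, seed=seed,
                                        n_datasets=2)
            vd = mc.variance_decomposition(rt)
            hits += int(vd["significant"].any())
        assert hits <= 1  # alpha=0.001 over ~21 terms keeps false hits rare

    def test_agrees_with_statsmodels_on_balanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rt = synthetic_result_table(
            {("selection", "PC 15"): 0.15, ("clustering", "kmeans"): 0.05},
            noise_sd=0.03, seed=3)
        vd = mc.variance_decomposition(rt, interactions=False)
        model = smf.ols(
            "arand ~ C(dataset) + C(normalization) + C(standardization)"
            " + C(imputation) + C(selection) + C(clustering)",
            data=rt).fit()
        oracle = sm.stats.anova_lm(model, typ=1)
        for term, oracle_name in [("dataset", "C(dataset)"),
                                  ("selection", "C(selection)"),
                                  ("clustering", "C(clustering)")]:
            ours = float(vd.loc[vd["term"] == term, "ss"].iloc[0])
            assert ours == pytest.approx(oracle.loc[oracle_name, "sum_sq"],
                                         rel=1e-8)

    def test_mclust_missing_cells_handled(self):
        rt = synthetic_result_table({("clustering", "mclust"): 0.1},
                                    clusts=("kmeans", "mclust"),
                                    sels=("STD 100", "STD 1000", "NONE"),
                                    seed=4)
        # structurally missing cells: mclust never runs with NONE/STD 1000
        rt = rt[~((rt["clustering"] == "mclust")
                  & rt["selection"].isin(["NONE", "STD 1000"]))]
        vd = mc.variance_decomposition(rt)
        assert vd["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_level_factor_dropped_with_note(self):
        rt = synthetic_result_table({}, n_datasets=1, seed=5)
        vd = mc.variance_decomposition(rt)
        assert "dataset" in vd.attrs["dropped_factors"]
        assert "dataset" not in set(vd["term"])


class TestEliminate:
    def test_planted_dominated_method_removed(self):
        rt = synthetic_result_table({("clustering", "som"): -0.2},
                                    noise_sd=0.02, seed=6)
        trace = mc.eliminate(rt)
        assert trace.steps["removed"].tolist() == ["som"]
        assert trace.steps["superior"].iloc[0] in ("kmeans",
                                                   "hclust.eucl.ward")
        assert "som" not in trace.survivors["clustering"]

    def test_one_dominated_method_per_subprocess_recovered(self):
        rt = synthetic_result_table(
            {("clustering", "som"): -0.25,
             ("normalization", "no.norm"): -0.2,
             ("selection", "PC 15"): -0.15},
            noise_sd=0.02, seed=7)
        trace = mc.eliminate(rt)
        assert set(trace.steps["removed"]) == {"som", "no.norm", "PC 15"}
        assert trace.survivors["normalization"] == ["norm.glob"]

    def test_exchangeable_methods_rarely_removed(self):
        removals = 0
        for seed in range(30):
            rt = synthetic_result_table({}, noise_sd=0.05, seed=seed,
                                        n_datasets=2)
            removals += int(len(mc.eliminate(rt).steps) > 0)
        assert removals <= 1

    def test_terminates_within_method_count_bound(self):
        rt = synthetic_result_table(
            {("clustering", "som"): -0.3, ("clustering", "kmeans"): -0.15},
            noise_sd=0.02, seed=8)
        trace = mc.eliminate(rt)
        n_methods = (rt["normalization"].nunique() + rt["selection"].nunique()
                     + rt["clustering"].nunique())
        assert len(trace.steps) <= n_methods - 3
        assert (trace.steps["p_value"] < 0.001).all()

    def test_pairs_without_common_settings_skipped(self):
        rt = synthetic_result_table({}, seed=9)
        # make 'som' exist only on dataset D0 rows with a disjoint selection
        rt = rt[~((rt["clustering"] == "som") & (rt["selection"] == "STD 100"))]
        rt = rt[~((rt["clustering"] != "som") & (rt["selection"] == "PC 15"))]
        trace = mc.eliminate(rt)
        assert any("som" in note for note in trace.skipped)


class TestSummarize:
    def test_mean_over_datasets_then_grouping(self):
        rt = synthetic_result_table({}, noise_sd=0.0, n_datasets=2, seed=10)
        rt.loc[rt["dataset"] == "D0", "arand"] = 0.2
        rt.loc[rt["dataset"] == "D1", "arand"] = 0.4
        out = mc.summarize(rt, by="clustering")
        assert np.allclose(out["mean"], 0.3)
        assert out["n"].sum() == len(rt) // 2  # one mean per spec combination

    def test_single_record(self):
        rt = synthetic_result_table({}, n_datasets=1, norms=("no.norm",),
                                    sels=("STD 100",), clusts=("kmeans",),
                                    seed=11).iloc[:1]
        out = mc.summarize(rt, by="selection")
        assert len(out) == 1
        assert out["mean"].iloc[0] == rt["arand"].iloc[0]

    def test_empty_errors(self):
        rt = synthetic_result_table({}, seed=12).iloc[:0]
        with pytest.raises(ValueError):
            mc.summarize(rt)
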