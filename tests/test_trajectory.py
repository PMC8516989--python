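"""ROI aggregation and longitudinal mixed models."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cortexgrowth.core import CohortDesign, LabelMask, QuantitativeMap
from cortexgrowth.simulate import CohortSimulationSpec, simulate_cohort, simulate_hierarchy
from cortexgrowth.trajectory import (LMMSpec, TrajectoryModel, bonferroni_threshold,
                                     build_roi_table, compare_lmm, fit_lmm,
                                     fit_per_area, fit_stream_lmm,
                                     pairwise_comparison_count, roi_distribution)
from conftest import ols_fit


class TestROIDistribution:
    def test_constant_map(self):
        qmap = QuantitativeMap(np.full((3, 3, 3), 2.0), metric="t1_s")
        mask = LabelMask([0, 5, 9], (3, 3, 3), "V1")
        s = roi_distribution(qmap, mask)
        assert (s.mean, s.sd, s.n) == (2.0, 0.0, 3)

    def test_known_values_and_histogram_conservation(self):
        vals = np.full((2, 2, 2), np.nan)
        vals.ravel()[[0, 1, 2]] = [1.0, 2.0, 3.0]
        qmap = QuantitativeMap(vals, metric="md_mm2_per_s")
        mask = LabelMask([0, 1, 2, 3], (2, 2, 2))  # index 3 is NaN: excluded
        s = roi_distribution(qmap, mask)
        assert s.mean == 2.0
        assert s.n == 3
        assert s.hist_counts.sum() == s.n

    def test_all_nan_mask_rejected(self):
        qmap = QuantitativeMap(np.full((2, 2, 2), np.nan), metric="t1_s")
        with pytest.raises(ValueError, match="finite"):
            roi_distribution(qmap, LabelMask([0, 1], (2, 2, 2)))


class TestBuildROITable:
    def test_three_timepoints_three_rows(self):
        qmaps = {("infant01", tp): QuantitativeMap(np.full((2, 2, 2), v), metric="t1_s")
                 for tp, v in zip(("newborn", "3mo", "6mo"), (2.0, 1.9, 1.8))}
        masks = {("V1", "left"): LabelMask([0, 1], (2, 2, 2), "V1")}
        ages = {("infant01", "newborn"): 10, ("infant01", "3mo"): 90,
                ("infant01", "6mo"): 180}
        table = build_roi_table(qmaps, masks, ages)
        assert len(table) == 3
        assert sorted(table["value"]) == [1.8, 1.9, 2.0]

    def test_mean_matches_roi_distribution(self):
        rng = np.random.default_rng(0)
        qmap = QuantitativeMap(rng.uniform(1.5, 2.5, (3, 3, 3)), metric="t1_s")
        mask = LabelMask(np.arange(10), (3, 3, 3), "V1")
        table = build_roi_table({("a", "newborn"): qmap},
                                {("V1", "left"): mask}, {("a", "newborn"): 20})
        assert table.loc[0, "value"] == roi_distribution(qmap, mask).mean


class TestFitLMM:
    def test_noiseless_line_recovered_exactly(self):
        spec = CohortSimulationSpec(tau=0.0, sigma=0.0, beta0=2.0,
                                    beta1=-0.0015, seed=1)
        table, _ = simulate_cohort(spec)
        res = fit_lmm(table)
        assert res.intercept == pytest.approx(2.0, abs=1e-8)
        assert res.slope == pytest.approx(-0.0015, abs=1e-10)
        vc = res.variance_components
        assert vc["var_intercept"] == pytest.approx(0.0, abs=1e-8)
        assert vc["var_residual"] == pytest.approx(0.0, abs=1e-8)

    def test_ols_oracle_balanced_tau_zero(self, balanced_cohort):
        """Balanced design, tau=0: REML and ML fixed effects equal OLS."""
        table, _ = balanced_cohort
        beta = ols_fit(table)
        for criterion in ("reml", "ml"):
            res = TrajectoryModel(table, LMMSpec(criterion=criterion)).fit()
            assert res.intercept == pytest.approx(beta[0], abs=1e-8)
            assert res.slope == pytest.approx(beta[1], abs=1e-8)

    def test_row_order_and_relabel_invariance(self, default_cohort):
        table, _ = default_cohort
        res = fit_lmm(table)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        relabeled = shuffled.assign(
            infant_id=shuffled["infant_id"].map(lambda s: "x" + s[::-1]))
        res2 = fit_lmm(relabeled)
        assert res2.intercept == pytest.approx(res.intercept, rel=1e-6)
        assert res2.slope == pytest.approx(res.slope, rel=1e-6)

    def test_single_infant_rejected(self, default_cohort):
        table, _ = default_cohort
        one = table[table["infant_id"] == "infant01"]
        with pytest.raises(ValueError):
            fit_lmm(one)

    def test_variance_components_nonnegative(self, default_cohort):
        table, _ = default_cohort
        vc = fit_lmm(table).variance_components
        assert all(v >= -1e-12 for k, v in vc.items() if k.startswith("var_"))


@pytest.fixture(scope="module")
def ml_fits(default_cohort):
    table, _ = default_cohort
    null = TrajectoryModel(table, LMMSpec(criterion="ml", random="infant")).fit()
    alt = TrajectoryModel(table, LMMSpec(criterion="ml", random="infant+slope")).fit()
    return null, alt


class TestModelComparison:
    def test_identical_models_lr_zero(self, ml_fits):
        null, _ = ml_fits
        mc = compare_lmm(null, null)
        assert mc.lr_stat == 0.0
        assert mc.p_value == 1.0

    def test_alt_loglik_at_least_null(self, ml_fits):
        null, alt = ml_fits
        assert alt.loglik >= null.loglik - 1e-8
        mc = compare_lmm(null, alt)
        assert mc.lr_stat >= 0.0
        assert mc.df_diff == 2  # slope variance + covariance

    def test_reml_fits_rejected(self, default_cohort):
        table, _ = default_cohort
        reml = fit_lmm(table)
        with pytest.raises(ValueError, match="ML"):
            compare_lmm(reml, reml)

    def test_power_against_large_slope_variance(self):
        """Strong per-infant slope heterogeneity is detected by the LRT."""
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 1000)
            table, _ = simulate_cohort(CohortSimulationSpec(
                tau=0.02, sigma=0.01, seed=seed))
            # inject per-infant slope deviations, SD comparable to the mean slope
            slope_dev = {inf: rng.normal(0, 8e-4)
                         for inf in table["infant_id"].unique()}
            table = table.assign(value=table["value"] + table["age_days"]
                                 * table["infant_id"].map(slope_dev))
            null = TrajectoryModel(table, LMMSpec(criterion="ml", random="infant")).fit()
            alt = TrajectoryModel(table, LMMSpec(criterion="ml",
                                                 random="infant+slope")).fit()
            detected += compare_lmm(null, alt).p_value < 0.05
        assert detected / n_seeds > 0.8


class TestPerArea:
    @pytest.mark.parametrize("k,expected", [(4, 6), (9, 36), (8, 28)])
    def test_pairwise_comparison_counts(self, k, expected):
        assert pairwise_comparison_count(k) == expected
        assert bonferroni_threshold(0.05, k) == pytest.approx(0.05 / expected)

    def test_missing_area_rejected(self, default_cohort):
        table, _ = default_cohort
        with pytest.raises(ValueError, match="V9"):
            fit_per_area(table, ["V1", "V9"])

    def test_per_area_estimates_close_to_truth(self):
        areas = ("V1d", "V2d", "V3d", "V3A")
        specs = [replace(CohortSimulationSpec(seed=31, tau=0.03, sigma=0.015),
                         area=a, beta0=2.0 + 0.05 * i, beta1=-0.0015 - 2e-4 * i)
                 for i, a in enumerate(areas)]
        table, _ = simulate_hierarchy(specs)
        fits = fit_per_area(table, areas)
        assert fits.attrs["n_comparisons"] == 6
        for i, a in enumerate(areas):
            assert fits.loc[a, "intercept"] == pytest.approx(2.0 + 0.05 * i, abs=0.05)
            assert fits.loc[a, "slope"] == pytest.approx(-0.0015 - 2e-4 * i, abs=2e-4)


class TestStreamLMM:
    def test_null_hemisphere_effect_small(self):
        """With no simulated hemisphere difference, its |t| stays small."""
        small = 0
        n_seeds = 10
        for seed in range(n_seeds):
            specs = [replace(CohortSimulationSpec(seed=40 + seed, tau=0.03,
                                                  sigma=0.02),
                             area=a, beta0=2.0 + 0.04 * i)
                     for i, a in enumerate(("V1d", "V2d", "V3d"))]
            table, _ = simulate_hierarchy(specs)
            res = fit_stream_lmm(table, factors=("area", "hemisphere"))
            t_hemi = res.fe_table.loc[
                res.fe_table.index.str.contains("hemisphere"), "t"].abs().max()
            small += t_hemi < 2.0
        assert small / n_seeds >= 0.9

    def test_null_stream_effect_with_area_gradient(self):
        """Cross-stream model: age and area matter, stream does not."""
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            specs = []
            for areas in (("V1d", "V2d", "V3d"), ("V1v", "V2v", "V3v")):
                specs += [replace(CohortSimulationSpec(seed=60 + seed, tau=0.03,
                                                       sigma=0.02),
                                  area=a, beta0=2.0 + 0.06 * i,
                                  beta1=-0.0015 - 1e-4 * i)
                          for i, a in enumerate(areas)]
            table, _ = simulate_hierarchy(specs)
            res = fit_stream_lmm(table, factors=("area_rank", "stream"))
            fe = res.fe_table
            age_sig = fe.loc["age_days", "p"] < 0.05
            stream_rows = fe.index.str.contains("stream")
            stream_null = fe.loc[stream_rows, "p"].min() > 0.05
            hits += age_sig and stream_null
        assert hits / n_seeds > 0.5

    def test_single_area_subset_reduces_to_fit_lmm(self, default_cohort):
        table, _ = default_cohort
        direct = fit_lmm(table)
        via_stream = fit_stream_lmm(table, factors=(), random="infant")
        assert via_stream.intercept == pytest.approx(direct.intercept, rel=1e-9)
        assert via_stream.slope == pytest.approx(direct.slope, rel=1e-9)

    def test_summary_mentions_key_quantities(self, default_cohort):
        table, _ = default_cohort
        s = fit_lmm(table).summary()
        assert "Fixed effects" in s and "age_days" in s and "Variance" in s
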