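"""Psychometric fitting, JND/PSE extraction, bias regression, outlier
filtering, common-slope localization regressions and bootstrap intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avrecal.experiment_simulator import TRIAL_COLUMNS
from avrecal.psychophysics_analysis import (
    BiasEstimate,
    bootstrap_ci,
    filter_outliers,
    fit_localization_regressions,
    fit_psychometric,
    jnd_from_fit,
    pse_from_fit,
    recalibration_effect,
    regress_pses,
)


def synth_2afc(sd, lapse, center=0.0, n=400, seed=0, span=12.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(center - span, center + span, n)
    p = 0.5 * lapse + (1 - lapse) * stats.norm.cdf((x - center) / sd)
    return x, (rng.random(n) < p).astype(float)


class TestPsychometricFit:
    def test_recovers_generating_sd_within_bootstrap_ci(self):
        x, r = synth_2afc(3.0, 0.02, n=176, seed=1)
        fit = fit_psychometric(x, r)
        rng = np.random.default_rng(2)
        boots = []
        for _ in range(120):
            idx = rng.integers(0, len(x), len(x))
            boots.append(fit_psychometric(x[idx], r[idx]).sd)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= 3.0 <= hi
        assert fit.converged

    def test_all_identical_responses_flagged(self):
        with pytest.warns(RuntimeWarning):
            fit = fit_psychometric(np.linspace(-5, 5, 50), np.ones(50))
        assert not fit.converged

    def test_lapse_never_exceeds_cap(self):
        # generating lapse above the 6% cap: the estimate must stay at <= 6%
        x, r = synth_2afc(2.0, 0.20, n=600, seed=3)
        fit = fit_psychometric(x, r)
        assert fit.lapse <= 0.06 + 1e-12

    def test_free_center_recovery(self):
        x, r = synth_2afc(2.5, 0.02, center=4.2, n=500, seed=4)
        fit = fit_psychometric(x, r, center_fixed=False, bin_width=3.0)
        assert pse_from_fit(fit) == pytest.approx(4.2, abs=0.6)

    def test_adjusted_r2_reasonable_on_clean_data(self):
        x, r = synth_2afc(3.0, 0.02, n=800, seed=5)
        fit = fit_psychometric(x, r)
        assert fit.adjusted_r2 > 0.8


class TestJndPse:
    def test_jnd_unit_sd(self):
        fit = fit_psychometric(*synth_2afc(1.0, 0.0, n=2000, seed=6))
        assert jnd_from_fit(fit) == pytest.approx(stats.norm.ppf(0.75) * fit.sd)

    def test_jnd_scale_equivariance(self):
        f1 = fit_psychometric(*synth_2afc(2.0, 0.0, n=4000, seed=7))
        f2 = fit_psychometric(*synth_2afc(4.0, 0.0, n=4000, seed=7, span=24))
        assert jnd_from_fit(f2) / jnd_from_fit(f1) == pytest.approx(2.0,
                                                                    rel=0.2)

    def test_pse_is_unscaled_center(self):
        fit = fit_psychometric(*synth_2afc(2.0, 0.05, center=1.5, n=1000,
                                           seed=8),
                               center_fixed=False)
        assert pse_from_fit(fit) == fit.center


class TestBiasRegression:
    LOCS = (-7.5, -2.5, 2.5, 7.5)

    def test_known_line(self):
        est = regress_pses([-3.5, -0.5, 2.5, 5.5], self.LOCS)
        assert est.slope == pytest.approx(0.6)
        assert est.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(est.aligned_visual_locations,
                                   [-3.5, -0.5, 2.5, 5.5])

    def test_identity_case(self):
        est = regress_pses(self.LOCS, self.LOCS)
        assert est.slope == pytest.approx(1.0)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)


def _loc_frame(rows):
    df = pd.DataFrame(rows)
    for c in TRIAL_COLUMNS:
        if c not in df:
            df[c] = np.nan
    df["task"] = "localization"
    return df


class TestOutlierFiltering:
    def test_single_far_outlier_removed(self):
        rng = np.random.default_rng(0)
        rows = [{"s_V": 0.0, "response": v, "modality": "V", "phase": "pre",
                 "reliability": 1, "direction": "V_left"}
                for v in rng.normal(0, 1, 500)]
        rows.append({"s_V": 0.0, "response": 5.5, "modality": "V",
                     "phase": "pre", "reliability": 1, "direction": "V_left"})
        df = _loc_frame(rows)
        df["task"] = "pointing"
        kept, report = filter_outliers(df, "pointing")
        assert len(kept) <= len(df) - 1
        assert not np.isclose(kept.response, 5.5).any()

    def test_identical_responses_are_noop_with_warning(self):
        df = _loc_frame([{"s_V": 0.0, "response": 1.0, "modality": "V",
                          "phase": "pre", "reliability": 1,
                          "direction": "V_left"}] * 20)
        df["task"] = "pointing"
        with pytest.warns(RuntimeWarning):
            kept, report = filter_outliers(df, "pointing")
        assert len(kept) == 20

    def test_clean_gaussian_exclusion_fraction(self):
        rng = np.random.default_rng(1)
        rows = [{"s_V": 0.0, "response": v, "modality": "V", "phase": "pre",
                 "reliability": 1, "direction": "V_left"}
                for v in rng.normal(0, 2, 30000)]
        df = _loc_frame(rows)
        df["task"] = "pointing"
        kept, report = filter_outliers(df, "pointing")
        frac = 1 - len(kept) / len(df)
        # Gaussian mass beyond 3 SD is about 0.27%
        assert 0.0005 < frac < 0.006

    def test_localization_policy_groups(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in (1, 2, 3):
            for d in ("V_left", "V_right"):
                for phase in ("pre", "post"):
                    for mod in ("A", "V"):
                        for loc in (-7.5, 7.5):
                            for v in rng.normal(loc, 2 + i, 12):
                                rows.append({
                                    "s_A": loc if mod == "A" else np.nan,
                                    "s_V": loc if mod == "V" else np.nan,
                                    "response": v, "modality": mod,
                                    "phase": phase, "reliability": i,
                                    "direction": d,
                                })
        df = _loc_frame(rows)
        kept, report = filter_outliers(df, "localization")
        assert set(report) == {"A", "V1", "V2", "V3"}
        assert all(0.0 <= v < 0.05 for v in report.values())

    def test_unknown_policy_raises(self):
        with pytest.raises(ValueError):
            filter_outliers(_loc_frame([]), "weird")


def _balanced_localization(shift_by_condition, slope=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    locs = (-7.5, -2.5, 2.5, 7.5)
    for i in (1, 2, 3):
        for d in ("V_left", "V_right"):
            for phase in ("pre", "post"):
                shift = shift_by_condition.get((i, d), 0.0) if phase == "post" else 0.0
                for loc in locs:
                    for _ in range(6):
                        rows.append({
                            "s_A": loc, "modality": "A", "phase": phase,
                            "reliability": i, "direction": d,
                            "response": slope * loc + shift
                            + rng.normal(0, noise) if noise else slope * loc
                            + shift,
                        })
    return _loc_frame(rows)


class TestLocalizationRegressions:
    def test_identical_pre_post_gives_equal_intercepts(self):
        df = _balanced_localization({})
        regs = fit_localization_regressions(df, "A")
        vals = list(regs["intercepts"].values())
        np.testing.assert_allclose(vals, vals[0], atol=1e-9)
        assert regs["slope"] == pytest.approx(1.0)

    def test_uniform_shift_recovered(self):
        df = _balanced_localization({(2, "V_right"): 2.0}, noise=0.3, seed=3)
        regs = fit_localization_regressions(df, "A")
        diff = regs["intercepts"][(2, "V_right")] - regs["intercepts"]["pre"]
        assert diff == pytest.approx(2.0, abs=0.3)

    def test_shared_slope_is_mean_of_group_slopes_on_balanced_design(self):
        # two groups with different slopes, same x design: the joint estimate
        # equals the average of the per-group OLS slopes
        rng = np.random.default_rng(4)
        rows = []
        for phase, slope in (("pre", 0.8), ("post", 1.2)):
            for loc in (-7.5, -2.5, 2.5, 7.5):
                for _ in range(10):
                    rows.append({"s_A": loc, "modality": "A", "phase": phase,
                                 "reliability": 1, "direction": "V_left",
                                 "response": slope * loc + rng.normal(0, .1)})
        df = _loc_frame(rows)
        regs = fit_localization_regressions(df, "A")
        assert regs["slope"] == pytest.approx(1.0, abs=0.05)


class TestRecalibrationEffect:
    def regs(self, pre, post, cond):
        return {"slope": 1.0, "intercepts": {"pre": pre, cond: post}}

    def test_zero_shift(self):
        eff = recalibration_effect(self.regs(0.3, 0.3, (1, "V_right")),
                                   (1, "V_right"), "A")
        assert eff.effect == 0.0

    def test_v_right_auditory_rightward_is_positive(self):
        eff = recalibration_effect(self.regs(0.0, 1.5, (1, "V_right")),
                                   (1, "V_right"), "A")
        assert eff.effect == pytest.approx(1.5)

    def test_mirrored_direction_same_positive_effect(self):
        right = recalibration_effect(self.regs(0.0, 1.5, (1, "V_right")),
                                     (1, "V_right"), "A")
        left = recalibration_effect(self.regs(0.0, -1.5, (1, "V_left")),
                                    (1, "V_left"), "A")
        assert right.effect == pytest.approx(left.effect)

    def test_visual_sign_is_opposite(self):
        eff = recalibration_effect(self.regs(0.0, -0.8, (1, "V_right")),
                                   (1, "V_right"), "V")
        assert eff.effect == pytest.approx(0.8)


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        df = pd.DataFrame({"x": np.arange(50.0)})
        lo, hi = bootstrap_ci(lambda d: 7.0, df, n_boot=50, seed=0)
        assert (lo, hi) == (7.0, 7.0)

    def test_seed_reproducibility(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(size=200)})
        f = lambda d: d["x"].mean()
        assert bootstrap_ci(f, df, 100, seed=5) == bootstrap_ci(f, df, 100,
                                                                seed=5)

    def test_mean_ci_coverage(self):
        rng = np.random.default_rng(6)
        cover = 0
        reps = 120
        for k in range(reps):
            df = pd.DataFrame({"x": rng.normal(0, 1, 100)})
            lo, hi = bootstrap_ci(lambda d: d["x"].mean(), df, n_boot=200,
                                  seed=k)
            cover += lo <= 0.0 <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.05)

    def test_stratified_resampling_respects_groups(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)],
                           "g": ["a"] * 50 + ["b"] * 50})
        lo, hi = bootstrap_ci(lambda d: d["x"].mean(), df, n_boot=100,
                              seed=0, strata="g")
        assert (lo, hi) == (0.5, 0.5)
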