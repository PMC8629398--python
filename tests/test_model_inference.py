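"""Staged model fitting: closed-form response probabilities against
Monte-Carlo oracles, stage log-likelihoods against brute-force recomputation,
the marginal post-recalibration likelihood, and AIC bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avrecal import model_inference as mi
from avrecal.experiment_simulator import (
    generate_full_study,
    run_pointing_practice,
    simulate_2ifc_response,
)
from avrecal.observer_core import ObserverParams
from avrecal.recalibration_dynamics import approximate_shift_distribution

from conftest import make_recal_design


@pytest.fixture(scope="module")
def small_dataset():
    return generate_full_study(
        ObserverParams(alpha_A=0.01, alpha_V=0.01), "CI", seed=31
    )


class TestParameterAccounting:
    def test_theta3_counts_per_model(self):
        counts = {m: mi.theta3_parameter_count(m)
                  for m in ("RB", "FR", "CI", "CI_tied")}
        assert counts == {"RB": 8, "FR": 9, "CI": 10, "CI_tied": 9}

    def test_stage1_identifies_only_scaled_auditory_sd(self, small_dataset):
        theta1 = mi.fit_theta1(small_dataset.trials)
        # stage 1 exposes the ratio sigma'_A / a_A, never sigma'_A itself
        assert not hasattr(theta1, "sigma_A_uni")
        p = small_dataset.params
        expected = p.sigma_A_uni / p.bias_slope
        assert theta1.k_A == pytest.approx(expected, rel=0.25)


class TestResponseProbabilities:
    def test_unimodal_midpoint_is_half_for_any_lapse(self):
        for lapse in (0.0, 0.03, 0.06):
            assert mi.p_right_unimodal(0.0, 0.0, 3.0, lapse) == pytest.approx(0.5)

    def test_unimodal_ceiling(self):
        assert mi.p_right_unimodal(1e3, 0.0, 2.0, 0.04) == pytest.approx(0.98)

    def test_unimodal_matches_2ifc_simulation(self):
        rng = np.random.default_rng(0)
        sigma, ds, n = 4.0, 3.0, 40000
        hits = sum(simulate_2ifc_response(ds, 0.0, sigma, 0.02, rng)
                   for _ in range(n))
        closed = mi.p_right_unimodal(ds, 0.0, np.sqrt(2) * sigma, 0.02)
        assert hits / n == pytest.approx(closed, abs=0.01)

    def test_bimodal_alignment_gives_half(self):
        # unbiased observer, physically aligned stimuli, flat prior
        p = mi.p_right_bimodal(2.5, 2.5, 1.0, 0.0, 4.5, 1.5, 0.03,
                               prior_sd=1e9)
        assert p == pytest.approx(0.5)

    def test_bimodal_pse_implied_by_bias(self):
        # at s_V = a_A s_A + b_A the shrunk means coincide for any SDs
        a, b, s_a = 1.2, -0.8, 5.0
        s_v = a * s_a + b
        for sig_a, sig_v in ((4.5, 1.5), (9.0, 0.5)):
            p = mi.p_right_bimodal(s_v, s_a, a, b, sig_a, sig_v, 0.0,
                                   prior_sd=1e9)
            assert p == pytest.approx(0.5, abs=1e-9)

    def test_bimodal_matches_estimate_comparison_simulation(self):
        rng = np.random.default_rng(1)
        a, b, sig_a, sig_v = 1.1, -0.6, 4.5, 1.5
        s_a, s_v, n = 2.5, 4.0, 40000
        hits = sum(
            simulate_2ifc_response(s_v, a * s_a + b, sig_v, 0.0, rng,
                                   sigma_standard=sig_a)
            for _ in range(n)
        )
        closed = mi.p_right_bimodal(s_v, s_a, a, b, sig_a, sig_v, 0.0)
        assert hits / n == pytest.approx(closed, abs=0.01)


class TestStageLikelihoods:
    def test_loglik_theta1_matches_bruteforce(self, small_dataset):
        theta1 = mi.fit_theta1(small_dataset.trials)
        ll = mi.loglik_theta1(small_dataset.trials, theta1)
        brute = 0.0
        for cond in ("A", "V1", "V2", "V3"):
            g = small_dataset.trials[
                (small_dataset.trials.task == "unimodal_discrimination")
                & (small_dataset.trials.condition == cond)
            ]
            for _, row in g.iterrows():
                p = float(mi.p_right_unimodal(row.test_location, 0.0,
                                              theta1.sd_psych[cond],
                                              theta1.lapses[cond]))
                brute += np.log(p if row.response == 1 else 1 - p)
        assert ll == pytest.approx(brute, rel=1e-9)
        # single trial at p = 0.5 contributes log 0.5
        assert mi.p_right_unimodal(0.0, 0.0, 3.0, 0.0) == 0.5

    def test_sigma_r_closed_form(self):
        df = pd.DataFrame({"s_V": [0.0] * 4, "response": [1.0, -1.0, 1.0, -1.0]})
        assert mi.estimate_sigma_r(df) == pytest.approx(1.0)
        df0 = pd.DataFrame({"s_V": [2.0, 3.0], "response": [2.0, 3.0]})
        assert mi.estimate_sigma_r(df0) == 0.0

    def test_sigma_r_recovery_at_study_size(self):
        p = ObserverParams(sigma_r=1.85)
        df = run_pointing_practice(p, 9)
        assert mi.estimate_sigma_r(df) == pytest.approx(1.85, abs=0.15)

    def test_pre_loglik_matches_bruteforce(self, small_dataset):
        theta1 = mi.fit_theta1(small_dataset.trials)
        stage3 = mi._extract_stage3(small_dataset)
        sigma_r = 1.85
        theta3 = {"a_A": 1.1, "b_A": -0.6, "lapse_AV": 0.03}
        ll = mi.loglik_theta3_pre(stage3, theta3, theta1, sigma_r)

        sigma_a = theta3["a_A"] * theta1.k_A
        p = mi.p_right_bimodal(stage3.bimodal_sV, stage3.bimodal_sA,
                               theta3["a_A"], theta3["b_A"], sigma_a,
                               theta1.sigma_V_uni[0], theta3["lapse_AV"])
        brute = float(np.sum(stage3.bimodal_r * np.log(p)
                             + (1 - stage3.bimodal_r) * np.log(1 - p)))
        f_a = sigma_a ** -2 / (sigma_a ** -2 + 100.0 ** -2)
        var_a = f_a ** 2 * sigma_a ** 2 + sigma_r ** 2
        for sess in stage3.sessions:
            s, r = sess.pre_A
            mu = f_a * (theta3["a_A"] * s + theta3["b_A"])
            brute += float(np.sum(stats.norm.logpdf(r, mu, np.sqrt(var_a))))
            sv = theta1.sigma_V_uni[sess.reliability_level - 1]
            f_v = sv ** -2 / (sv ** -2 + 100.0 ** -2)
            var_v = f_v ** 2 * sv ** 2 + sigma_r ** 2
            s, r = sess.pre_V
            brute += float(np.sum(stats.norm.logpdf(r, f_v * s,
                                                    np.sqrt(var_v))))
        assert ll == pytest.approx(brute, rel=1e-9)

    def test_pre_loglik_peaks_near_true_bias(self, small_dataset):
        theta1 = mi.fit_theta1(small_dataset.trials)
        stage3 = mi._extract_stage3(small_dataset)
        base = {"a_A": 1.1, "b_A": -0.6, "lapse_AV": 0.03}
        ll_true = mi.loglik_theta3_pre(stage3, base, theta1, 1.85)
        for off in (1.5, 3.0, -3.0):
            ll_off = mi.loglik_theta3_pre(
                stage3, {**base, "b_A": base["b_A"] + off}, theta1, 1.85
            )
            assert ll_off < ll_true


class TestMarginalLikelihood:
    def _session_and_dist(self, small_dataset, model="CI"):
        stage3 = mi._extract_stage3(small_dataset)
        sess = stage3.sessions[0]
        dist = approximate_shift_distribution(
            model, small_dataset.params, sess.recal_design, 400, 2
        )
        theta1 = mi.fit_theta1(small_dataset.trials)
        return sess, dist, theta1

    def test_point_mass_equals_conditional(self, small_dataset):
        sess, dist, theta1 = self._session_and_dist(small_dataset)
        theta3 = {"a_A": 1.1, "b_A": -0.6, "sigma_AV_A": 6.0,
                  "sigma_AV_V1": 3.0, "sigma_AV_V2": 6.0, "sigma_AV_V3": 9.0,
                  "lapse_AV": 0.03}
        dist.form = "point_mass"
        ll_pm = mi.loglik_post_marginal(sess, theta3, "CI", dist, theta1, 1.85)
        # brute-force conditional at the point
        da, dv = dist.mean
        sigma_a = theta3["a_A"] * theta1.k_A
        f_a = sigma_a ** -2 / (sigma_a ** -2 + 1e-4)
        var_a = f_a ** 2 * sigma_a ** 2 + 1.85 ** 2
        s, r = sess.post_A
        mu = f_a * (theta3["a_A"] * s + theta3["b_A"] + da)
        brute = float(np.sum(stats.norm.logpdf(r, mu, np.sqrt(var_a))))
        sv = theta1.sigma_V_uni[0]
        f_v = sv ** -2 / (sv ** -2 + 1e-4)
        var_v = f_v ** 2 * sv ** 2 + 1.85 ** 2
        s, r = sess.post_V
        brute += float(np.sum(stats.norm.logpdf(r, f_v * (s + dv),
                                                np.sqrt(var_v))))
        assert ll_pm == pytest.approx(brute, rel=1e-6)

    def test_grid_marginal_matches_monte_carlo(self, small_dataset):
        """Midpoint-rule marginal vs. averaging conditional likelihoods over
        draws from the fitted shift distribution."""
        sess, dist, theta1 = self._session_and_dist(small_dataset)
        theta3 = {"a_A": 1.1, "b_A": -0.6, "sigma_AV_A": 6.0,
                  "sigma_AV_V1": 3.0, "sigma_AV_V2": 6.0, "sigma_AV_V3": 9.0,
                  "lapse_AV": 0.03}
        ll_grid = mi.loglik_post_marginal(sess, theta3, "CI", dist, theta1,
                                          1.85)
        rng = np.random.default_rng(3)
        draws = rng.multivariate_normal(dist.mean, dist.cov, 100000)
        sigma_a = theta3["a_A"] * theta1.k_A
        f_a = sigma_a ** -2 / (sigma_a ** -2 + 1e-4)
        var_a = f_a ** 2 * sigma_a ** 2 + 1.85 ** 2
        s, r = sess.post_A
        ll_a = -0.5 * len(r) * np.log(2 * np.pi * var_a) - 0.5 / var_a * (
            ((r - f_a * (theta3["a_A"] * s + theta3["b_A"]))[None, :]
             - f_a * draws[:, 0:1]) ** 2
        ).sum(axis=1)
        sv = theta1.sigma_V_uni[0]
        f_v = sv ** -2 / (sv ** -2 + 1e-4)
        var_v = f_v ** 2 * sv ** 2 + 1.85 ** 2
        s, r = sess.post_V
        ll_v = -0.5 * len(r) * np.log(2 * np.pi * var_v) - 0.5 / var_v * (
            ((r - f_v * s)[None, :] - f_v * draws[:, 1:2]) ** 2
        ).sum(axis=1)
        tot = ll_a + ll_v
        m = tot.max()
        ll_mc = m + np.log(np.mean(np.exp(tot - m)))
        assert ll_grid == pytest.approx(ll_mc, abs=0.1)

    def test_rb_marginal_uses_variance_ratio_tie(self, small_dataset):
        sess, _, theta1 = self._session_and_dist(small_dataset, model="RB")
        p_rb = ObserverParams(alpha_A=0.008, alpha_V=0.008)
        dist = approximate_shift_distribution("RB", p_rb, sess.recal_design,
                                              400, 4)
        theta3 = {"a_A": 1.1, "b_A": -0.6, "sigma_AV_A": 6.0,
                  "sigma_AV_V1": 3.0, "sigma_AV_V2": 6.0, "sigma_AV_V3": 9.0,
                  "alpha": 0.008, "lapse_AV": 0.03}
        ll = mi.loglik_post_marginal(sess, theta3, "RB", dist, theta1, 1.85)
        assert np.isfinite(ll)
        # distorting the tied ratio changes the marginal
        ll2 = mi.loglik_post_marginal(sess, {**theta3, "sigma_AV_A": 12.0},
                                      "RB", dist, theta1, 1.85)
        assert ll != ll2


class TestFittingAndComparison:
    def test_fit_is_deterministic_given_seed(self, small_dataset):
        kw = dict(n_starts=1, seed=3, n_sims=60, maxfev=15, n_sims_final=100)
        r1 = mi.fit_model(small_dataset, "RB", **kw)
        r2 = mi.fit_model(small_dataset, "RB", **kw)
        assert r1.ll3 == r2.ll3
        assert r1.theta3 == r2.theta3

    def test_ci_tied_nested_in_ci(self, small_dataset):
        results = mi.fit_all_models(
            small_dataset, model_ids=("CI_tied", "CI"), n_starts=1, seed=1,
            n_sims=60, maxfev=25, n_sims_final=150,
        )
        by_id = {r.model_id: r for r in results}
        assert by_id["CI"].ll3 >= by_id["CI_tied"].ll3 - 1e-6

    def test_aic_arithmetic_and_labels(self):
        def mk(model_id, ll3, k):
            return mi.ModelFitResult(
                model_id=model_id, theta1={}, sigma_r=1.8, theta3={},
                ll1=-50.0, ll2=-50.0, ll3=ll3, aic=2 * k - 2 * (-100 + ll3),
                k_params=k, n_starts=1, n_sims=10, seed=0, converged=True,
                start_loglik3=[], shift_diagnostics=[],
            )

        best = mk("RB", 0.0, 8)
        assert best.aic == pytest.approx(216.0)
        worse = mk("FR", -5.5, 9)
        table = mi.compare_models([worse, best])
        assert table.model_id.tolist() == ["RB", "FR"]
        assert table.delta_aic.iloc[0] == 0.0
        assert table.delta_aic.iloc[1] == pytest.approx(13.0)
        assert table.support.iloc[1] == "essentially no support"
        assert mi.aic_support_label(1.0) == "substantial support"
        assert mi.aic_support_label(5.0) == "considerably less support"

    def test_fit_result_json_roundtrip(self, small_dataset, tmp_path):
        r = mi.fit_model(small_dataset, "RB", n_starts=1, seed=0, n_sims=60,
                         maxfev=10, n_sims_final=80)
        path = tmp_path / "fit.json"
        r.to_json(path)
        again = mi.ModelFitResult.from_json(path)
        assert again.model_id == "RB"
        assert again.ll3 == pytest.approx(r.ll3)
        assert again.theta3 == pytest.approx(r.theta3)
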