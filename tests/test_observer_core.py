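"""Closed-form perceptual computations: remapping, conditional estimates,
causal-scenario likelihoods (against quadrature oracles), posterior and
model-averaged estimates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from avrecal.observer_core import (
    DegenerateInputError,
    InvalidParameterError,
    MeasurementPair,
    ObserverParams,
    final_estimates,
    fused_estimate,
    likelihood_common,
    likelihood_separate,
    posterior_common,
    remap_to_internal,
    segregated_estimate,
)


def params_with(**kw) -> ObserverParams:
    return ObserverParams(**kw)


class TestObserverParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"sigma_A_uni": -1.0},
            {"sigma_A_bi": 0.0},
            {"lapse_A": 0.07},
            {"lapse_V": (0.01, -0.01, 0.02)},
            {"p_common": 1.5},
            {"alpha_A": -0.1},
            {"sigma_V_bi": (6.0, 3.0, 9.0)},  # not non-decreasing
            {"sigma_A_bi": 23.0},  # > 5x unimodal reference (4.5)
            {"sigma_V_bi": (3.0, 6.0, 40.0)},  # level-3 cap (5 x 7.5)
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            params_with(**kw)

    def test_reliability_accessors_are_one_based(self, default_params):
        assert default_params.sigma_v_bi(1) == default_params.sigma_V_bi[0]
        assert default_params.lapse_v(3) == default_params.lapse_V[2]


class TestRemap:
    def test_visual_identity(self, default_params):
        assert remap_to_internal(3.0, "V", default_params) == 3.0

    @pytest.mark.parametrize(
        "s, slope, intercept, shift, expected",
        [(5.0, 1.2, -1.0, 0.0, 5.0), (0.0, 2.0, 0.5, 1.5, 2.0)],
    )
    def test_auditory_affine(self, s, slope, intercept, shift, expected):
        p = params_with(bias_slope=slope, bias_intercept=intercept)
        assert remap_to_internal(s, "A", p, shift) == pytest.approx(expected)

    def test_unknown_modality_raises(self, default_params):
        with pytest.raises(ValueError):
            remap_to_internal(0.0, "X", default_params)


class TestConditionalEstimates:
    def test_fused_symmetry(self):
        p = params_with(sigma_A_bi=2.0, sigma_V_bi=(2.0, 2.0, 2.0))
        m = MeasurementPair(-4.0, 4.0, 1)
        assert fused_estimate(m, p) == pytest.approx(0.0, abs=1e-9)

    def test_fused_weighted_mean(self):
        p = params_with(sigma_A_bi=2.0, sigma_V_bi=(1.0, 1.0, 1.0))
        m = MeasurementPair(0.0, 6.0, 1)
        # (0/4 + 6/1) / (1/4 + 1 + 1/1e4)
        assert fused_estimate(m, p) == pytest.approx(4.7996, abs=1e-3)

    def test_fused_reliable_cue_dominates(self):
        p = params_with(sigma_A_bi=2.0, sigma_V_bi=(1e-4, 1e-4, 1e-4),
                        sigma_V_uni=(1e-4, 1e-4, 1e-4))
        m = MeasurementPair(0.0, 6.0, 1)
        assert fused_estimate(m, p) == pytest.approx(6.0, abs=1e-5)

    def test_segregated_weighted_mean(self, default_params):
        assert segregated_estimate(10.0, 1.0, default_params) == pytest.approx(
            9.999, abs=1e-3
        )

    def test_segregated_flat_prior_limit(self, flat_prior_params):
        assert segregated_estimate(10.0, 1.0, flat_prior_params) == pytest.approx(
            10.0, abs=1e-3
        )

    def test_segregated_agreement_case(self, default_params):
        mu = default_params.prior_mean
        assert segregated_estimate(mu, 2.0, default_params) == pytest.approx(mu)

    def test_segregated_rejects_bad_sigma(self, default_params):
        with pytest.raises(InvalidParameterError):
            segregated_estimate(1.0, -2.0, default_params)


def _quadrature_common(m_a, m_v, sig_a, sig_v, mu_p, sd_p):
    f = lambda s: (
        stats.norm.pdf(m_a, s, sig_a)
        * stats.norm.pdf(m_v, s, sig_v)
        * stats.norm.pdf(s, mu_p, sd_p)
    )
    # integrand can be a narrow spike near the measurements: hint those points
    val, _ = integrate.quad(
        f, -400.0, 400.0, limit=800, points=[m_a, m_v], epsabs=1e-13
    )
    return val


def _quadrature_single(m, sig, mu_p, sd_p):
    f = lambda s: stats.norm.pdf(m, s, sig) * stats.norm.pdf(s, mu_p, sd_p)
    val, _ = integrate.quad(
        f, -400.0, 400.0, limit=800, points=[m], epsabs=1e-13
    )
    return val


class TestScenarioLikelihoods:
    # grid spanning measurements in [-20, 20] and SDs in [0.5, 10]
    GRID = [
        (m_a, m_v, sig_a, sig_v)
        for m_a in (-20.0, -5.0, 0.0, 7.5, 20.0)
        for m_v in (-12.0, 0.0, 16.0)
        for sig_a in (0.5, 3.0, 10.0)
        for sig_v in (0.9, 6.0)
    ]

    @pytest.mark.parametrize("m_a, m_v, sig_a, sig_v", GRID)
    def test_common_matches_quadrature(self, m_a, m_v, sig_a, sig_v):
        p = params_with(sigma_A_bi=sig_a, sigma_V_bi=(sig_v,) * 3,
                        sigma_A_uni=sig_a, sigma_V_uni=(sig_v,) * 3)
        m = MeasurementPair(m_a, m_v, 1)
        expected = _quadrature_common(m_a, m_v, sig_a, sig_v, 0.0, 100.0)
        assert likelihood_common(m, p) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("m_a, m_v, sig_a, sig_v", GRID[::5])
    def test_separate_matches_product_of_quadratures(self, m_a, m_v, sig_a, sig_v):
        p = params_with(sigma_A_bi=sig_a, sigma_V_bi=(sig_v,) * 3,
                        sigma_A_uni=sig_a, sigma_V_uni=(sig_v,) * 3)
        m = MeasurementPair(m_a, m_v, 1)
        expected = _quadrature_single(m_a, sig_a, 0.0, 100.0) * _quadrature_single(
            m_v, sig_v, 0.0, 100.0
        )
        assert likelihood_separate(m, p) == pytest.approx(expected, abs=1e-8)

    def test_common_symmetric_under_cue_swap(self):
        p1 = params_with(sigma_A_bi=2.0, sigma_V_bi=(3.0, 3.0, 3.0))
        p2 = params_with(sigma_A_bi=3.0, sigma_V_bi=(2.0, 2.0, 2.0))
        v1 = likelihood_common(MeasurementPair(0.0, 5.0, 1), p1)
        v2 = likelihood_common(MeasurementPair(5.0, 0.0, 1), p2)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_separate_factorizes(self):
        p = params_with(sigma_A_bi=2.0, sigma_V_bi=(3.0, 3.0, 3.0))
        lone = likelihood_separate(MeasurementPair(1.0, 4.0, 1), p)
        f_a = likelihood_separate(MeasurementPair(1.0, 0.0, 1), p)
        g_v = likelihood_separate(MeasurementPair(0.0, 4.0, 1), p)
        zero = likelihood_separate(MeasurementPair(0.0, 0.0, 1), p)
        assert lone == pytest.approx(f_a * g_v / zero, rel=1e-9)

    def test_likelihoods_positive_and_log_stable_for_large_discrepancy(self):
        from avrecal.observer_core import (
            log_likelihood_common,
            log_likelihood_separate,
        )

        p = params_with()
        m = MeasurementPair(-50.0, 50.0, 1)
        assert likelihood_common(m, p) > 0
        assert likelihood_separate(m, p) > 0
        # far beyond float exp range the log densities stay finite
        m_far = MeasurementPair(-200.0, 200.0, 1)
        assert np.isfinite(log_likelihood_common(m_far, p))
        assert np.isfinite(log_likelihood_separate(m_far, p))


class TestPosteriorAndFinalEstimates:
    def test_posterior_prior_limits(self, default_params):
        m = MeasurementPair(0.0, 5.0, 1)
        assert posterior_common(m, params_with(p_common=1.0)).p_c1_given_m == 1.0
        assert posterior_common(m, params_with(p_common=0.0)).p_c1_given_m == 0.0

    def test_posterior_decreases_with_discrepancy(self, default_params):
        discrepancies = np.linspace(0.0, 30.0, 16)
        post = [
            posterior_common(MeasurementPair(0.0, d, 1), default_params).p_c1_given_m
            for d in discrepancies
        ]
        assert np.all(np.diff(post) < 0)

    def test_posterior_complement_sums_to_one(self, default_params):
        cp = posterior_common(MeasurementPair(1.0, 7.0, 2), default_params)
        odds = (cp.lik_c1 * default_params.p_common) / (
            cp.lik_c1 * default_params.p_common
            + cp.lik_c2 * (1 - default_params.p_common)
        )
        assert cp.p_c1_given_m == pytest.approx(odds, rel=1e-9)

    def test_full_integration_limit(self):
        p = params_with(p_common=1.0)
        m = MeasurementPair(0.0, 6.0, 1)
        s_a, s_v = final_estimates(m, p)
        assert s_a == pytest.approx(fused_estimate(m, p))
        assert s_v == pytest.approx(fused_estimate(m, p))

    def test_full_segregation_limit(self):
        p = params_with(p_common=0.0)
        m = MeasurementPair(0.0, 6.0, 1)
        s_a, _ = final_estimates(m, p)
        assert s_a == pytest.approx(
            segregated_estimate(0.0, p.sigma_A_bi, p)
        )

    def test_model_average_composes(self):
        p = params_with(sigma_A_bi=2.0, sigma_V_bi=(1.0, 1.0, 1.0),
                        p_common=0.5)
        m = MeasurementPair(0.0, 6.0, 1)
        w = posterior_common(m, p).p_c1_given_m
        expected_a = w * fused_estimate(m, p) + (1 - w) * segregated_estimate(
            0.0, 2.0, p
        )
        s_a, _ = final_estimates(m, p)
        assert s_a == pytest.approx(expected_a, rel=1e-12)

    @pytest.mark.parametrize("m_a, m_v", [(0.0, 3.0), (-10.0, 14.0), (2.0, 2.0)])
    @pytest.mark.parametrize("pc", [0.2, 0.5, 0.9])
    def test_convexity_between_conditional_estimates(self, m_a, m_v, pc):
        p = params_with(p_common=pc)
        m = MeasurementPair(m_a, m_v, 1)
        fused = fused_estimate(m, p)
        seg_a = segregated_estimate(m_a, p.sigma_A_bi, p)
        s_a, _ = final_estimates(m, p)
        assert min(fused, seg_a) - 1e-12 <= s_a <= max(fused, seg_a) + 1e-12

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        m_a=st.floats(-25.0, 25.0),
        m_v=st.floats(-25.0, 25.0),
        pc=st.floats(0.01, 0.99),
        sig_a=st.floats(0.5, 12.0),
        sig_v=st.floats(0.5, 12.0),
    )
    def test_convexity_property(self, m_a, m_v, pc, sig_a, sig_v):
        """For any measurements, SDs and common-cause prior, both final
        estimates lie between their fused and segregated conditionals."""
        p = params_with(p_common=pc, sigma_A_bi=sig_a,
                        sigma_V_bi=(sig_v,) * 3, sigma_A_uni=sig_a,
                        sigma_V_uni=(sig_v,) * 3)
        m = MeasurementPair(m_a, m_v, 1)
        fused = fused_estimate(m, p)
        s_a, s_v = final_estimates(m, p)
        seg_a = segregated_estimate(m_a, sig_a, p)
        seg_v = segregated_estimate(m_v, sig_v, p)
        assert min(fused, seg_a) - 1e-9 <= s_a <= max(fused, seg_a) + 1e-9
        assert min(fused, seg_v) - 1e-9 <= s_v <= max(fused, seg_v) + 1e-9

    def test_degenerate_vision_limit(self):
        # infinitely unreliable vision: the auditory estimate reverts to the
        # auditory measurement (flat prior)
        p = params_with(sigma_V_uni=(2e3, 2e3, 2e3), sigma_V_bi=(1e4, 1e4, 1e4),
                        prior_sd=1e6)
        m = MeasurementPair(5.0, -5.0, 1)
        s_a, _ = final_estimates(m, p)
        assert s_a == pytest.approx(5.0, abs=1e-3)
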