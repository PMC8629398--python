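"""Closed-form perceptual computations for a Bayesian causal-inference observer.

The observer receives noisy spatial measurements from audition and vision in a
shared internal reference frame.  Auditory physical locations are remapped
linearly (``s'_A = a_A * s_A + b_A``); visual remapping is fixed to the
identity, since only relative biases are measurable.  Given an audiovisual
measurement pair the observer weighs two causal scenarios -- a single common
source (C = 1) versus two independent sources (C = 2) -- and reports
model-averaged location estimates.

All computations accept NumPy arrays and broadcast; densities are evaluated in
log space internally to avoid underflow for widely discrepant measurements.

Coordinate convention: degrees of visual angle, 0 = straight ahead, positive =
rightward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LAPSE_MAX",
    "BIMODAL_SD_FACTOR_MAX",
    "InvalidParameterError",
    "DegenerateInputError",
    "ObserverParams",
    "MeasurementPair",
    "CausalPosterior",
    "remap_to_internal",
    "fused_estimate",
    "segregated_estimate",
    "log_likelihood_common",
    "log_likelihood_separate",
    "likelihood_common",
    "likelihood_separate",
    "posterior_common",
    "final_estimates",
]

#: Upper bound on every lapse rate (probability of a stimulus-independent
#: random response).
LAPSE_MAX = 0.06

#: Bimodal measurement SDs may not exceed this multiple of the corresponding
#: unimodal reference SD.
BIMODAL_SD_FACTOR_MAX = 5.0


class InvalidParameterError(ValueError):
    """An observer parameter violates its domain constraints."""


class DegenerateInputError(ValueError):
    """An input renders the requested computation undefined."""


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) != 3:
        raise InvalidParameterError(f"{name} must have exactly 3 entries, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class ObserverParams:
    """Complete generative parameter set of a synthetic (or fitted) observer.

    Attributes
    ----------
    sigma_A_uni : float
        Auditory measurement SD under unimodal presentation (deg).
    sigma_V_uni : tuple of 3 floats
        Visual measurement SDs per reliability level 1 (high) .. 3 (low), deg.
    sigma_A_bi : float
        Auditory measurement SD in bimodal trials (deg).
    sigma_V_bi : tuple of 3 floats
        Visual measurement SDs in bimodal trials per reliability level (deg);
        must be non-decreasing from level 1 to 3.
    bias_slope, bias_intercept : float
        Linear auditory-to-internal remapping (unitless slope a_A, intercept
        b_A in deg); vision is remapped by the identity.
    prior_mean, prior_sd : float
        Supra-modal Gaussian prior over internal locations.  The default
        (0, 100) implements an effectively flat prior.
    p_common : float
        Prior probability of a common audiovisual cause, P(C = 1).
    alpha_A, alpha_V : float
        Learning rates of the measurement-shift updates.  Models with a single
        supra-modal rate (reliability-based, tied causal inference) read
        ``alpha_A`` and ignore ``alpha_V``.
    sigma_r : float
        SD of pointing-response noise unrelated to spatial perception (deg).
    lapse_A : float
        Lapse rate in the unimodal auditory discrimination task.
    lapse_V : tuple of 3 floats
        Lapse rates in the unimodal visual discrimination tasks.
    lapse_AV : float
        Lapse rate in the bimodal discrimination task.
    """

    sigma_A_uni: float = 4.5
    sigma_V_uni: tuple[float, float, float] = (1.5, 4.5, 7.5)
    sigma_A_bi: float = 6.0
    sigma_V_bi: tuple[float, float, float] = (3.0, 6.0, 9.0)
    bias_slope: float = 1.1
    bias_intercept: float = -0.6
    prior_mean: float = 0.0
    prior_sd: float = 100.0
    p_common: float = 0.7
    alpha_A: float = 0.003
    alpha_V: float = 0.003
    sigma_r: float = 1.85
    lapse_A: float = 0.03
    lapse_V: tuple[float, float, float] = (0.02, 0.03, 0.04)
    lapse_AV: float = 0.03

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_V_uni", _as_tuple3(self.sigma_V_uni, "sigma_V_uni"))
        object.__setattr__(self, "sigma_V_bi", _as_tuple3(self.sigma_V_bi, "sigma_V_bi"))
        object.__setattr__(self, "lapse_V", _as_tuple3(self.lapse_V, "lapse_V"))
        sds = {
            "sigma_A_uni": self.sigma_A_uni,
            "sigma_A_bi": self.sigma_A_bi,
            "prior_sd": self.prior_sd,
            **{f"sigma_V_uni[{i}]": v for i, v in enumerate(self.sigma_V_uni)},
            **{f"sigma_V_bi[{i}]": v for i, v in enumerate(self.sigma_V_bi)},
        }
        for name, v in sds.items():
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be a positive finite SD, got {v}")
        if self.sigma_r < 0:
            raise InvalidParameterError(f"sigma_r must be >= 0, got {self.sigma_r}")
        lapses = {
            "lapse_A": self.lapse_A,
            "lapse_AV": self.lapse_AV,
            **{f"lapse_V[{i}]": v for i, v in enumerate(self.lapse_V)},
        }
        for name, v in lapses.items():
            if not 0.0 <= v <= LAPSE_MAX:
                raise InvalidParameterError(f"{name} must lie in [0, {LAPSE_MAX}], got {v}")
        if not 0.0 <= self.p_common <= 1.0:
            raise InvalidParameterError(f"p_common must lie in [0, 1], got {self.p_common}")
        for name in ("alpha_A", "alpha_V"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
        if not (self.sigma_V_bi[0] <= self.sigma_V_bi[1] <= self.sigma_V_bi[2]):
            raise InvalidParameterError(
                f"sigma_V_bi must be non-decreasing across reliability levels, got {self.sigma_V_bi}"
            )
        if self.sigma_A_bi > BIMODAL_SD_FACTOR_MAX * self.sigma_A_uni:
            raise InvalidParameterError(
                "sigma_A_bi exceeds "
                f"{BIMODAL_SD_FACTOR_MAX}x the unimodal auditory reference SD"
            )
        for i in range(3):
            if self.sigma_V_bi[i] > BIMODAL_SD_FACTOR_MAX * self.sigma_V_uni[i]:
                raise InvalidParameterError(
                    f"sigma_V_bi[{i}] exceeds {BIMODAL_SD_FACTOR_MAX}x the "
                    "corresponding unimodal visual reference SD"
                )

    # -- convenience accessors (reliability levels are 1-based) -------------
    def sigma_v_uni(self, level: int) -> float:
        return self.sigma_V_uni[level - 1]

    def sigma_v_bi(self, level: int) -> float:
        return self.sigma_V_bi[level - 1]

    def lapse_v(self, level: int) -> float:
        return self.lapse_V[level - 1]


@dataclass
class MeasurementPair:
    """One audiovisual measurement pair in internal coordinates.

    ``m_A`` and ``m_V`` may be scalars or broadcastable arrays (the latter is
    used by the vectorized recalibration simulator).
    """

    m_A: np.ndarray | float
    m_V: np.ndarray | float
    reliability_level: int = 1

    def __post_init__(self) -> None:
        if self.reliability_level not in (1, 2, 3):
            raise InvalidParameterError(
                f"reliability_level must be 1, 2 or 3, got {self.reliability_level}"
            )
        if not (np.all(np.isfinite(self.m_A)) and np.all(np.isfinite(self.m_V))):
            raise DegenerateInputError("measurements must be finite")


@dataclass
class CausalPosterior:
    """Posterior over the causal structure given one measurement pair."""

    p_c1_given_m: np.ndarray | float
    lik_c1: np.ndarray | float
    lik_c2: np.ndarray | float


def remap_to_internal(s, modality: str, params: ObserverParams, shift=0.0):
    """Map a physical location into internal coordinates.

    Auditory: ``a_A * s + b_A + shift``;  visual: ``s + shift`` (identity
    remap, a_V = 1, b_V = 0).  ``shift`` is the accumulated measurement shift
    for that modality.
    """
    s = np.asarray(s, dtype=float)
    if modality == "A":
        return params.bias_slope * s + params.bias_intercept + shift
    if modality == "V":
        return s + shift
    raise ValueError(f"modality must be 'A' or 'V', got {modality!r}")


def _bimodal_sigmas(m: MeasurementPair, params: ObserverParams) -> tuple[float, float]:
    return params.sigma_A_bi, params.sigma_v_bi(m.reliability_level)


def fused_estimate(m: MeasurementPair, params: ObserverParams):
    """Common-cause location estimate: the reliability-weighted average of the
    two measurements and the prior mean (bimodal SDs)."""
    sa, sv = _bimodal_sigmas(m, params)
    ja, jv, jp = sa ** -2, sv ** -2, params.prior_sd ** -2
    return (np.asarray(m.m_A) * ja + np.asarray(m.m_V) * jv + params.prior_mean * jp) / (
        ja + jv + jp
    )


def segregated_estimate(m, sigma: float, params: ObserverParams):
    """Separate-cause estimate of one modality: reliability-weighted average
    of the measurement and the prior mean."""
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    j, jp = sigma ** -2, params.prior_sd ** -2
    return (np.asarray(m, dtype=float) * j + params.prior_mean * jp) / (j + jp)


def log_likelihood_common(m: MeasurementPair, params: ObserverParams):
    """Log-likelihood of a single common source for the measurement pair.

    Closed form of the marginal
    ``integral phi(m_A; s, sigma_A) phi(m_V; s, sigma_V) phi(s; mu_P, sigma_P) ds``.
    """
    sa, sv = _bimodal_sigmas(m, params)
    va, vv, vp = sa ** 2, sv ** 2, params.prior_sd ** 2
    mu = params.prior_mean
    m_A = np.asarray(m.m_A, dtype=float)
    m_V = np.asarray(m.m_V, dtype=float)
    det = va * vv + va * vp + vv * vp
    quad = ((m_A - m_V) ** 2 * vp + (m_A - mu) ** 2 * vv + (m_V - mu) ** 2 * va) / det
    return -math.log(2.0 * math.pi) - 0.5 * math.log(det) - 0.5 * quad


def log_likelihood_separate(m: MeasurementPair, params: ObserverParams):
    """Log-likelihood of two independent sources (the product of the two
    single-cue marginals)."""
    sa, sv = _bimodal_sigmas(m, params)
    va, vv, vp = sa ** 2, sv ** 2, params.prior_sd ** 2
    mu = params.prior_mean
    m_A = np.asarray(m.m_A, dtype=float)
    m_V = np.asarray(m.m_V, dtype=float)
    quad = (m_A - mu) ** 2 / (va + vp) + (m_V - mu) ** 2 / (vv + vp)
    return (
        -math.log(2.0 * math.pi)
        - 0.5 * math.log((va + vp) * (vv + vp))
        - 0.5 * quad
    )


def likelihood_common(m: MeasurementPair, params: ObserverParams):
    return np.exp(log_likelihood_common(m, params))


def likelihood_separate(m: MeasurementPair, params: ObserverParams):
    return np.exp(log_likelihood_separate(m, params))


def posterior_common(m: MeasurementPair, params: ObserverParams) -> CausalPosterior:
    """Posterior probability of a common cause, Bayes-combining the two
    scenario likelihoods with the prior P(C = 1)."""
    log_l1 = np.asarray(log_likelihood_common(m, params), dtype=float)
    log_l2 = np.asarray(log_likelihood_separate(m, params), dtype=float)
    if np.any(np.isneginf(log_l1) & np.isneginf(log_l2)):
        raise DegenerateInputError("both causal-scenario likelihoods are zero")
    pc = params.p_common
    if pc == 1.0:
        p = np.ones_like(log_l1)
    elif pc == 0.0:
        p = np.zeros_like(log_l1)
    else:
        # p = 1 / (1 + exp(log odds against))
        log_odds = (log_l2 + math.log(1.0 - pc)) - (log_l1 + math.log(pc))
        p = 1.0 / (1.0 + np.exp(log_odds))
    squeeze = np.isscalar(m.m_A) or (np.ndim(m.m_A) == 0 and np.ndim(m.m_V) == 0)
    if squeeze:
        p = float(p)
        log_l1 = float(log_l1)
        log_l2 = float(log_l2)
        return CausalPosterior(p, math.exp(log_l1), math.exp(log_l2))
    return CausalPosterior(p, np.exp(log_l1), np.exp(log_l2))


def final_estimates(m: MeasurementPair, params: ObserverParams):
    """Model-averaged final location estimates (s_hat_A, s_hat_V).

    Each estimate is the posterior-weighted mix of the fused (C = 1) and the
    modality's segregated (C = 2) conditional estimates, so it always lies in
    the closed interval between them.
    """
    post = posterior_common(m, params)
    p = np.asarray(post.p_c1_given_m, dtype=float)
    sa, sv = _bimodal_sigmas(m, params)
    fused = fused_estimate(m, params)
    seg_a = segregated_estimate(m.m_A, sa, params)
    seg_v = segregated_estimate(m.m_V, sv, params)
    s_hat_a = p * fused + (1.0 - p) * seg_a
    s_hat_v = p * fused + (1.0 - p) * seg_v
    return s_hat_a, s_hat_v


def _final_estimates_core(m_a, m_v, var_a, var_v, mu_p, var_p, p_common):
    """Broadcasting kernel behind :func:`final_estimates` with explicit
    measurement variances (used by the vectorized recalibration simulator,
    where sigma varies across stacked sessions)."""
    ja, jv, jp = 1.0 / var_a, 1.0 / var_v, 1.0 / var_p
    fused = (m_a * ja + m_v * jv + mu_p * jp) / (ja + jv + jp)
    seg_a = (m_a * ja + mu_p * jp) / (ja + jp)
    seg_v = (m_v * jv + mu_p * jp) / (jv + jp)
    if p_common >= 1.0:
        return fused, fused
    if p_common <= 0.0:
        return seg_a, seg_v
    det = var_a * var_v + var_a * var_p + var_v * var_p
    log_l1 = (
        -0.5 * np.log(det)
        - 0.5
        * ((m_a - m_v) ** 2 * var_p + (m_a - mu_p) ** 2 * var_v
           + (m_v - mu_p) ** 2 * var_a) / det
    )
    log_l2 = (
        -0.5 * np.log((var_a + var_p) * (var_v + var_p))
        - 0.5 * ((m_a - mu_p) ** 2 / (var_a + var_p)
                 + (m_v - mu_p) ** 2 / (var_v + var_p))
    )
    log_odds = (log_l2 + math.log(1.0 - p_common)) - (log_l1 + math.log(p_common))
    p = 1.0 / (1.0 + np.exp(log_odds))
    return p * fused + (1.0 - p) * seg_a, p * fused + (1.0 - p) * seg_v
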