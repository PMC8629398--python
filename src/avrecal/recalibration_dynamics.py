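"""Trial-by-trial measurement-shift dynamics and their Monte-Carlo summaries.

During the recalibration phase the observer encounters 120 spatially
discrepant audiovisual stimuli (3 location pairs x 40 repetitions, random
order).  After every trial the modality-specific measurement shifts
(Delta_A, Delta_V) are updated according to one of three candidate rules:

``RB``
    reliability-based: each modality moves toward the other by a fraction of
    the measurement discrepancy proportional to the other modality's relative
    reliability (supra-modal learning rate).
``FR``
    fixed-ratio: each modality moves by a modality-specific fraction of the
    discrepancy, independent of stimulus reliability.
``CI`` / ``CI_tied``
    causal-inference: each modality moves toward its own model-averaged
    perceptual estimate (see :mod:`avrecal.observer_core`); ``CI_tied`` uses a
    single supra-modal learning rate.

The shifts feed back: they displace the measurement-distribution means on the
*next* trial.  Because the final shifts after 120 trials have no closed-form
distribution, they are approximated by Monte-Carlo simulation, summarized as
a (possibly bivariate) Gaussian, and replaced by a kernel density estimate
whenever the Gaussian fails an R-squared > 0.925 histogram check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .observer_core import (
    InvalidParameterError,
    MeasurementPair,
    ObserverParams,
    _final_estimates_core,
    final_estimates,
)

__all__ = [
    "MODEL_IDS",
    "GAUSSIAN_R2_THRESHOLD",
    "RecalibrationDesign",
    "ShiftState",
    "ShiftTrajectory",
    "ShiftDistribution",
    "relative_visual_weight",
    "update_reliability_based",
    "update_fixed_ratio",
    "update_causal_inference",
    "simulate_final_shifts",
    "simulate_recalibration_phase",
    "approximate_shift_distribution",
    "approximate_shift_distributions_multi",
]

MODEL_IDS = ("RB", "FR", "CI", "CI_tied")

#: Acceptance threshold of the Gaussian goodness-of-fit check on the
#: Monte-Carlo shift distribution.
GAUSSIAN_R2_THRESHOLD = 0.925

_N_BINS = 100  # histogram bins of the Gaussian check and integration grid


@dataclass(frozen=True)
class RecalibrationDesign:
    """Stimulus design of one recalibration session.

    ``pairs`` holds the three physical (s_A, s_V) location pairs: each
    auditory location is paired with the visual location perceived as aligned
    with the *neighboring* auditory location (one location step to the left or
    right, depending on ``direction``).
    """

    pairs: tuple[tuple[float, float], ...]
    reliability_level: int
    direction: str  # 'V_left' or 'V_right' (visual left/right of auditory)
    n_repeats: int = 40

    def __post_init__(self) -> None:
        if len(self.pairs) != 3:
            raise ValueError(f"expected 3 audiovisual pairs, got {len(self.pairs)}")
        if self.direction not in ("V_left", "V_right"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.reliability_level not in (1, 2, 3):
            raise ValueError(f"reliability_level must be 1-3, got {self.reliability_level}")

    @property
    def n_trials(self) -> int:
        return 3 * self.n_repeats

    @property
    def direction_sign(self) -> int:
        """+1 if the visual stimulus lies to the right of the auditory one."""
        return 1 if self.direction == "V_right" else -1


@dataclass
class ShiftState:
    """Measurement shifts before trial ``t`` (1-based; t=1 is calibrated)."""

    delta_A: float = 0.0
    delta_V: float = 0.0
    t: int = 1

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("trial index is 1-based")


@dataclass
class ShiftTrajectory:
    """Per-trial (Delta_A, Delta_V) sequence over one recalibration phase.

    ``deltas`` has shape (T+1, 2): row 0 is the calibrated initial state and
    row T holds the final shifts entering the post-recalibration phase.
    """

    deltas: np.ndarray
    model_id: str
    reliability_level: int
    direction: str

    def __len__(self) -> int:
        return self.deltas.shape[0]

    @property
    def final_shifts(self) -> tuple[float, float]:
        return float(self.deltas[-1, 0]), float(self.deltas[-1, 1])

    @property
    def states(self) -> list[ShiftState]:
        return [
            ShiftState(float(a), float(v), t + 1)
            for t, (a, v) in enumerate(self.deltas)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(1, len(self) + 1),
                "delta_A": self.deltas[:, 0],
                "delta_V": self.deltas[:, 1],
                "model_id": self.model_id,
                "reliability_level": self.reliability_level,
                "direction": self.direction,
            }
        )


def relative_visual_weight(params: ObserverParams, reliability_level: int) -> float:
    """Relative visual reliability w_i = sigma_V^-2 / (sigma_V^-2 + sigma_A^-2)
    using bimodal measurement SDs."""
    sv = params.sigma_v_bi(reliability_level)
    sa = params.sigma_A_bi
    if sv <= 0 or sa <= 0:
        raise InvalidParameterError("bimodal SDs must be positive")
    return sv ** -2 / (sv ** -2 + sa ** -2)


def update_reliability_based(
    state: ShiftState, m: MeasurementPair, params: ObserverParams
) -> ShiftState:
    """Reliability-based update with supra-modal rate alpha (= ``alpha_A``)."""
    w = relative_visual_weight(params, m.reliability_level)
    alpha = params.alpha_A
    disc = np.asarray(m.m_V) - np.asarray(m.m_A)
    return ShiftState(
        state.delta_A + alpha * w * float(disc),
        state.delta_V + alpha * (1.0 - w) * float(-disc),
        state.t + 1,
    )


def update_fixed_ratio(
    state: ShiftState, m: MeasurementPair, params: ObserverParams
) -> ShiftState:
    disc = float(np.asarray(m.m_V) - np.asarray(m.m_A))
    return ShiftState(
        state.delta_A + params.alpha_A * disc,
        state.delta_V - params.alpha_V * disc,
        state.t + 1,
    )


def update_causal_inference(
    state: ShiftState,
    m: MeasurementPair,
    params: ObserverParams,
    tied: bool = False,
) -> ShiftState:
    """Causal-inference update: each modality moves toward its final estimate.

    With ``tied=True`` both modalities use the supra-modal rate ``alpha_A``.
    """
    s_hat_a, s_hat_v = final_estimates(m, params)
    alpha_a = params.alpha_A
    alpha_v = params.alpha_A if tied else params.alpha_V
    return ShiftState(
        state.delta_A + alpha_a * float(s_hat_a - np.asarray(m.m_A)),
        state.delta_V + alpha_v * float(s_hat_v - np.asarray(m.m_V)),
        state.t + 1,
    )


def _rates(model_id: str, params: ObserverParams, reliability_level: int):
    if model_id == "RB":
        w = relative_visual_weight(params, reliability_level)
        return params.alpha_A * w, params.alpha_A * (1.0 - w)
    if model_id == "FR":
        return params.alpha_A, params.alpha_V
    if model_id == "CI":
        return params.alpha_A, params.alpha_V
    if model_id == "CI_tied":
        return params.alpha_A, params.alpha_A
    raise ValueError(f"unknown model_id {model_id!r}")


def simulate_final_shifts(
    model_id: str,
    params: ObserverParams,
    design: RecalibrationDesign,
    n_sims: int,
    rng: np.random.Generator,
    record: bool = False,
):
    """Simulate ``n_sims`` independent recalibration phases (vectorized).

    Each simulated phase presents the design's three audiovisual pairs
    ``n_repeats`` times in an independent random order, draws fresh bimodal
    measurements around the shifted remapped locations, and applies the
    model's update rule after every trial.

    Returns an array of final shifts with shape (n_sims, 2); with
    ``record=True`` additionally returns the full trajectory array of shape
    (T+1, n_sims, 2).
    """
    rate_a, rate_v = _rates(model_id, params, design.reliability_level)
    i = design.reliability_level
    sig_a = params.sigma_A_bi
    sig_v = params.sigma_v_bi(i)
    pairs = np.asarray(design.pairs, dtype=float)
    T = design.n_trials

    order = np.tile(np.repeat(np.arange(3), design.n_repeats), (n_sims, 1))
    order = rng.permuted(order, axis=1)

    d_a = np.zeros(n_sims)
    d_v = np.zeros(n_sims)
    traj = np.zeros((T + 1, n_sims, 2)) if record else None
    causal = model_id in ("CI", "CI_tied")

    for t in range(T):
        s_a = pairs[order[:, t], 0]
        s_v = pairs[order[:, t], 1]
        m_a = (
            params.bias_slope * s_a
            + params.bias_intercept
            + d_a
            + rng.normal(0.0, sig_a, n_sims)
        )
        m_v = s_v + d_v + rng.normal(0.0, sig_v, n_sims)
        if causal:
            s_hat_a, s_hat_v = final_estimates(
                MeasurementPair(m_a, m_v, i), params
            )
            d_a = d_a + rate_a * (s_hat_a - m_a)
            d_v = d_v + rate_v * (s_hat_v - m_v)
        else:
            disc = m_v - m_a
            d_a = d_a + rate_a * disc
            d_v = d_v - rate_v * disc
        if record:
            traj[t + 1, :, 0] = d_a
            traj[t + 1, :, 1] = d_v

    finals = np.column_stack([d_a, d_v])
    if record:
        return finals, traj
    return finals


@njit(cache=False, fastmath=True)
def _dynamics_kernel(order, noise_a, noise_v, pairs, slope, intercept,
                     rate_a, rate_v, var_a, var_v, mu_p, var_p, pc,
                     causal):  # pragma: no cover - exercised via wrapper
    S, N, T = order.shape
    out = np.zeros((S, N, 2))
    log_pc_odds = 0.0
    if causal and 0.0 < pc < 1.0:
        log_pc_odds = math.log(1.0 - pc) - math.log(pc)
    for s in range(S):
        va = var_a
        vv = var_v[s]
        ja, jv, jp = 1.0 / va, 1.0 / vv, 1.0 / var_p
        det = va * vv + va * var_p + vv * var_p
        for n in range(N):
            d_a = 0.0
            d_v = 0.0
            for t in range(T):
                k = order[s, n, t]
                m_a = (slope * pairs[s, k, 0] + intercept + d_a
                       + noise_a[s, n, t])
                m_v = pairs[s, k, 1] + d_v + noise_v[s, n, t]
                if causal:
                    fused = (m_a * ja + m_v * jv + mu_p * jp) / (ja + jv + jp)
                    seg_a = (m_a * ja + mu_p * jp) / (ja + jp)
                    seg_v = (m_v * jv + mu_p * jp) / (jv + jp)
                    if pc >= 1.0:
                        p = 1.0
                    elif pc <= 0.0:
                        p = 0.0
                    else:
                        log_l1 = -0.5 * math.log(det) - 0.5 * (
                            (m_a - m_v) ** 2 * var_p
                            + (m_a - mu_p) ** 2 * vv
                            + (m_v - mu_p) ** 2 * va) / det
                        log_l2 = -0.5 * math.log((va + var_p) * (vv + var_p)) \
                            - 0.5 * ((m_a - mu_p) ** 2 / (va + var_p)
                                     + (m_v - mu_p) ** 2 / (vv + var_p))
                        lo = log_l2 - log_l1 + log_pc_odds
                        if lo > 35.0:
                            p = 0.0
                        elif lo < -35.0:
                            p = 1.0
                        else:
                            p = 1.0 / (1.0 + math.exp(lo))
                    d_a += rate_a[s] * (p * fused + (1 - p) * seg_a - m_a)
                    d_v += rate_v[s] * (p * fused + (1 - p) * seg_v - m_v)
                else:
                    disc = m_v - m_a
                    d_a += rate_a[s] * disc
                    d_v -= rate_v[s] * disc
            out[s, n, 0] = d_a
            out[s, n, 1] = d_v
    return out


@njit(cache=False, fastmath=True)
def _kde_logpdf_1d(train, var, x):  # pragma: no cover - exercised via wrapper
    n = train.size
    const = -math.log(n) - 0.5 * math.log(2.0 * math.pi * var)
    out = np.empty(x.size)
    for i in range(x.size):
        m = -1e308
        for j in range(n):
            q = -0.5 * (x[i] - train[j]) ** 2 / var
            if q > m:
                m = q
        acc = 0.0
        for j in range(n):
            acc += math.exp(-0.5 * (x[i] - train[j]) ** 2 / var - m)
        out[i] = const + m + math.log(acc)
    return out


@njit(cache=False, fastmath=True)
def _kde_logpdf_2d(train, inv00, inv01, inv11, log_norm, pts):
    # pragma: no cover - exercised via wrapper
    # kernel exponents are <= 0, so the plain sum cannot overflow; kernels
    # beyond ~e-34 relative weight are skipped
    n = train.shape[0]
    out = np.empty(pts.shape[0])
    for i in range(pts.shape[0]):
        acc = 0.0
        for j in range(n):
            da = pts[i, 0] - train[j, 0]
            dv = pts[i, 1] - train[j, 1]
            q = -0.5 * (inv00 * da * da + 2.0 * inv01 * da * dv
                        + inv11 * dv * dv)
            if q > -60.0:
                acc += math.exp(q)
        if acc > 0.0:
            out[i] = log_norm + math.log(acc)
        else:
            # far tail: fall back to the nearest kernel alone
            m = -1e308
            for j in range(n):
                da = pts[i, 0] - train[j, 0]
                dv = pts[i, 1] - train[j, 1]
                q = -0.5 * (inv00 * da * da + 2.0 * inv01 * da * dv
                            + inv11 * dv * dv)
                if q > m:
                    m = q
            out[i] = log_norm + m
    return out


def _simulate_final_shifts_multi(
    model_id: str,
    params: ObserverParams,
    designs: list,
    n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized variant of :func:`simulate_final_shifts` running several
    sessions at once; returns final shifts of shape (n_sessions, n_sims, 2).

    All designs must share the same trial count.  Used by the model-fitting
    objective, where the six sessions of one candidate parameter set are
    simulated in a single pass (measurement noise pre-drawn, dynamics
    compiled).
    """
    S = len(designs)
    T = designs[0].n_trials
    if any(d.n_trials != T for d in designs):
        raise ValueError("all designs must have the same trial count")
    pairs = np.asarray([d.pairs for d in designs], dtype=float)  # (S, 3, 2)
    sig_a = params.sigma_A_bi
    sig_v = np.array(
        [params.sigma_v_bi(d.reliability_level) for d in designs]
    )
    rates = np.asarray(
        [_rates(model_id, params, d.reliability_level) for d in designs]
    )
    causal = model_id in ("CI", "CI_tied")

    order = np.tile(
        np.repeat(np.arange(3), designs[0].n_repeats), (S, n_sims, 1)
    )
    order = rng.permuted(order, axis=2)
    noise_a = rng.standard_normal((S, n_sims, T)) * sig_a
    noise_v = rng.standard_normal((S, n_sims, T)) * sig_v[:, None, None]
    return _dynamics_kernel(
        order, noise_a, noise_v, pairs,
        params.bias_slope, params.bias_intercept,
        np.ascontiguousarray(rates[:, 0]), np.ascontiguousarray(rates[:, 1]),
        sig_a ** 2, sig_v ** 2,
        params.prior_mean, params.prior_sd ** 2, params.p_common, causal,
    )


def simulate_recalibration_phase(
    model_id: str,
    params: ObserverParams,
    design: RecalibrationDesign,
    seed: int | np.random.Generator = 0,
) -> ShiftTrajectory:
    """Run one recalibration phase and return its full shift trajectory
    (length T+1 = 121 for the standard design)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, traj = simulate_final_shifts(model_id, params, design, 1, rng, record=True)
    return ShiftTrajectory(
        deltas=traj[:, 0, :],
        model_id=model_id,
        reliability_level=design.reliability_level,
        direction=design.direction,
    )


def _expanded_bounds(x: np.ndarray) -> tuple[float, float]:
    """3x-expansion rule: centre the integration region on the sample range
    and make it three times as wide."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    return lo - span, hi + span


def _gaussian_r2(x: np.ndarray, mean: float, sd: float, lb: float, ub: float) -> float:
    """R^2 between observed and Gaussian-predicted counts over equal-width
    bins spanning the numerical-integration region."""
    edges = np.linspace(lb, ub, _N_BINS + 1)
    obs, _ = np.histogram(x, edges)
    pred = x.size * np.diff(stats.norm.cdf(edges, mean, sd))
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass
class ShiftDistribution:
    """Monte-Carlo approximation of the final-shift distribution.

    ``form`` is one of ``gaussian`` (1-D over Delta_V; reliability-based and
    fixed-ratio models, where Delta_A is tied to Delta_V by a fixed ratio),
    ``bivariate_gaussian`` (causal-inference models), ``kde`` (fallback when
    the Gaussian histogram check fails) or ``point_mass`` (degenerate,
    near-zero sample variance).
    """

    samples: np.ndarray  # (n_sims, 2) final (Delta_A, Delta_V) pairs
    form: str
    model_id: str
    reliability_level: int
    direction: str
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None
    r_squared: float = np.nan
    r_squared_per_dim: tuple[float, ...] = ()
    integration_bounds: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    kde: object | None = None
    kde_bandwidth: float | None = None

    @property
    def n_sims(self) -> int:
        return self.samples.shape[0]

    # -- densities used by the marginal likelihood --------------------------
    def logpdf_delta_v(self, x: np.ndarray, cell_var: float = 0.0) -> np.ndarray:
        """Log density of the visual shift (1-D forms only).

        ``cell_var`` (the within-cell variance ``width**2 / 12`` of the
        caller's integration grid) convolves the density with the cell so
        that midpoint density times cell width equals the cell mass even when
        the distribution is much narrower than a grid cell.
        """
        x = np.asarray(x, dtype=float)
        if self.form == "gaussian":
            sd = np.sqrt(self.cov[1, 1] + cell_var)
            return stats.norm.logpdf(x, self.mean[1], sd)
        if self.form == "kde":
            return _kde_logpdf_1d(
                np.ascontiguousarray(self.kde.dataset[0]),
                float(self.kde.covariance[0, 0]),
                np.atleast_1d(x).astype(float),
            )
        raise ValueError(f"no 1-D density for form {self.form!r}")

    def logpdf_joint(
        self,
        delta_a: np.ndarray,
        delta_v: np.ndarray,
        cell_var: tuple[float, float] = (0.0, 0.0),
    ) -> np.ndarray:
        """Log joint density evaluated on the grid outer product; returns an
        array of shape (len(delta_a), len(delta_v)).

        ``cell_var`` convolves the Gaussian with the integration cell.  This
        matters because the causal-inference updates make Delta_A and Delta_V
        almost exactly proportional (the supra-modal prior is nearly flat),
        so the sample covariance is a degenerate ridge far narrower than a
        grid cell; without the correction, midpoint-rule quadrature of the
        raw density is arbitrarily inaccurate.
        """
        a = np.asarray(delta_a, dtype=float)
        v = np.asarray(delta_v, dtype=float)
        if self.form == "bivariate_gaussian":
            cov = np.asarray(self.cov, dtype=float) + np.diag(cell_var)
            det = float(np.linalg.det(cov))
            if det <= 0:  # near-singular sample covariance
                cov = cov + 1e-12 * np.eye(2)
                det = float(np.linalg.det(cov))
            inv = np.linalg.inv(cov)
            da = (a - self.mean[0])[:, None]
            dv = (v - self.mean[1])[None, :]
            quad = (
                inv[0, 0] * da ** 2
                + 2.0 * inv[0, 1] * da * dv
                + inv[1, 1] * dv ** 2
            )
            return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad
        if self.form == "kde":
            # the kernel mixture is numerically zero a few bandwidths outside
            # the sample box; skip those grid points
            bw = np.sqrt(np.diag(self.kde.covariance))
            lo = self.samples.min(axis=0) - 5.0 * bw
            hi = self.samples.max(axis=0) + 5.0 * bw
            aa, vv = np.meshgrid(a, v, indexing="ij")
            pts = np.vstack([aa.ravel(), vv.ravel()])
            inside = (
                (pts[0] >= lo[0]) & (pts[0] <= hi[0])
                & (pts[1] >= lo[1]) & (pts[1] <= hi[1])
            )
            out = np.full(pts.shape[1], -np.inf)
            if inside.any():
                cov = self.kde.covariance
                det = float(np.linalg.det(cov))
                inv = np.linalg.inv(cov)
                log_norm = -math.log(self.kde.n) - math.log(2.0 * math.pi) \
                    - 0.5 * math.log(det)
                out[inside] = _kde_logpdf_2d(
                    np.ascontiguousarray(self.kde.dataset.T),
                    float(inv[0, 0]), float(inv[0, 1]), float(inv[1, 1]),
                    log_norm, np.ascontiguousarray(pts[:, inside].T),
                )
            return out.reshape(a.size, v.size)
        raise ValueError(f"no joint density for form {self.form!r}")

    def metadata(self) -> dict:
        return {
            "form": self.form,
            "model_id": self.model_id,
            "reliability_level": self.reliability_level,
            "direction": self.direction,
            "n_sims": int(self.n_sims),
            "mean": None if self.mean is None else np.asarray(self.mean).tolist(),
            "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
            "r_squared": None if np.isnan(self.r_squared) else float(self.r_squared),
            "r_squared_per_dim": [float(r) for r in self.r_squared_per_dim],
            "integration_bounds": [float(b) for b in self.integration_bounds],
            "kde_bandwidth": self.kde_bandwidth,
        }

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["delta_A", "delta_V"])


def approximate_shift_distribution(
    model_id: str,
    params: ObserverParams,
    design: RecalibrationDesign,
    n_sims: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ShiftDistribution:
    """Monte-Carlo approximation of the distribution of final shifts.

    Simulates ``n_sims`` recalibration phases; for the reliability-based and
    fixed-ratio models fits a 1-D Gaussian to the visual shifts (the auditory
    shift is implied by the fixed ratio), for the causal-inference models a
    bivariate Gaussian to the (Delta_A, Delta_V) pairs.  The Gaussian is
    accepted if the R^2 between observed and predicted counts over 100
    equal-width bins (per dimension) exceeds 0.925; otherwise a Gaussian KDE
    (Silverman bandwidth) replaces it.  Integration bounds follow the
    3x-expansion rule per dimension.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    finals = simulate_final_shifts(model_id, params, design, n_sims, rng)
    return _summarize_finals(finals, model_id, design)


def approximate_shift_distributions_multi(
    model_id: str,
    params: ObserverParams,
    designs: list,
    n_sims: int,
    rng: np.random.Generator,
) -> list[ShiftDistribution]:
    """Shift distributions for several sessions from one vectorized
    simulation pass (single random stream; deterministic given ``rng``)."""
    finals = _simulate_final_shifts_multi(model_id, params, designs, n_sims, rng)
    return [
        _summarize_finals(finals[s], model_id, d)
        for s, d in enumerate(designs)
    ]


def _summarize_finals(
    finals: np.ndarray, model_id: str, design: RecalibrationDesign
) -> ShiftDistribution:
    d_a, d_v = finals[:, 0], finals[:, 1]
    lb_a, ub_a = _expanded_bounds(d_a)
    lb_v, ub_v = _expanded_bounds(d_v)
    bounds = (lb_a, ub_a, lb_v, ub_v)
    mean = finals.mean(axis=0)
    common = dict(
        samples=finals,
        model_id=model_id,
        reliability_level=design.reliability_level,
        direction=design.direction,
        integration_bounds=bounds,
    )

    bivariate = model_id in ("CI", "CI_tied")
    spans = (np.ptp(d_a), np.ptp(d_v)) if bivariate else (np.ptp(d_v),)
    if min(spans) < 1e-9:
        warnings.warn(
            "degenerate (near-zero variance) shift sample; returning point mass",
            RuntimeWarning,
        )
        return ShiftDistribution(
            form="point_mass", mean=mean, cov=np.zeros((2, 2)), **common
        )

    if bivariate:
        cov = np.cov(finals.T)
        r2_a = _gaussian_r2(d_a, mean[0], np.sqrt(cov[0, 0]), lb_a, ub_a)
        r2_v = _gaussian_r2(d_v, mean[1], np.sqrt(cov[1, 1]), lb_v, ub_v)
        r2 = min(r2_a, r2_v)
        per_dim = (r2_a, r2_v)
        if r2 > GAUSSIAN_R2_THRESHOLD:
            return ShiftDistribution(
                form="bivariate_gaussian",
                mean=mean,
                cov=cov,
                r_squared=r2,
                r_squared_per_dim=per_dim,
                **common,
            )
        kde = stats.gaussian_kde(finals.T, bw_method="silverman")
        return ShiftDistribution(
            form="kde",
            mean=mean,
            cov=cov,
            r_squared=r2,
            r_squared_per_dim=per_dim,
            kde=kde,
            kde_bandwidth=float(kde.factor),
            **common,
        )

    sd_v = float(np.std(d_v, ddof=1))
    cov = np.cov(finals.T)
    r2 = _gaussian_r2(d_v, mean[1], sd_v, lb_v, ub_v)
    if r2 > GAUSSIAN_R2_THRESHOLD:
        return ShiftDistribution(
            form="gaussian",
            mean=mean,
            cov=cov,
            r_squared=r2,
            r_squared_per_dim=(r2,),
            **common,
        )
    kde = stats.gaussian_kde(d_v, bw_method="silverman")
    return ShiftDistribution(
        form="kde",
        mean=mean,
        cov=cov,
        r_squared=r2,
        r_squared_per_dim=(r2,),
        kde=kde,
        kde_bandwidth=float(kde.factor),
        **common,
    )
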