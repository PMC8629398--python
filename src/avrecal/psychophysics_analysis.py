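"""Descriptive analysis of the behavioral trial logs.

Implements the data-preparation chain used before model fitting: cumulative-
Gaussian psychometric fits with a lapse rate capped at 6%, JND and PSE
extraction, the PSE-vs-auditory-location regression yielding the perceptually
aligned visual locations, z-score outlier filtering with the study's pooling
rules, common-slope localization regressions, sign-coded recalibration
effects, and stratified percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .experiment_simulator import ExperimentDesign

__all__ = [
    "PsychometricFit",
    "BiasEstimate",
    "RecalibrationEffect",
    "fit_psychometric",
    "jnd_from_fit",
    "pse_from_fit",
    "regress_pses",
    "estimate_bias_from_bimodal",
    "filter_outliers",
    "fit_localization_regressions",
    "recalibration_effect",
    "bootstrap_ci",
    "analyze_study",
]

LAPSE_BOUND = 0.06
Z_CUTOFF = 3.0


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit with lapse.

    The response probability model is ``p(x) = lapse/2 + (1-lapse) *
    Phi((x - center)/sd)``; ``center`` is fixed at 0 for the unimodal
    discrimination task and free for the bimodal per-location fits.  JND and
    PSE are read off the *unscaled* (lapse-free) function.
    """

    center: float
    sd: float
    lapse: float
    adjusted_r2: float
    bin_width: float
    converged: bool
    n_trials: int
    loglik: float


@dataclass
class BiasEstimate:
    """Linear description of the four bimodal PSEs: PSE = slope*s_A + intercept."""

    slope: float
    intercept: float
    pse: np.ndarray
    auditory_locations: np.ndarray
    aligned_visual_locations: np.ndarray
    slope_ci: tuple[float, float] | None = None
    intercept_ci: tuple[float, float] | None = None


@dataclass
class RecalibrationEffect:
    """Post-minus-pre intercept difference, sign-coded so that shifts
    compensating for the audiovisual discrepancy are positive."""

    modality: str
    reliability_level: int
    direction: str
    effect: float
    ci: tuple[float, float] | None = None


def _nll(theta, x, r, center_fixed):
    if center_fixed:
        sd, lapse = theta
        center = 0.0
    else:
        center, sd, lapse = theta
    p = 0.5 * lapse + (1.0 - lapse) * stats.norm.cdf((x - center) / sd)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p))


def fit_psychometric(
    x,
    responses,
    center_fixed: bool = True,
    bin_width: float = 1.8,
    center_bounds: tuple[float, float] = (-40.0, 40.0),
    init: tuple | None = None,
) -> PsychometricFit:
    """Fit a lapse-contaminated cumulative Gaussian by maximum likelihood.

    Multi-start over an (sd, lapse) grid to escape the lapse-boundary local
    optimum; an explicit ``init`` ((sd, lapse) or (center, sd, lapse))
    replaces the grid with a single start, which is the usual choice for
    bootstrap refits initialized at the point estimate.  ``adjusted_r2`` is
    computed on binned response proportions (bins of ``bin_width`` anchored
    at 0, empty bins dropped).
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(responses, dtype=float)
    n = x.size
    if np.unique(r).size < 2:
        warnings.warn("all responses identical; psychometric fit is degenerate",
                      RuntimeWarning)
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, bin_width,
                               False, n, np.nan)

    if center_fixed:
        bounds = [(0.05, 60.0), (0.0, LAPSE_BOUND)]
        starts = [(1.0, 0.02), (4.0, 0.02), (10.0, 0.05)]
    else:
        # crude center init: location where the response proportion crosses 0.5
        order = np.argsort(x)
        c0 = float(np.interp(0.5, np.clip(np.cumsum(r[order]) / max(r.sum(), 1), 0, 1),
                             x[order])) if r.sum() > 0 else 0.0
        c0 = float(np.clip(c0, *center_bounds))
        bounds = [center_bounds, (0.05, 60.0), (0.0, LAPSE_BOUND)]
        starts = [(c0, 2.0, 0.02), (c0, 6.0, 0.02), (0.0, 4.0, 0.05)]
    if init is not None:
        starts = [tuple(init)]

    best = None
    for theta0 in starts:
        res = optimize.minimize(
            _nll, np.asarray(theta0), args=(x, r, center_fixed),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and np.isfinite(best.fun)
    if center_fixed:
        center, (sd, lapse) = 0.0, best.x
        k = 2
    else:
        center, sd, lapse = best.x
        k = 3

    # binned adjusted R^2 (bins anchored at 0)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    obs, centers = [], []
    for b in np.unique(idx):
        mask = idx == b
        obs.append(r[mask].mean())
        centers.append(0.5 * (edges[b] + edges[b + 1]))
    obs = np.asarray(obs)
    centers = np.asarray(centers)
    pred = 0.5 * lapse + (1.0 - lapse) * stats.norm.cdf((centers - center) / sd)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    nb = obs.size
    if ss_tot > 0 and nb > k + 1:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (nb - 1) / (nb - k - 1)
    else:
        adj_r2 = np.nan
    return PsychometricFit(float(center), float(sd), float(lapse), adj_r2,
                           bin_width, converged, n, -float(best.fun))


def jnd_from_fit(fit: PsychometricFit) -> float:
    """JND = half the 25%-75% distance of the unscaled function
    = Phi^-1(0.75) * sd."""
    return float(stats.norm.ppf(0.75) * fit.sd)


def pse_from_fit(fit: PsychometricFit) -> float:
    """PSE = 50% point of the unscaled function (the fitted center)."""
    return float(fit.center)


def regress_pses(pses, auditory_locations) -> BiasEstimate:
    """Ordinary least squares of the four PSEs on auditory location; the
    aligned visual locations are the fitted line evaluated at the auditory
    locations."""
    pses = np.asarray(pses, dtype=float)
    locs = np.asarray(auditory_locations, dtype=float)
    slope, intercept = np.polyfit(locs, pses, 1)
    return BiasEstimate(
        slope=float(slope),
        intercept=float(intercept),
        pse=pses,
        auditory_locations=locs,
        aligned_visual_locations=slope * locs + intercept,
    )


def estimate_bias_from_bimodal(
    bimodal_trials: pd.DataFrame,
    design: ExperimentDesign = ExperimentDesign(),
    bin_width: float = 3.0,
) -> BiasEstimate:
    """Fit one psychometric function per auditory standard location and
    regress the PSEs on auditory location."""
    pses = []
    for s_a in design.auditory_locations:
        g = bimodal_trials[np.isclose(bimodal_trials["standard_location"], s_a)]
        fit = fit_psychometric(
            g["s_V"].to_numpy(), g["response"].to_numpy(),
            center_fixed=False, bin_width=bin_width,
        )
        pses.append(pse_from_fit(fit))
    return regress_pses(pses, design.auditory_locations)


def _zscore_filter(df, mean_groups, sd_groups):
    """Demean per ``mean_groups``, compute SDs of the demeaned residuals per
    ``sd_groups``, drop |z| > 3.  Zero-SD groups are left untouched."""
    demeaned = df["response"] - df.groupby(mean_groups, dropna=False)[
        "response"
    ].transform("mean")
    sd = demeaned.groupby(
        [df[g] for g in sd_groups] if sd_groups else np.zeros(len(df))
    ).transform("std")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = demeaned / sd
    bad_sd = ~np.isfinite(sd) | (sd == 0)
    if bad_sd.any():
        warnings.warn("zero/undefined group SD; affected trials kept",
                      RuntimeWarning)
    keep = bad_sd | (z.abs() <= Z_CUTOFF)
    return keep


def filter_outliers(trials: pd.DataFrame, grouping_policy: str):
    """Remove |z| > 3 responses following the study's pooling rules.

    ``grouping_policy='pointing'``: demean per stimulus location; one SD over
    all demeaned responses.

    ``grouping_policy='localization'``: demean pre-phase responses per
    (modality, location) pooled across sessions and post-phase responses per
    (condition, modality, location); auditory SD pooled over all sessions and
    phases, visual SD per reliability level.

    Returns ``(kept_trials, report)`` where the report maps group labels to
    exclusion fractions.
    """
    df = trials.copy()
    if grouping_policy == "pointing":
        df = df[df["task"] == "pointing"]
        demeaned = df["response"] - df.groupby("s_V")["response"].transform("mean")
        sd = float(demeaned.std())
        if sd == 0 or not np.isfinite(sd):
            warnings.warn("zero SD in pointing responses; nothing removed",
                          RuntimeWarning)
            return df, {"pointing": 0.0}
        keep = (demeaned / sd).abs() <= Z_CUTOFF
        return df[keep], {"pointing": float(1.0 - keep.mean())}

    if grouping_policy == "localization":
        df = df[df["task"] == "localization"].copy()
        loc = df["s_A"].where(df["modality"] == "A", df["s_V"])
        df["_loc"] = loc
        pre = df["phase"] == "pre"
        mean_key = pd.Series("", index=df.index, dtype=object)
        mean_key[pre] = (
            "pre|" + df.loc[pre, "modality"] + "|" + df.loc[pre, "_loc"].astype(str)
        )
        mean_key[~pre] = (
            "post|" + df.loc[~pre, "modality"] + "|"
            + df.loc[~pre, "reliability"].astype(str) + "|"
            + df.loc[~pre, "direction"] + "|" + df.loc[~pre, "_loc"].astype(str)
        )
        demeaned = df["response"] - df.groupby(mean_key)["response"].transform("mean")
        sd_key = pd.Series("A", index=df.index, dtype=object)
        vis = df["modality"] == "V"
        sd_key[vis] = "V" + df.loc[vis, "reliability"].astype(int).astype(str)
        sd = demeaned.groupby(sd_key).transform("std")
        with np.errstate(invalid="ignore", divide="ignore"):
            z = demeaned / sd
        bad = ~np.isfinite(sd) | (sd == 0)
        if bad.any():
            warnings.warn("zero/undefined group SD; affected trials kept",
                          RuntimeWarning)
        keep = bad | (z.abs() <= Z_CUTOFF)
        report = {
            str(k): float(1.0 - keep[sd_key == k].mean()) for k in sd_key.unique()
        }
        out = df[keep].drop(columns="_loc")
        return out, report

    raise ValueError(f"unknown grouping policy {grouping_policy!r}")


def fit_localization_regressions(
    localization_trials: pd.DataFrame, modality: str
) -> dict:
    """Joint least squares of localization responses on stimulus location:
    one shared slope, seven intercepts (pooled pre + six post conditions).

    Returns ``{'slope': s, 'intercepts': {'pre': b0, (i, direction): b}}``.
    """
    df = localization_trials
    df = df[(df["task"] == "localization") & (df["modality"] == modality)]
    loc = df["s_A"] if modality == "A" else df["s_V"]
    conditions = sorted(
        {(int(i), d) for i, d in
         zip(df.loc[df["phase"] == "post", "reliability"],
             df.loc[df["phase"] == "post", "direction"])},
        key=lambda c: (c[0], c[1]),
    )
    groups = ["pre"] + conditions
    n = len(df)
    X = np.zeros((n, 1 + len(groups)))
    X[:, 0] = loc.to_numpy(dtype=float)
    pre_mask = (df["phase"] == "pre").to_numpy()
    X[pre_mask, 1] = 1.0
    for k, (i, d) in enumerate(conditions, start=2):
        mask = (
            (df["phase"] == "post")
            & (df["reliability"] == i)
            & (df["direction"] == d)
        ).to_numpy()
        X[mask, k] = 1.0
    y = df["response"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercepts = {"pre": float(beta[1])}
    for k, cond in enumerate(conditions, start=2):
        intercepts[cond] = float(beta[k])
    return {"slope": float(beta[0]), "intercepts": intercepts}


def recalibration_effect(
    regressions: dict, condition: tuple[int, str], modality: str
) -> RecalibrationEffect:
    """Intercept difference post - pre, sign-flipped per direction so that a
    shift compensating for the discrepancy is positive.

    In a V-right-of-A session the compensating auditory shift is rightward
    (+) and the compensating visual shift is leftward (-); in a V-left
    session the signs are mirrored.
    """
    i, direction = condition
    sign = 1.0 if direction == "V_right" else -1.0
    if modality == "V":
        sign = -sign
    diff = regressions["intercepts"][condition] - regressions["intercepts"]["pre"]
    return RecalibrationEffect(
        modality=modality, reliability_level=i, direction=direction,
        effect=float(sign * diff),
    )


def bootstrap_ci(
    statistic_fn,
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    strata=None,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``statistic_fn(resampled_data)``.

    ``strata`` (optional column name or array of labels) restricts resampling
    to within-stratum draws, respecting the study's per-location/session/
    modality stratification.
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    if strata is None:
        labels = np.zeros(n)
    elif isinstance(strata, str):
        labels = data[strata].to_numpy()
    else:
        labels = np.asarray(strata)
    groups = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    stats_out = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([g[rng.integers(0, g.size, g.size)] for g in groups])
        stats_out[b] = statistic_fn(data.iloc[idx])
    lo, hi = np.percentile(stats_out, percentiles)
    return float(lo), float(hi)


def analyze_study(
    dataset,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Per-observer descriptive report: JNDs with bootstrap CIs, the PSE
    regression (bias estimate), pointing precision, and sign-coded
    recalibration effects per condition and modality."""
    trials = dataset.trials
    design = dataset.design
    rng_seed = np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31)

    report: dict = {"jnd": {}, "jnd_ci": {}}
    for cond in ("A", "V1", "V2", "V3"):
        g = trials[
            (trials["task"] == "unimodal_discrimination")
            & (trials["condition"] == cond)
        ]
        fit = fit_psychometric(g["test_location"].to_numpy(),
                               g["response"].to_numpy(), center_fixed=True)
        report["jnd"][cond] = jnd_from_fit(fit)
        if n_boot:
            report["jnd_ci"][cond] = bootstrap_ci(
                lambda d: jnd_from_fit(
                    fit_psychometric(d["test_location"].to_numpy(),
                                     d["response"].to_numpy(), center_fixed=True)
                ),
                g, n_boot=n_boot, seed=rng_seed,
            )

    bimodal = trials[trials["task"] == "bimodal_discrimination"]
    bias = estimate_bias_from_bimodal(bimodal, design)
    if n_boot:
        bias.slope_ci = bootstrap_ci(
            lambda d: estimate_bias_from_bimodal(d, design).slope,
            bimodal, n_boot=n_boot, seed=rng_seed + 1, strata="standard_location",
        )
        bias.intercept_ci = bootstrap_ci(
            lambda d: estimate_bias_from_bimodal(d, design).intercept,
            bimodal, n_boot=n_boot, seed=rng_seed + 2, strata="standard_location",
        )
    report["bias"] = bias

    pointing, point_report = filter_outliers(trials, "pointing")
    resid = pointing["response"] - pointing["s_V"]
    report["sigma_r"] = float(np.sqrt(np.mean(resid ** 2)))
    report["pointing_exclusions"] = point_report

    loc, loc_report = filter_outliers(trials, "localization")
    report["localization_exclusions"] = loc_report
    report["recalibration_effects"] = {}
    for modality in ("A", "V"):
        regs = fit_localization_regressions(loc, modality)
        for cond in regs["intercepts"]:
            if cond == "pre":
                continue
            eff = recalibration_effect(regs, cond, modality)
            report["recalibration_effects"][(modality, *cond)] = eff.effect
    return report
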