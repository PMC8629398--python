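"""End-to-end orchestration: simulate a study, analyze it, fit and compare
all four recalibration models, run model-behavior sweeps, and run
model-recovery experiments.

Everything is driven by a :class:`StudyConfig`, which fully determines every
random draw of a run (one root seed; per-stage streams derived from it).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model_inference as mi
from . import psychophysics_analysis as ppa
from .experiment_simulator import StudyDataset, generate_full_study
from .observer_core import ObserverParams
from .recalibration_dynamics import (
    MODEL_IDS,
    RecalibrationDesign,
    simulate_final_shifts,
)

__all__ = [
    "StudyConfig",
    "run_study",
    "run_sweeps",
    "reliability_sweep",
    "posterior_surface",
    "bias_sweep",
    "model_recovery",
]


@dataclass
class StudyConfig:
    """Fully reproducible configuration of one pipeline run."""

    observer: ObserverParams = field(default_factory=ObserverParams)
    generating_model: str = "CI"
    seed: int = 0
    out_dir: str = "study_out"
    # fitting budget (reduced defaults; --full-scale restores 20 / 1000)
    n_starts: int = 5
    n_sims: int = 500
    maxfev: int = 300
    n_boot: int = 200
    full_scale: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.generating_model not in MODEL_IDS:
            raise ValueError(f"unknown generating model {self.generating_model!r}")
        if self.full_scale:
            self.n_starts = 20
            self.n_sims = 1000
            self.n_boot = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        obs = raw.pop("observer", None)
        cfg = cls(**raw)
        if obs is not None:
            for key in ("sigma_V_uni", "sigma_V_bi", "lapse_V"):
                if key in obs:
                    obs[key] = tuple(obs[key])
            cfg.observer = ObserverParams(**obs)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _plot_report(report: dict, dataset: StudyDataset, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    conds = ["V1", "V2", "V3"]
    jnds = [report["jnd"][c] for c in conds]
    axes[0].bar(conds, jnds, color="tab:pink")
    axes[0].axhline(report["jnd"]["A"], color="tab:blue", label="auditory")
    axes[0].set_ylabel("JND (deg)")
    axes[0].set_title("Spatial discrimination")
    axes[0].legend()

    bias = report["bias"]
    axes[1].plot(bias.auditory_locations, bias.pse, "o", label="PSE")
    xs = np.linspace(-10, 10, 2)
    axes[1].plot(xs, bias.slope * xs + bias.intercept, "-",
                 label=f"slope {bias.slope:.2f}")
    axes[1].plot(xs, xs, "--", color="grey", lw=0.8)
    axes[1].set_xlabel("auditory location (deg)")
    axes[1].set_ylabel("PSE (deg)")
    axes[1].set_title("Modality-specific bias")
    axes[1].legend()

    effects = report["recalibration_effects"]
    for modality, color in (("A", "tab:blue"), ("V", "tab:pink")):
        for direction, marker in (("V_left", "o"), ("V_right", "s")):
            lv = [1, 2, 3]
            ys = [effects[(modality, i, direction)] for i in lv]
            axes[2].plot(lv, ys, marker=marker, color=color,
                         label=f"{modality} {direction}")
    axes[2].axhline(0, color="grey", lw=0.8)
    axes[2].set_xticks([1, 2, 3])
    axes[2].set_xlabel("visual reliability level")
    axes[2].set_ylabel("recalibration effect (deg)")
    axes[2].set_title("Recalibration")
    axes[2].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "analysis.png", dpi=120)
    plt.close(fig)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, Path)):
        return _json_ready(vars(obj))
    return obj


def run_study(config: StudyConfig) -> Path:
    """simulate -> analyze -> fit all four models -> compare.

    Writes the trial logs, an analysis report (JSON + plot), one fit-result
    JSON per model, a comparison CSV and a manifest into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(3)]

    dataset = generate_full_study(
        config.observer, config.generating_model, seed=seeds[0]
    )
    dataset.save(out / "data")

    report = ppa.analyze_study(dataset, n_boot=config.n_boot, seed=seeds[1])
    with open(out / "analysis.json", "w") as fh:
        json.dump(_json_ready(report), fh, indent=2)
    if config.make_plots:
        _plot_report(report, dataset, out)

    results = mi.fit_all_models(
        dataset, n_starts=config.n_starts, seed=seeds[2],
        n_sims=config.n_sims, maxfev=config.maxfev,
    )
    for r in results:
        r.to_json(out / f"fit_{r.model_id}.json")
    table = mi.compare_models(results)
    table.to_csv(out / "model_comparison.csv", index=False)

    manifest = {
        "config": _json_ready(asdict(config)),
        "stage_seeds": seeds,
        "winner": table["model_id"].iloc[0],
        "package_version": __import__("avrecal").__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


# ---------------------------------------------------------------------------
# model-behavior sweeps
# ---------------------------------------------------------------------------

def _mean_auditory_recalibration(
    model_id: str,
    params: ObserverParams,
    n_sims: int,
    rng: np.random.Generator,
    discrepancy: float = 5.5,
) -> tuple[float, float]:
    """Mean compensating final shifts (auditory, visual) for a V-right
    session at reliability level 1 with the given perceptual discrepancy."""
    pairs = tuple(
        (s_a, params.bias_slope * s_a + params.bias_intercept + discrepancy)
        for s_a in (-7.5, -2.5, 2.5)
    )
    design = RecalibrationDesign(pairs=pairs, reliability_level=1,
                                 direction="V_right")
    finals = simulate_final_shifts(model_id, params, design, n_sims, rng)
    return float(finals[:, 0].mean()), float(-finals[:, 1].mean())


def reliability_sweep(
    model_id: str,
    params: ObserverParams,
    sigma_v_grid=(1.0, 3.0, 6.0, 12.0),
    n_sims: int = 300,
    seed: int = 0,
    discrepancy: float = 5.5,
) -> pd.DataFrame:
    """Mean auditory/visual recalibration as a function of the bimodal visual
    SD (one model, remaining parameters fixed)."""
    rng = np.random.default_rng(seed)
    rows = []
    for sv in sigma_v_grid:
        p = ObserverParams(**{
            **asdict(params),
            "sigma_V_bi": (sv, sv, sv),
            "sigma_V_uni": (max(params.sigma_V_uni[0], sv / 5 + 0.1),) * 3,
        })
        rec_a, rec_v = _mean_auditory_recalibration(
            model_id, p, n_sims, rng, discrepancy
        )
        rows.append({"model_id": model_id, "sigma_V_bi": sv,
                     "recal_A": rec_a, "recal_V": rec_v})
    return pd.DataFrame(rows)


def posterior_surface(
    params: ObserverParams,
    discrepancies=np.linspace(0.0, 20.0, 21),
    p_common_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
) -> pd.DataFrame:
    """Posterior probability of a common cause and the auditory
    estimate-measurement distance as functions of the measurement discrepancy
    and the common-cause prior (noise-free measurement grid)."""
    from .observer_core import MeasurementPair, final_estimates, posterior_common

    rows = []
    for pc in p_common_grid:
        p = ObserverParams(**{**asdict(params), "p_common": pc})
        for d in discrepancies:
            m = MeasurementPair(0.0, float(d), 1)
            post = posterior_common(m, p)
            s_hat_a, _ = final_estimates(m, p)
            rows.append({
                "p_common": pc,
                "discrepancy": float(d),
                "posterior_c1": float(post.p_c1_given_m),
                "auditory_pull": float(s_hat_a - 0.0),
            })
    return pd.DataFrame(rows)


def bias_sweep(
    params: ObserverParams,
    slopes=(0.8, 1.0, 1.2),
    intercepts=(-2.0, 0.0, 2.0),
    alignment: str = "perceptual",
    n_sims: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean causal-inference recalibration as a function of the remapping
    bias, with the audiovisual pairs constructed either in perceptual space
    (one step of the *perceived*-aligned locations, as in the study) or in
    physical space (constant physical offset)."""
    rng = np.random.default_rng(seed)
    rows = []
    a_locs = np.array([-7.5, -2.5, 2.5, 7.5])
    for a in slopes:
        for b in intercepts:
            p = ObserverParams(**{**asdict(params),
                                  "bias_slope": a, "bias_intercept": b})
            if alignment == "perceptual":
                v = a * a_locs + b
                pairs = tuple((a_locs[l], float(v[l + 1])) for l in range(3))
            elif alignment == "physical":
                pairs = tuple((a_locs[l], float(a_locs[l + 1])) for l in range(3))
            else:
                raise ValueError(f"unknown alignment {alignment!r}")
            design = RecalibrationDesign(pairs=pairs, reliability_level=1,
                                         direction="V_right")
            finals = simulate_final_shifts("CI", p, design, n_sims, rng)
            rows.append({
                "bias_slope": a, "bias_intercept": b, "alignment": alignment,
                "recal_A": float(finals[:, 0].mean()),
                "recal_V": float(-finals[:, 1].mean()),
            })
    return pd.DataFrame(rows)


#: Causal-inference parameter sets spanning the model's qualitative
#: repertoire of auditory recalibration vs. bimodal visual SD (grid 1-12
#: deg): the profile shape is governed by where the posterior-of-common-cause
#: transition falls relative to the reliability weighting.  Larger
#: audiovisual discrepancies push the transition toward less reliable vision,
#: turning the decreasing profile into a peaked and finally an increasing one.
CI_REPERTOIRE_SETS: dict[str, dict] = {
    "decreasing": {"sigma_A_bi": 6.0, "p_common": 0.7, "alpha": 0.01,
                   "discrepancy": 5.5},
    "peaked": {"sigma_A_bi": 2.5, "p_common": 0.9, "alpha": 0.03,
               "discrepancy": 16.0},
    "increasing": {"sigma_A_bi": 2.5, "p_common": 0.6, "alpha": 0.03,
                   "discrepancy": 30.0},
}


def ci_repertoire_sweep(
    sigma_v_grid=(1.0, 3.0, 6.0, 12.0),
    n_sims: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean auditory recalibration of the causal-inference model over the
    visual-reliability grid for the three qualitative-regime parameter
    sets."""
    rng = np.random.default_rng(seed)
    rows = []
    for regime, spec in CI_REPERTOIRE_SETS.items():
        for sv in sigma_v_grid:
            params = ObserverParams(
                sigma_A_bi=spec["sigma_A_bi"],
                sigma_V_bi=(sv, sv, sv),
                sigma_A_uni=max(4.5, spec["sigma_A_bi"] / 5 + 0.1),
                sigma_V_uni=(max(1.5, sv / 5 + 0.1),) * 3,
                p_common=spec["p_common"],
                alpha_A=spec["alpha"],
                alpha_V=spec["alpha"],
            )
            rec_a, rec_v = _mean_auditory_recalibration(
                "CI", params, n_sims, rng, discrepancy=spec["discrepancy"],
            )
            rows.append({"regime": regime, "sigma_V_bi": sv,
                         "recal_A": rec_a, "recal_V": rec_v,
                         **spec})
    return pd.DataFrame(rows)


def run_sweeps(config: StudyConfig) -> Path:
    """Model-behavior sweeps: recalibration vs. visual reliability per model
    and learning rate, the causal-posterior surface, and the bias sweep."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed

    frames = []
    base = asdict(config.observer)
    for rate_label, scale in (("slow", 1.0), ("fast", 3.0)):
        for model_id, pdict in (
            ("RB", {**base, "alpha_A": 0.005 * scale, "alpha_V": 0.005 * scale}),
            ("FR", {**base, "alpha_A": 0.01 * scale, "alpha_V": 0.005 * scale}),
            ("CI", {**base, "alpha_A": 0.01 * scale, "alpha_V": 0.01 * scale}),
        ):
            df = reliability_sweep(model_id, ObserverParams(**pdict),
                                   n_sims=config.n_sims // 2 or 100,
                                   seed=rng_seed)
            df["learning_rate"] = rate_label
            frames.append(df)
    rel = pd.concat(frames, ignore_index=True)
    rel.to_csv(out / "sweep_reliability.csv", index=False)

    post = posterior_surface(config.observer)
    post.to_csv(out / "sweep_posterior.csv", index=False)

    bias_frames = [
        bias_sweep(config.observer, alignment=al,
                   n_sims=config.n_sims // 2 or 100, seed=rng_seed)
        for al in ("perceptual", "physical")
    ]
    bias = pd.concat(bias_frames, ignore_index=True)
    bias.to_csv(out / "sweep_bias.csv", index=False)

    if config.make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, rate in zip(axes, ("slow", "fast")):
            for model_id, style in (("RB", "-."), ("FR", "--"), ("CI", "-")):
                g = rel[(rel.model_id == model_id) & (rel.learning_rate == rate)]
                ax.plot(g.sigma_V_bi, g.recal_A, style, label=model_id)
            ax.set_xlabel("bimodal visual SD (deg)")
            ax.set_title(f"{rate} learning")
        axes[0].set_ylabel("auditory recalibration (deg)")
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(out / "sweep_reliability.png", dpi=120)
        plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# model recovery
# ---------------------------------------------------------------------------

#: Generating observers used for model recovery: strong learning rates, and
#: parameter regimes in which each update rule leaves its own signature.
#: The causal-inference generators use a small bimodal auditory SD and a low
#: common-cause prior, so the posterior P(C=1|m) -- and with it the total
#: compensation -- varies strongly across visual-reliability levels, a
#: pattern the reliability-based and fixed-ratio rules cannot produce.  The
#: fixed-ratio generator recalibrates vision more than audition, breaking the
#: reliability-based coupling between update ratio and update size.
RECOVERY_GENERATORS: dict[str, ObserverParams] = {
    "RB": ObserverParams(alpha_A=0.02, alpha_V=0.02),
    "FR": ObserverParams(alpha_A=0.012, alpha_V=0.15),
    "CI": ObserverParams(sigma_A_bi=0.9, sigma_V_bi=(0.6, 1.5, 9.0),
                         p_common=0.05, alpha_A=0.24, alpha_V=0.04),
    "CI_tied": ObserverParams(sigma_A_bi=0.9, sigma_V_bi=(0.6, 1.5, 9.0),
                              p_common=0.05, alpha_A=0.12, alpha_V=0.12),
}


def model_recovery(
    n_replicates: int = 10,
    generators: dict | None = None,
    seed: int = 0,
    n_starts: int = 1,
    n_sims: int = 100,
    maxfev: int | dict = None,
    n_sims_final: int = 600,
) -> pd.DataFrame:
    """Simulate ``n_replicates`` studies per generating model, fit all four
    models to each, and tabulate which model wins the AIC comparison.

    Returns a tidy frame (one row per generated dataset) from which the
    confusion matrix can be cross-tabulated; each row also records the
    generating model's own fitted dynamics parameters.
    """
    generators = generators or RECOVERY_GENERATORS
    if maxfev is None:
        # the RB/FR objectives are cheap; spend more evaluations there
        maxfev = {"RB": 150, "FR": 150, "CI": 80, "CI_tied": 80}
    rows = []
    for g_idx, (gen_id, gen_params) in enumerate(generators.items()):
        for rep in range(n_replicates):
            data_seed = (seed * 7919 + rep * 104729 + g_idx * 613) % (2 ** 31 - 1)
            dataset = generate_full_study(gen_params, gen_id, seed=data_seed)
            results = mi.fit_all_models(
                dataset, n_starts=n_starts, seed=seed + rep,
                n_sims=n_sims, maxfev=maxfev, n_sims_final=n_sims_final,
            )
            table = mi.compare_models(results)
            own = next(r for r in results if r.model_id == gen_id)
            rows.append({
                "generating": gen_id,
                "replicate": rep,
                "winner": table["model_id"].iloc[0],
                **{f"aic_{r.model_id}": r.aic for r in results},
                "theta3_gen": json.dumps(own.theta3),
            })
    return pd.DataFrame(rows)
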