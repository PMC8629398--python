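"""Synthetic-observer simulation of the complete behavioral protocol.

Generates tidy trial logs for all five tasks of the audiovisual
recalibration study:

1. unimodal spatial discrimination (2IFC, 4 interleaved adaptive staircases;
   one session per stimulus condition A, V1, V2, V3) -- 176 trials each;
2. bimodal spatial discrimination (visual vs. auditory, 8 staircases over 4
   auditory locations) -- 320 trials;
3. pointing practice (direct localization of a maximally reliable visual
   stimulus) -- 240 trials;
4. unimodal localization (pre- and post-recalibration) -- 96 trials per phase;
5. bimodal localization / recalibration phase (3 discrepant audiovisual pairs
   x 40 repetitions) -- 120 trials per session.

The full study comprises six recalibration sessions (3 visual-reliability
levels x 2 recalibration directions).  As in the real protocol, the visual
stimulus locations of the localization tasks are *not* ground truth: they are
derived from the simulated observer's own bimodal-discrimination data via a
PSE regression, so analysis and model fitting exercise the same dependency
chain as the study.

Trial-log column dictionary (unused fields are NaN/empty):

==================  =====================================================
column              meaning
==================  =====================================================
task                one of ``unimodal_discrimination``,
                    ``bimodal_discrimination``, ``pointing``,
                    ``localization``, ``recalibration``
condition           stimulus condition of discrimination sessions
                    (``A``, ``V1``, ``V2``, ``V3``) or empty
reliability         visual-reliability level of the recalibration session
direction           ``V_left`` / ``V_right`` recalibration direction
phase               ``pre`` / ``recal`` / ``post`` or empty
modality            cued/tested modality of localization trials (A or V)
s_A, s_V            physical stimulus locations (deg)
test_location       test-stimulus location of discrimination trials (deg)
standard_location   standard-stimulus location (deg)
staircase_id        staircase bookkeeping index
is_catch            catch-trial flag (discrimination tasks)
response            0/1 (discrimination) or degrees (localization tasks)
trial               within-session trial index (0-based)
==================  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .observer_core import ObserverParams, MeasurementPair, final_estimates
from .recalibration_dynamics import (
    RecalibrationDesign,
    ShiftState,
    ShiftTrajectory,
    update_causal_inference,
    update_fixed_ratio,
    update_reliability_based,
)

__all__ = [
    "TRIAL_COLUMNS",
    "ExperimentDesign",
    "StaircaseState",
    "StudyDataset",
    "simulate_2ifc_response",
    "step_staircase",
    "run_unimodal_discrimination_session",
    "run_bimodal_discrimination_session",
    "run_pointing_practice",
    "run_localization_phase",
    "run_recalibration_phase",
    "make_recalibration_design",
    "generate_full_study",
    "write_trial_log",
    "read_trial_log",
]

TRIAL_COLUMNS = [
    "task",
    "condition",
    "reliability",
    "direction",
    "phase",
    "modality",
    "s_A",
    "s_V",
    "test_location",
    "standard_location",
    "staircase_id",
    "is_catch",
    "response",
    "trial",
]

STEP_SCHEDULE = (1.9, 1.0, 0.5)


@dataclass(frozen=True)
class ExperimentDesign:
    """Stimulus geometry and trial counts of the study protocol."""

    auditory_locations: tuple[float, ...] = (-7.5, -2.5, 2.5, 7.5)
    blob_spreads: tuple[float, float, float] = (1.1, 5.4, 8.7)  # metadata only
    staircase_start_uni: float = 12.5
    staircase_trials_uni: int = 40
    catch_every_uni: int = 10
    catch_location_uni: float = 12.5
    staircase_start_bi: float = 15.0
    staircase_trials_bi: int = 36
    catch_every_bi: int = 9
    catch_offset_bi: float = 15.0
    step_schedule: tuple[float, float, float] = STEP_SCHEDULE
    pointing_locations: tuple[float, ...] = tuple(np.arange(-17.5, 18.0, 5.0))
    pointing_repeats: int = 30
    localization_repeats: int = 12
    recalibration_repeats: int = 40
    directions: tuple[str, str] = ("V_left", "V_right")

    # -- derived session totals --------------------------------------------
    @property
    def n_unimodal_discrimination(self) -> int:
        n_stair = 4 * self.staircase_trials_uni
        return n_stair + n_stair // self.catch_every_uni

    @property
    def n_bimodal_discrimination(self) -> int:
        n_stair = 8 * self.staircase_trials_bi
        return n_stair + n_stair // self.catch_every_bi

    @property
    def n_pointing(self) -> int:
        return len(self.pointing_locations) * self.pointing_repeats

    @property
    def n_localization(self) -> int:
        return 2 * len(self.auditory_locations) * self.localization_repeats

    @property
    def n_recalibration(self) -> int:
        return 3 * self.recalibration_repeats


@dataclass
class StaircaseState:
    """State of one transformed up-down staircase.

    ``rule`` is ``2D1U`` (two consecutive "right" responses move the test
    stimulus down/leftward; converges to the 70.7% point) or ``1D2U``
    (converges to the 29.3% point).  The step starts at 1.9 deg, drops to
    1.0 deg after the first reversal and to 0.5 deg after the third.
    """

    level: float
    rule: str
    step: float = STEP_SCHEDULE[0]
    step_schedule: tuple[float, float, float] = STEP_SCHEDULE
    reversal_count: int = 0
    consecutive: int = 0
    last_move: int = 0
    trials_done: int = 0
    history: list = field(default_factory=list)
    reversal_levels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rule not in ("2D1U", "1D2U"):
            raise ValueError(f"unknown staircase rule {self.rule!r}")


def step_staircase(state: StaircaseState, response: int) -> StaircaseState:
    """Apply one response to the staircase (mutates and returns ``state``).

    Down = leftward movement of the test stimulus (negative direction).
    """
    r = int(response)
    state.history.append((state.level, r))
    if state.rule == "2D1U":
        if r == 1:
            state.consecutive += 1
            move = -1 if state.consecutive >= 2 else 0
            if move:
                state.consecutive = 0
        else:
            move = 1
            state.consecutive = 0
    else:  # 1D2U
        if r == 1:
            move = -1
            state.consecutive = 0
        else:
            state.consecutive += 1
            move = 1 if state.consecutive >= 2 else 0
            if move:
                state.consecutive = 0
    if move:
        if state.last_move and move != state.last_move:
            state.reversal_count += 1
            state.reversal_levels.append(state.level)
            if state.reversal_count >= 3:
                state.step = state.step_schedule[2]
            elif state.reversal_count >= 1:
                state.step = state.step_schedule[1]
        state.level += move * state.step
        state.last_move = move
    state.trials_done += 1
    return state


def staircase_convergence_probability(
    rule: str = "2D1U",
    psychometric_sd: float = 6.4,
    n_staircases: int = 200,
    n_trials: int = 40,
    seed: int | np.random.Generator = 0,
    last_reversals: int = 10,
) -> float:
    """Empirical convergence point of the transformed up-down staircase.

    Runs ``n_staircases`` staircases (step schedule 1.9/1.0/0.5 deg) against
    a lapse-free cumulative-Gaussian observer ``p(x) = Phi(x / sd)``,
    averages the final reversal levels per staircase (reversals before the
    step reaches its final size are discarded, as usual), and maps the grand
    mean back through the generating psychometric function.  A
    two-down-one-up staircase converges to p = sqrt(0.5) ~ 70.7%.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = []
    for k in range(n_staircases):
        start = 12.5 if k % 2 == 0 else -12.5
        st = StaircaseState(start, rule)
        while st.trials_done < n_trials:
            p = float(stats.norm.cdf(st.level / psychometric_sd))
            step_staircase(st, int(rng.random() < p))
        final_step = st.reversal_levels[3:] or st.reversal_levels
        if final_step:
            levels.append(float(np.mean(final_step[-last_reversals:])))
    return float(stats.norm.cdf(np.mean(levels) / psychometric_sd))


def _shrink_factor(sigma: float, prior_sd: float) -> float:
    return sigma ** -2 / (sigma ** -2 + prior_sd ** -2)


def simulate_2ifc_response(
    test_internal: float,
    standard_internal: float,
    sigma: float,
    lapse: float,
    rng: np.random.Generator,
    sigma_standard: float | None = None,
    prior_mean: float = 0.0,
    prior_sd: float = 100.0,
) -> int:
    """Simulate one 2IFC "test right of standard" judgment.

    Draws one noisy measurement per interval, shrinks each toward the prior
    mean by its reliability, and responds 1 iff the test estimate exceeds the
    standard estimate.  With probability ``lapse`` the response is replaced by
    a fair coin flip.
    """
    if sigma_standard is None:
        sigma_standard = sigma
    m_t = rng.normal(test_internal, sigma)
    m_s = rng.normal(standard_internal, sigma_standard)
    f_t = _shrink_factor(sigma, prior_sd)
    f_s = _shrink_factor(sigma_standard, prior_sd)
    est_t = f_t * m_t + (1.0 - f_t) * prior_mean
    est_s = f_s * m_s + (1.0 - f_s) * prior_mean
    response = int(est_t > est_s)
    if lapse > 0 and rng.random() < lapse:
        response = int(rng.integers(2))
    return response


def _blank_row(**kw) -> dict:
    row = {c: np.nan for c in TRIAL_COLUMNS}
    row.update(task="", condition="", reliability=np.nan, direction="", phase="",
               modality="", staircase_id=-1, is_catch=False)
    row.update(kw)
    return row


def run_unimodal_discrimination_session(
    params: ObserverParams,
    stimulus_condition: str,
    seed: int | np.random.Generator = 0,
    design: ExperimentDesign = ExperimentDesign(),
) -> pd.DataFrame:
    """One unimodal 2IFC session (176 trials): four interleaved 40-trial
    staircases plus one +-12.5 deg catch trial per 10 staircase trials."""
    if stimulus_condition not in ("A", "V1", "V2", "V3"):
        raise ValueError(f"unknown stimulus condition {stimulus_condition!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if stimulus_condition == "A":
        sigma, lapse = params.sigma_A_uni, params.lapse_A
    else:
        level = int(stimulus_condition[1])
        sigma, lapse = params.sigma_v_uni(level), params.lapse_v(level)
    modality = "A" if stimulus_condition == "A" else "V"

    start = design.staircase_start_uni
    stairs = [
        StaircaseState(start, "2D1U", step_schedule=design.step_schedule),
        StaircaseState(start, "1D2U", step_schedule=design.step_schedule),
        StaircaseState(-start, "2D1U", step_schedule=design.step_schedule),
        StaircaseState(-start, "1D2U", step_schedule=design.step_schedule),
    ]

    def respond(test_loc: float) -> int:
        if modality == "A":
            test_int = params.bias_slope * test_loc + params.bias_intercept
            std_int = params.bias_intercept  # standard at 0 deg
        else:
            test_int, std_int = test_loc, 0.0
        return simulate_2ifc_response(
            test_int, std_int, sigma, lapse, rng,
            prior_mean=params.prior_mean, prior_sd=params.prior_sd,
        )

    rows: list[dict] = []
    n_stair_trials = 0
    catch_sign = 1
    trial = 0
    while any(s.trials_done < design.staircase_trials_uni for s in stairs):
        open_ids = [k for k, s in enumerate(stairs)
                    if s.trials_done < design.staircase_trials_uni]
        k = int(open_ids[rng.integers(len(open_ids))])
        sc = stairs[k]
        test_loc = sc.level
        r = respond(test_loc)
        rows.append(_blank_row(
            task="unimodal_discrimination", condition=stimulus_condition,
            modality=modality, test_location=test_loc, standard_location=0.0,
            staircase_id=k, is_catch=False, response=r, trial=trial,
        ))
        step_staircase(sc, r)
        trial += 1
        n_stair_trials += 1
        if n_stair_trials % design.catch_every_uni == 0:
            catch_loc = catch_sign * design.catch_location_uni
            catch_sign = -catch_sign
            r = respond(catch_loc)
            rows.append(_blank_row(
                task="unimodal_discrimination", condition=stimulus_condition,
                modality=modality, test_location=catch_loc,
                standard_location=0.0, staircase_id=-1, is_catch=True,
                response=r, trial=trial,
            ))
            trial += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_bimodal_discrimination_session(
    params: ObserverParams,
    seed: int | np.random.Generator = 0,
    design: ExperimentDesign = ExperimentDesign(),
) -> pd.DataFrame:
    """One bimodal "visual right of auditory?" session (320 trials): eight
    interleaved 36-trial staircases (two per auditory location, starting
    +-15 deg relative to it) plus one +-15 deg catch per 9 staircase trials.

    Staircase levels are visual locations *relative* to the trial's auditory
    stimulus; the emitted ``s_V`` column holds absolute locations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_a, sigma_v = params.sigma_A_uni, params.sigma_v_uni(1)

    stairs: list[tuple[float, StaircaseState]] = []
    for s_a in design.auditory_locations:
        # start right of the auditory stimulus -> 1D2U; left -> 2D1U
        stairs.append((s_a, StaircaseState(design.staircase_start_bi, "1D2U",
                                           step_schedule=design.step_schedule)))
        stairs.append((s_a, StaircaseState(-design.staircase_start_bi, "2D1U",
                                           step_schedule=design.step_schedule)))

    def respond(s_a: float, s_v: float) -> int:
        return simulate_2ifc_response(
            s_v,
            params.bias_slope * s_a + params.bias_intercept,
            sigma_v,
            params.lapse_AV,
            rng,
            sigma_standard=sigma_a,
            prior_mean=params.prior_mean,
            prior_sd=params.prior_sd,
        )

    rows: list[dict] = []
    n_stair_trials = 0
    n_catch = 0
    trial = 0
    while any(sc.trials_done < design.staircase_trials_bi for _, sc in stairs):
        open_ids = [k for k, (_, sc) in enumerate(stairs)
                    if sc.trials_done < design.staircase_trials_bi]
        k = int(open_ids[rng.integers(len(open_ids))])
        s_a, sc = stairs[k]
        s_v = s_a + sc.level
        r = respond(s_a, s_v)
        rows.append(_blank_row(
            task="bimodal_discrimination", s_A=s_a, s_V=s_v,
            test_location=sc.level, standard_location=s_a,
            staircase_id=k, is_catch=False, response=r, trial=trial,
        ))
        step_staircase(sc, r)
        trial += 1
        n_stair_trials += 1
        if n_stair_trials % design.catch_every_bi == 0:
            s_a = design.auditory_locations[n_catch % len(design.auditory_locations)]
            sign = 1 if (n_catch % 2 == 0) else -1
            n_catch += 1
            s_v = s_a + sign * design.catch_offset_bi
            r = respond(s_a, s_v)
            rows.append(_blank_row(
                task="bimodal_discrimination", s_A=s_a, s_V=s_v,
                test_location=sign * design.catch_offset_bi,
                standard_location=s_a, staircase_id=-1, is_catch=True,
                response=r, trial=trial,
            ))
            trial += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_pointing_practice(
    params: ObserverParams,
    seed: int | np.random.Generator = 0,
    design: ExperimentDesign = ExperimentDesign(),
) -> pd.DataFrame:
    """Pointing practice (240 trials): responses are the physical stimulus
    locations perturbed only by pointing noise sigma_r."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    locs = np.repeat(design.pointing_locations, design.pointing_repeats)
    locs = rng.permutation(locs)
    resp = locs + rng.normal(0.0, params.sigma_r, locs.size)
    rows = [
        _blank_row(task="pointing", modality="V", s_V=s, response=r, trial=t)
        for t, (s, r) in enumerate(zip(locs, resp))
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_localization_phase(
    params: ObserverParams,
    phase: str,
    shifts: tuple[float, float],
    reliability_level: int,
    direction: str,
    aligned_visual_locations: np.ndarray,
    seed: int | np.random.Generator = 0,
    design: ExperimentDesign = ExperimentDesign(),
) -> pd.DataFrame:
    """Unimodal localization (96 trials): cursor responses drawn from the
    Gaussian response distributions implied by remapping, prior shrinkage,
    accumulated shifts (post phase) and pointing noise."""
    if phase not in ("pre", "post"):
        raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    delta_a, delta_v = shifts
    sigma_v = params.sigma_v_uni(reliability_level)
    f_a = _shrink_factor(params.sigma_A_uni, params.prior_sd)
    f_v = _shrink_factor(sigma_v, params.prior_sd)
    sd_a = np.sqrt(f_a ** 2 * params.sigma_A_uni ** 2 + params.sigma_r ** 2)
    sd_v = np.sqrt(f_v ** 2 * sigma_v ** 2 + params.sigma_r ** 2)

    stims: list[tuple[str, float, float]] = []
    for s_a in design.auditory_locations:
        stims += [("A", s_a, np.nan)] * design.localization_repeats
    for s_v in aligned_visual_locations:
        stims += [("V", np.nan, float(s_v))] * design.localization_repeats
    order = rng.permutation(len(stims))

    rows = []
    for t, idx in enumerate(order):
        modality, s_a, s_v = stims[idx]
        if modality == "A":
            mu = f_a * (params.bias_slope * s_a + params.bias_intercept + delta_a) \
                + (1.0 - f_a) * params.prior_mean
            r = rng.normal(mu, sd_a)
        else:
            mu = f_v * (s_v + delta_v) + (1.0 - f_v) * params.prior_mean
            r = rng.normal(mu, sd_v)
        rows.append(_blank_row(
            task="localization", phase=phase, modality=modality,
            reliability=reliability_level, direction=direction,
            s_A=s_a, s_V=s_v, response=r, trial=t,
        ))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_recalibration_phase(
    params: ObserverParams,
    model_id: str,
    recal_design: RecalibrationDesign,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, ShiftTrajectory]:
    """One recalibration phase (120 trials) under the given model.

    Returns the trial log (with cued-modality localization responses, which
    are generated for completeness but never fitted) and the full shift
    trajectory whose final state seeds the post-recalibration phase.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i = recal_design.reliability_level
    sig_a, sig_v = params.sigma_A_bi, params.sigma_v_bi(i)
    pairs = np.asarray(recal_design.pairs, dtype=float)
    order = rng.permuted(np.repeat(np.arange(3), recal_design.n_repeats))

    state = ShiftState()
    deltas = np.zeros((recal_design.n_trials + 1, 2))
    rows = []
    for t, pair_idx in enumerate(order):
        s_a, s_v = pairs[pair_idx]
        m_a = rng.normal(
            params.bias_slope * s_a + params.bias_intercept + state.delta_A, sig_a
        )
        m_v = rng.normal(s_v + state.delta_V, sig_v)
        m = MeasurementPair(m_a, m_v, i)
        cued = "A" if rng.random() < 0.5 else "V"
        if model_id in ("CI", "CI_tied"):
            s_hat_a, s_hat_v = final_estimates(m, params)
            perceived = s_hat_a if cued == "A" else s_hat_v
        else:
            # non-inference models: report the shrunk cued measurement
            sig = sig_a if cued == "A" else sig_v
            f = _shrink_factor(sig, params.prior_sd)
            m_c = m_a if cued == "A" else m_v
            perceived = f * m_c + (1.0 - f) * params.prior_mean
        response = float(perceived) + rng.normal(0.0, params.sigma_r)
        rows.append(_blank_row(
            task="recalibration", phase="recal", modality=cued,
            reliability=i, direction=recal_design.direction,
            s_A=s_a, s_V=s_v, response=response, trial=t,
        ))
        if model_id == "RB":
            state = update_reliability_based(state, m, params)
        elif model_id == "FR":
            state = update_fixed_ratio(state, m, params)
        elif model_id == "CI":
            state = update_causal_inference(state, m, params)
        elif model_id == "CI_tied":
            state = update_causal_inference(state, m, params, tied=True)
        else:
            raise ValueError(f"unknown model_id {model_id!r}")
        deltas[t + 1] = (state.delta_A, state.delta_V)
    trajectory = ShiftTrajectory(
        deltas=deltas, model_id=model_id,
        reliability_level=i, direction=recal_design.direction,
    )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS), trajectory


def make_recalibration_design(
    aligned_visual_locations: np.ndarray,
    direction: str,
    reliability_level: int,
    design: ExperimentDesign = ExperimentDesign(),
    n_repeats: int | None = None,
) -> RecalibrationDesign:
    """Build the three discrepant audiovisual pairs of one session.

    Each auditory location is paired with the visual location perceived as
    aligned with the auditory location one step to its left (``V_left``) or
    right (``V_right``), producing a constant discrepancy in perceptual space.
    """
    a = design.auditory_locations
    v = np.asarray(aligned_visual_locations, dtype=float)
    if direction == "V_right":
        pairs = tuple((a[l], float(v[l + 1])) for l in range(3))
    elif direction == "V_left":
        pairs = tuple((a[l], float(v[l - 1])) for l in range(1, 4))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return RecalibrationDesign(
        pairs=pairs,
        reliability_level=reliability_level,
        direction=direction,
        n_repeats=n_repeats if n_repeats is not None else design.recalibration_repeats,
    )


@dataclass
class StudyDataset:
    """A complete simulated study: trial logs plus generating ground truth."""

    trials: pd.DataFrame
    params: ObserverParams
    model_id: str
    seed: int
    design: ExperimentDesign
    bias_slope_est: float
    bias_intercept_est: float
    aligned_visual_locations: np.ndarray
    trajectories: dict
    recal_designs: dict

    def manifest(self) -> dict:
        from dataclasses import asdict

        return {
            "model_id": self.model_id,
            "seed": int(self.seed),
            "params": asdict(self.params),
            "bias_slope_est": float(self.bias_slope_est),
            "bias_intercept_est": float(self.bias_intercept_est),
            "aligned_visual_locations": np.asarray(
                self.aligned_visual_locations
            ).tolist(),
            "design": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.design).items()
            },
            "recal_designs": {
                f"{i}_{d}": {
                    "pairs": [list(p) for p in rd.pairs],
                    "reliability_level": rd.reliability_level,
                    "direction": rd.direction,
                    "n_repeats": rd.n_repeats,
                }
                for (i, d), rd in self.recal_designs.items()
            },
        }

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_trial_log(self.trials, directory / "trials.csv")
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)
        traj = pd.concat(
            [t.to_frame() for t in self.trajectories.values()], ignore_index=True
        )
        traj.to_csv(directory / "trajectories.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "StudyDataset":
        directory = Path(directory)
        trials = read_trial_log(directory / "trials.csv")
        with open(directory / "manifest.json") as fh:
            man = json.load(fh)
        p = man["params"]
        for key in ("sigma_V_uni", "sigma_V_bi", "lapse_V"):
            p[key] = tuple(p[key])
        params = ObserverParams(**p)
        d = man["design"]
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        design = ExperimentDesign(**d)
        recal_designs = {}
        for key, rd in man["recal_designs"].items():
            i, direction = key.split("_", 1)
            recal_designs[(int(i), direction)] = RecalibrationDesign(
                pairs=tuple(tuple(p) for p in rd["pairs"]),
                reliability_level=rd["reliability_level"],
                direction=rd["direction"],
                n_repeats=rd["n_repeats"],
            )
        traj_df = pd.read_csv(directory / "trajectories.csv")
        trajectories = {}
        for (i, direction), g in traj_df.groupby(
            ["reliability_level", "direction"], sort=False
        ):
            g = g.sort_values("t")
            trajectories[(int(i), direction)] = ShiftTrajectory(
                deltas=g[["delta_A", "delta_V"]].to_numpy(),
                model_id=str(g["model_id"].iloc[0]),
                reliability_level=int(i),
                direction=str(direction),
            )
        return cls(
            trials=trials,
            params=params,
            model_id=man["model_id"],
            seed=man["seed"],
            design=design,
            bias_slope_est=man["bias_slope_est"],
            bias_intercept_est=man["bias_intercept_est"],
            aligned_visual_locations=np.asarray(man["aligned_visual_locations"]),
            trajectories=trajectories,
            recal_designs=recal_designs,
        )


def write_trial_log(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "task": str, "condition": str, "direction": str,
            "phase": str, "modality": str,
        },
        keep_default_na=False,
        na_values=[""],
    )
    for col in ("task", "condition", "direction", "phase", "modality"):
        df[col] = df[col].fillna("")
    df["is_catch"] = df["is_catch"].astype(bool)
    df["staircase_id"] = df["staircase_id"].astype(int)
    return df[TRIAL_COLUMNS]


def generate_full_study(
    params: ObserverParams,
    model_id: str,
    design: ExperimentDesign = ExperimentDesign(),
    seed: int = 0,
    bootstrap_ci: bool = False,
) -> StudyDataset:
    """Simulate the complete protocol for one synthetic observer.

    Follows the real study's dependency chain: the bimodal-discrimination
    session is analyzed (PSE regression) to obtain the perceptually aligned
    visual locations used in all localization and recalibration tasks.
    """
    from . import psychophysics_analysis as ppa

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(30)]
    r = iter(rngs)

    frames = []
    for cond in ("A", "V1", "V2", "V3"):
        frames.append(
            run_unimodal_discrimination_session(params, cond, next(r), design)
        )
    bimodal = run_bimodal_discrimination_session(params, next(r), design)
    frames.append(bimodal)

    bias = ppa.estimate_bias_from_bimodal(bimodal, design)
    aligned = np.asarray(bias.aligned_visual_locations)

    frames.append(run_pointing_practice(params, next(r), design))

    trajectories = {}
    recal_designs = {}
    for i in (1, 2, 3):
        for direction in design.directions:
            rd = make_recalibration_design(aligned, direction, i, design)
            recal_designs[(i, direction)] = rd
            frames.append(
                run_localization_phase(
                    params, "pre", (0.0, 0.0), i, direction, aligned,
                    next(r), design,
                )
            )
            recal_df, trajectory = run_recalibration_phase(
                params, model_id, rd, next(r)
            )
            frames.append(recal_df)
            trajectories[(i, direction)] = trajectory
            frames.append(
                run_localization_phase(
                    params, "post", trajectory.final_shifts, i, direction,
                    aligned, next(r), design,
                )
            )

    trials = pd.concat(frames, ignore_index=True)
    return StudyDataset(
        trials=trials,
        params=params,
        model_id=model_id,
        seed=seed,
        design=design,
        bias_slope_est=bias.slope,
        bias_intercept_est=bias.intercept,
        aligned_visual_locations=aligned,
        trajectories=trajectories,
        recal_designs=recal_designs,
    )
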