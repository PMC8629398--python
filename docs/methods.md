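# Methods

This note documents the generative model, the task formalizations, the
fitting procedure and the numerical choices made in `avrecal`, in the
package's own terms. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Observer model

A stimulus at physical azimuth *s* (degrees, 0 = straight ahead, positive =
rightward) produces a noisy internal measurement m′ ~ N(s′, σ′²). Auditory
remapping into the shared internal frame is affine, s′_A = a_A·s_A + b_A;
visual remapping is fixed to the identity because only relative audiovisual
biases are measurable. Measurement SDs differ between unimodal (σ′_A,
σ′_V1..V3) and bimodal (σ′_AV,A, σ′_AV,V1..V3) presentation, with visual
reliability level i ∈ {1,2,3} ordered from high to low. A supra-modal
Gaussian prior over internal locations is fixed to an effectively flat
N(0, 100²); the closed forms keep the prior parametric so non-flat cases
remain testable.

Given a bimodal measurement pair, the causal-inference observer computes
the likelihoods of one common source (a single Gaussian marginal over the
shared location) and of two independent sources, combines them with the
prior probability of a common cause P(C = 1), and reports model-averaged
location estimates: the posterior-weighted mix of the fused
(reliability-weighted) and segregated (single-cue) conditional estimates.
All densities are evaluated in log space; exposed densities are
exponentiated on return, so they underflow to 0 beyond discrepancies of
roughly 100 SDs while the log forms remain finite.

## Recalibration dynamics

Modality-specific measurement shifts (Δ_A, Δ_V), zero at session start,
displace the measurement-distribution means and are updated after every
recalibration trial:

- reliability-based: Δ_A += α·w_i·(m′_V − m′_A), Δ_V += α·(1−w_i)·(m′_A −
  m′_V), with w_i the relative visual reliability in bimodal trials;
- fixed-ratio: Δ_A += α_A·(m′_V − m′_A), Δ_V += α_V·(m′_A − m′_V);
- causal inference: Δ_A += α_A·(ŝ′_A − m′_A), Δ_V += α_V·(ŝ′_V − m′_V),
  with model-averaged estimates ŝ′; the tied variant sets α_A = α_V.

Shifts updated on trial *t* take effect on trial *t*+1, and the final
shifts after the 120-trial phase are frozen and applied unchanged in the
post-recalibration localization task. Responses produced *during* the
recalibration phase are generated for completeness (estimate of the cued
modality plus pointing noise; for the non-inference models the shrunk cued
measurement) but are never fitted.

An exact structural property worth noting: under the (near-)flat prior,
both causal-inference increments share the trial factor
P(C=1|m)·(m′_V − m′_A), so Δ_A and Δ_V are proportional *within a run* up
to prior-shrinkage terms of order (σ/σ_P)². The simulated joint
distribution of final shifts is therefore a near-degenerate ridge
(|correlation| ≈ 1 − 1e−8). Consequences for the quadrature are handled
below.

## Task designs

The synthetic protocol reproduces the study design exactly:

- unimodal 2IFC discrimination: 4 interleaved staircases × 40 trials
  (starts ±12.5°, one two-down-one-up and one one-down-two-up per side;
  steps 1.9° → 1.0° after the first reversal → 0.5° after the third), one
  ±12.5° catch trial per 10 staircase trials — 176 trials per condition;
- bimodal discrimination: 8 staircases × 36 trials over auditory locations
  ±2.5°, ±7.5° (starts ±15° relative; the staircase starting right of the
  auditory stimulus runs one-down-two-up), one ±15° catch per 9 staircase
  trials — 320 trials;
- pointing: 8 locations from −17.5° to 17.5° × 30 visits — 240 trials,
  responses N(s, σ_r²);
- unimodal localization: 4 auditory + 4 visual locations × 12 repeats — 96
  trials per phase; responses are Gaussian with mean equal to the shrunk,
  remapped (and, post-recalibration, shifted) location and variance
  σ²_est + σ_r²;
- recalibration: 3 audiovisual pairs × 40 repeats — 120 trials. Each
  auditory location is paired with the visual location perceived as aligned
  with its neighbor one step left or right, so the discrepancy is constant
  in perceptual space.

Choices the protocol leaves open were fixed as follows: catch trials are
placed deterministically after every 10th (9th) staircase trial with
alternating sign, and do not feed the staircase; interleaving picks
uniformly among unfinished staircases; the bimodal "down" direction mirrors
the unimodal convention (down = leftward test movement). The perceptually
aligned visual locations used by the localization and recalibration tasks
come from the simulated observer's *own* bimodal-discrimination PSE
regression, not from ground truth, so analysis and fitting exercise the
same dependency chain as a real study.

The default synthetic observer is σ′_A = 4.5°, σ′_V = (1.5, 4.5, 7.5)°
(visual reliability bracketing audition), σ′_AV,A = 6°, σ′_AV,V = (3, 6,
9)° (bimodal noise moderately above unimodal), a_A = 1.1, b_A = −0.6°
(peripheral auditory bias with a small leftward offset, the direction most
observers show), P(C=1) = 0.7, α_A = α_V = 0.003, σ_r = 1.85° (typical
reported pointing noise), lapses 0.02–0.04. These values are realistic for
broadband-noise auditory and blurred-blob visual stimuli at these
eccentricities.

## Descriptive analysis

Psychometric functions are lapse-contaminated cumulative Gaussians
(λ ≤ 0.06), fit by maximum likelihood with a small multi-start grid over
(SD, lapse) to avoid the lapse-boundary local optimum; the center is fixed
at 0 for the unimodal task and free for the bimodal per-location fits.
JND = Φ⁻¹(0.75)·SD and PSE = fitted center are read off the unscaled
function. Binned adjusted R² (1.8° unimodal, 3° bimodal bins anchored at
0, empty bins dropped) is reported as a fit diagnostic. The four bimodal
PSEs are regressed on auditory location (OLS); the aligned visual
locations are the fitted line at the four auditory locations.

Outlier filtering removes |z| > 3 responses with the study's pooling
rules: pointing demeaned per location with one overall SD; localization
demeaned per (modality, location) pooled over sessions in the pre phase
and per condition in the post phase, with the auditory SD pooled over all
sessions and phases and visual SDs per reliability level. Zero-variance
groups are left untouched with a warning. Localization responses are
summarized by joint least squares with a shared slope and seven intercepts
per modality (pooled pre + six post conditions); the recalibration effect
is the post-minus-pre intercept difference, sign-coded so shifts
compensating the discrepancy are positive. Confidence intervals are
percentile bootstrap (2.5/97.5) with stratified resampling.

## Model fitting

Fitting is staged. Stage 1 fits the four unimodal psychometric functions;
the auditory task identifies only √2·σ′_A/a_A, so the stage stores the
ratio σ′_A/a_A and downstream code reconstructs σ′_A = a_A·(ratio) once
a_A is estimated. Stage 2 is the closed-form RMS estimate of σ_r from the
outlier-filtered pointing data. Stage 3 jointly maximizes, per model, the
bimodal-discrimination Bernoulli likelihood plus the pre- and
post-recalibration localization likelihoods over the bias (a_A, b_A), the
bimodal SDs, the learning rate(s), P(C=1) (causal-inference models) and
the bimodal lapse — 8/9/10/9 free parameters for RB/FR/CI/CI_tied.

The post-recalibration likelihood marginalizes over the latent final
shifts. The shift distribution is approximated from n_sims simulated
phases per session (1,000 at full scale); for RB/FR a 1-D Gaussian over
Δ_V (Δ_A is tied by −σ′²_AV,A/σ′²_AV,Vi or −α_A/α_V), for CI a bivariate
Gaussian over (Δ_A, Δ_V). The Gaussian is accepted if the R² between
observed and predicted counts over 100 equal-width bins per dimension
exceeds 0.925, computed over the numerical-integration region (the
3×-expanded sample range; binning over the raw sample range would reject a
*true* Gaussian most of the time at n = 1000, which is incompatible with
the threshold's intended role). On rejection a Gaussian KDE with Silverman
bandwidth replaces it; a near-zero-variance sample short-circuits to a
point mass with a warning.

The marginal integral uses the midpoint rule on 100 points per dimension
(100×100 for CI) over bounds lb = Δ_min − (Δ_max − Δ_min), ub = Δ_max +
(Δ_max − Δ_min) per session. Because the CI shift cloud is a
near-degenerate ridge far narrower than a grid cell (see above), the
Gaussian density is convolved with the integration cell (cov +=
diag(cell_width²/12)) so that midpoint density × area equals the cell
mass; the data likelihood varies slowly at cell scale, so the corrected
midpoint rule is consistent. Without this correction the 2-D quadrature is
arbitrarily inaccurate for the CI models. The localization likelihood as a
function of the shifts is evaluated through precomputed quadratic
sufficient statistics, making each grid evaluation O(grid) rather than
O(grid × trials).

Optimization is derivative-free (bounded Powell) in transformed
coordinates (log SDs and rates; the visual bimodal SDs as a base value
plus non-negative increments, enforcing monotonicity by construction; the
5×-unimodal caps as smooth penalties, with the auditory reference taken as
5× this observer's stage-1 ratio times the current slope because no
cross-participant average exists for a single synthetic observer).
Because the bias/lapse block (a_A, b_A, λ_AV) is pinned by thousands of
discrimination and pre-localization trials and its likelihood is
deterministic, it is profiled out first; the stochastic search then runs
over the dynamics block only, followed by a short joint polish. The
warm-start grid spans learning rates, rate ratios, P(C=1) and a scale
factor on the bimodal SDs — the bimodal SDs are constrained by no direct
response data, so the grid must cover the strongly-gated small-SD regime
as well. Remaining starts are drawn from an evenly spaced per-dimension
grid. The shift distribution is rebuilt at every objective evaluation with
a per-start fixed seed, so each run is deterministic while the objective
keeps its stochastic-approximation character. Every start's solution is
then re-evaluated on a common Monte-Carlo approximation (seed derived from
the fit seed alone, at the final simulation count) and the best is
reported, so models fit with the same seed are compared on a shared
approximation.

Nested and near-nested models are additionally compared at common
solutions: the reliability-based model is the tied causal-inference model
at P(C=1) = 1, and every fixed-ratio mean structure is reproducible by the
reliability-based rule, so each model is seeded from the optimum of its
already-fit relative (CI_tied → RB → FR → CI, with rate-split variants for
the untied model), and tied projections of the CI optimum are polished and
offered back to CI_tied. Without this, AIC ranking between nested pairs
measures optimizer luck — the Monte-Carlo noise of the marginal
log-likelihood between simulation seeds reaches 10–20 log units in the
strongly gated regime, far above the 2-point AIC penalty at stake.
AIC = 2k − 2·LL_total with k the stage-3 parameter count; ΔAIC labels
follow the conventional support bands (<2 substantial, 4–7 considerably
less, >10 essentially none).

## Problem sizes

Default pipeline budgets are n_starts = 5, n_sims = 500 and 200 bootstrap
draws; `--full-scale` restores 20 starts, 1,000 simulations and 1,000
draws. The test suite runs the recovery experiments at reduced budgets
chosen as the smallest that keep the checks informative: 10 synthetic
observers with 100-draw bootstraps for parameter recovery, and 10
replicates per generating model with one warm start, 60-simulation
objectives and 300-simulation final evaluations for model recovery. The
model-recovery generators use strong learning rates and, for the
causal-inference pair, a small bimodal auditory SD with a low common-cause
prior and the reliability levels placed on the posterior-transition cliff:
in that regime P(C=1|m) gates recalibration on or off across levels,
producing level-dependent total compensation that the reliability-based
and fixed-ratio rules cannot reproduce (the true-parameter likelihood
exceeds the best wrong-model fit by 10–25 log units there). At weak,
homogeneous learning rates the four models' fitted predictions for this
design largely coincide and AIC ranking is close to chance.

One identifiability limit is structural rather than budgetary: the
fixed-ratio model cannot be recovered against the reliability-based model
from this protocol. Any fixed-ratio behavior (level-constant mean shifts
with a fixed update ratio) is reproduced exactly by the reliability-based
rule with a level-constant weight, the residual difference in simulated
shift-distribution widths is worth less than 2 log units even at strong
visual learning rates, and the reliability-based model has one parameter
fewer — so AIC systematically prefers it on fixed-ratio data. Measured
directly: the likelihood at the true fixed-ratio parameters falls below
the fitted reliability-based model on fixed-ratio-generated data. The
confusion-matrix test reports this honestly; the converse direction (data
with reliability-dependent mean shifts, which the fixed-ratio rule cannot
produce) is recovered reliably. This mirrors the empirical logic of the
study: only reliability-dependent recalibration patterns separate the
candidate mechanisms.

## What the synthetic data do and do not show

The generator emulates Gaussian measurement and response noise, affine
auditory remapping, lapses, staircase adaptivity and trial-by-trial shift
dynamics. It does not emulate attention or vigilance drifts, sequential
response dependencies other than the modeled shifts, audibility of speaker
movement, reliability-dependent central biases, or non-Gaussian noise.
Passing recovery tests therefore demonstrates internal consistency of the
pipeline (the estimators recover the generative process that matches their
assumptions), not that real observers satisfy those assumptions.

## Known limitations

- The recalibration build-up (trial-by-trial responses during the
  recalibration phase) is generated but not fitted; only the final shifts
  constrain the dynamics parameters.
- Separating the tied from the untied causal-inference model requires the
  fit to resolve likelihood differences near the 2-point AIC margin, which
  in turn requires search budgets (many starts, large simulation counts)
  well beyond the package's reduced defaults; at those defaults the tied
  model frequently wins on untied data by the parameter-count penalty.
- P(C=1) and the learning rates trade off strongly; point estimates of
  either should be interpreted with care even when model ranking is
  stable.
- The bimodal measurement SDs are constrained only through their influence
  on the shift distribution and are weakly identified.
- With the study's one-location-step discrepancy, the causal-inference
  model's mean auditory recalibration as a function of bimodal visual SD
  is decreasing or peaked; monotonically increasing profiles over the 1–12°
  grid require larger discrepancies (the posterior transition must fall
  beyond the least reliable visual condition), which is how the behavioral
  sweeps produce that regime.
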