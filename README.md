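# avrecal

Simulation and model-based analysis of **audiovisual spatial recalibration**
(the ventriloquism aftereffect): after repeated exposure to spatially
discrepant audiovisual stimuli, unimodal sound and light localization shifts
to compensate for the discrepancy. `avrecal` implements a complete in-silico
version of a five-task psychophysics protocol -- adaptive spatial
discrimination, bimodal discrimination, pointing, and pre/post-recalibration
localization -- together with three competing models of the recalibration
process and the staged maximum-likelihood machinery to fit and compare them.

It is intended for computational cognitive scientists who want to

- generate realistic synthetic behavioral datasets for the full protocol
  (trial counts, staircases and stimulus geometry reproduced exactly),
- study how the candidate update rules shape recalibration as a function of
  cue reliability, discrepancy and the common-cause prior, and
- run parameter- and model-recovery experiments for this class of designs.

## The models

Each audiovisual exposure updates modality-specific measurement shifts
(Δ_A, Δ_V) that displace subsequent internal measurements:

- **Reliability-based (RB)** — each modality moves toward the other by a
  fraction of the measurement discrepancy proportional to the *other*
  modality's relative reliability, with one supra-modal learning rate α:
  Δ_A ← Δ_A + α·w_i·(m′_V − m′_A), w_i = σ⁻²_AV,Vi / (σ⁻²_AV,Vi + σ⁻²_AV,A).
- **Fixed-ratio (FR)** — modality-specific fractions of the discrepancy,
  independent of reliability: Δ_A ← Δ_A + α_A·(m′_V − m′_A).
- **Causal inference (CI, CI_tied)** — a Bayesian observer weighs a
  common-cause against a separate-cause interpretation of each measurement
  pair, P(C=1|m′_A, m′_V), and each modality moves toward its model-averaged
  location estimate: Δ_A ← Δ_A + α_A·(ŝ′_A − m′_A). `CI_tied` shares one
  learning rate between modalities.

Because the final shifts after a 120-trial recalibration phase are latent
and have no closed-form distribution, fitting marginalizes the
post-recalibration localization likelihood over a Monte-Carlo approximation
of the shift distribution (Gaussian, or a KDE when a histogram R² check at
the published 0.925 threshold rejects the Gaussian). Models are compared by
AIC with the dynamics-stage parameter counts 8 / 9 / 10 / 9.

## Worked example

```python
from avrecal.observer_core import ObserverParams
from avrecal.experiment_simulator import generate_full_study
from avrecal import psychophysics_analysis as ppa
from avrecal import model_inference as mi

observer = ObserverParams()               # default synthetic observer
dataset = generate_full_study(observer, "CI", seed=1)
report = ppa.analyze_study(dataset, n_boot=100)
print({k: round(v, 2) for k, v in report["jnd"].items()})
print(round(report["bias"].slope, 3), round(report["bias"].intercept, 3))
print(round(report["sigma_r"], 3))
```

prints (seed 1):

```
{'A': 2.74, 'V1': 1.21, 'V2': 5.73, 'V3': 6.22}
1.141 -0.578
1.89
```

The JNDs recover the generating reliability ordering (high-reliability
vision < audition < low-reliability vision; the generating values imply
JNDs of 3.9, 1.4, 4.3 and 7.2 deg, each estimated here from one 176-trial
staircase session), the PSE regression recovers the auditory remapping bias
(true slope 1.1, intercept −0.6 deg), and the pointing task recovers the
response noise (true σ_r = 1.85 deg). Fitting
and comparing all four models on this dataset:

```python
results = mi.fit_all_models(dataset, n_starts=2, seed=0, n_sims=200)
print(mi.compare_models(results)[["model_id", "aic", "delta_aic"]])
```

A command-line interface mirrors the library:
`avrecal simulate | analyze | fit | compare | study | recover | sweep`.

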