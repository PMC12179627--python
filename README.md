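# esmdyn

Multi-method dynamic modelling of experience-sampling (ESM) data that links a
passively sensed **social-presence proxy** — the number of Bluetooth devices a
phone detects in a short scan — to repeatedly measured **emotional states**
(vigor, fatigue, dejection, anger; four 1–4 Likert items each, prompted ~4
times a day over ~2 weeks).

It is written for researchers in ambulatory assessment / intensive
longitudinal methods who want one coherent toolchain for the four analyses
such data typically demand, each probing a different timescale:

1. **Reliability** (`esmdyn.gtheory`) — generalizability-theory decomposition
   of item responses over persons × items × occasions and the relative
   generalizability coefficient
   ρ² = σ²ₚ / (σ²ₚ + σ²ₚᵢ/nᵢ + σ²ₚₒ/nₒ + σ²ᵣₑₛ/(nᵢnₒ)).
2. **Within/between mixed models** (`esmdyn.lmm`) — log(n_BT+1) regressed on
   subject-mean-centered (cwc) and grand-mean-centered (cmc) predictors,
   contemporaneous or lagged by one assessment, with random intercept + time
   slope and a continuous-time AR(1) residual correlation ρ^|Δt|; Nakagawa
   R²marginal/R²conditional, ICC, VIF, standardized β; plus a
   simulation-based power analysis for a within-person effect.
3. **Continuous-time state-space model** (`esmdyn.ctssm`) — a bivariate
   latent SDE dη = [Aη + Mχ]dt + G dW (social presence ↔ negative mood)
   observed through five indicators, fitted by exact Kalman maximum
   likelihood over irregular gaps; derived **half-lives** (first t with
   [e^{At}]ᵢᵢ = ½) and the **peak cross-lag** (argmax of the off-diagonal
   impulse response).
4. **Continuous-time hidden Markov model** (`esmdyn.cthmm`) — a two-state
   mood regime (vigorous/fatigued) with covariate-dependent intensities
   q₁₂ = α₁₂·exp(β·z) and zero-inflated negative-binomial emissions of the
   shifted 0–12 sum scores; mean sojourn times 1/|qᵢᵢ|, hazard ratios
   exp(β), one-day transition probabilities e^{Q·1}, Viterbi decoding.

A synthetic generator (`esmdyn.simulate`) reproduces the statistical
structure each stage assumes — irregular beep schedules at ~77% compliance,
right-skewed Bluetooth counts, item-level emotion responses driven by a
latent Ornstein–Uhlenbeck system with stable trait differences, and a
separate two-regime ZINB generator — so everything here runs and is tested
without any external data. See `docs/methods.md` for the models, defaults
and limitations.

## Worked example

```python
from esmdyn.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo_out", seed=7,
    design={"n_subjects": 40, "n_days": 14},
    ctssm={"n_starts": 2, "maxiter": 60, "triage_iter": 20, "compute_se": False},
    cthmm={"n_starts": 2, "maxiter": 120, "compute_se": False},
    power={"n_subjects": 21, "n_assessments": 42, "effect_r": 0.1,
           "alpha": 0.05, "reps": 1000},
)
run_pipeline(cfg)
print(open("demo_out/report.md").read())
```

which simulates a 40-subject dataset, runs all stages (~1 min) and prints:

```
## Generalizability analysis

- vigor: person share 21.7%, person x occasion 31.5%, rho^2 = 0.962
- fatigue: person share 32.9%, person x occasion 32.7%, rho^2 = 0.974
- dejection: person share 36.7%, person x occasion 3.2%, rho^2 = 0.989
- anger: person share 27.5%, person x occasion 2.3%, rho^2 = 0.976

## Mixed models (CAR(1) residuals)

- contemporaneous: R2m = 3%, R2c = 42%, ICC = 42%, rho = 1.8e-10, k = 1727
- lagged: R2m = 3%, R2c = 42%, ICC = 42%, rho = 2.4e-12, k = 1687
- validation: standardized beta(log_bt) = 0.69 [0.66, 0.73]

## Continuous-time state-space model

- drift A = [[-7.61, -0.14], [-0.18, -6.77]]
- half-life negative mood: 2 h 27 min; social presence: 2 h 11 min
- peak cross-lag SP -> NM: 3 h 21 min

## Power simulation

- power = 81.6% [79.1%, 83.9%] (1000 replicates, alpha = 0.05)
```

Reading the output: measurement is highly reliable (ρ² ≥ 0.96) with
person and person×occasion variance both substantial; between-person
differences carry ~40% of the Bluetooth outcome's variance (ICC) while
residual autocorrelation beyond the random effects is negligible (ρ ≈ 0);
the latent dynamics self-regulate on an hours scale — a perturbation of
negative mood decays by half in ~2½ h, and a social-presence impulse has its
peak cross-effect on mood ~3 h later; and 21 subjects × 42 beeps give ~82%
power to detect a within-person effect of r = 0.1.

The same stages are exposed as model classes (`MixedCAR1Model`,
`CtssmModel`, `CthmmModel`, `GStudy`; each `fit()` returns a results object
with `summary()`), and as a CLI:

```bash
esmdyn simulate --n-subjects 40 --seed 7 --out demo_out
esmdyn lmm demo_out/esm_data.csv --model contemporaneous --out demo_out
esmdyn ctssm demo_out/esm_data.csv --out demo_out
esmdyn run-all --seed 7
```

A full default configuration file ships as
`src/esmdyn/default_config.yaml` (pass via `--config`).

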