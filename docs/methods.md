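# Methods

`esmdyn` implements a multi-method analysis of experience-sampling (ESM) data
linking a passively sensed social-presence proxy — the number of Bluetooth
devices detected in a short scan — to four repeatedly measured emotional
states (vigor, fatigue, dejection, anger). The same long-format table (one
row per subject × beep, continuous time in days) feeds four models that probe
the data at different timescales, plus a simulation-based power analysis. A
synthetic generator reproduces the statistical structure each stage assumes,
so the whole pipeline is exercised end-to-end without any external data.

## Data model and transformations

Bluetooth counts are strongly right-skewed (sample skewness well above
Bentler's ±3 guideline), so all analyses use `log_bt = log(n_BT + 1)`
(natural log). The four emotion scales are sums of four 1–4 Likert items
(range 4–16); the hidden-Markov stage shifts them to 0–12 by subtracting 4.
Self-reported people counts (known + unknown within 2 m) validate the
Bluetooth proxy. Situational control is a 0–1 visual-analogue rating.

Conventions shared by every module:

- time is measured in **days**, with t = 0 at each subject's first answered
  assessment;
- level-1 predictors are centered within subject (cwc), level-2 predictors
  are subject means centered at the grand mean of subject means (cmc);
- lagging is by assessment order within subject regardless of the gap length
  (overnight gaps are lagged like any other), because the lagged model
  indexes the previous completed beep, not clock time;
- missingness is handled complete-case per analysis.

## Generalizability theory (`gtheory`)

Item responses are decomposed over the crossed random facets person × item ×
occasion with expected-mean-squares (ANOVA) estimators; at one observation
per cell the three-way interaction is confounded with the residual, giving
seven components. Negative solutions are truncated at zero with a warning
(standard practice). Cells missing from the crossing are tolerated by a
moment approximation with harmonic-mean level counts. The generalizability
coefficient is the relative coefficient of the mean over `n_items` items and
`n_occasions` occasions,

    rho^2 = s2_p / (s2_p + s2_pi/n_i + s2_po/n_o + s2_res/(n_i n_o)),

averaging over both facets — the only configuration that yields coefficients
above 0.9 when person variance is 25–60% of the item-level total, as observed
here. Both facet sizes are user-settable; defaults are 4 items and the mean
number of occasions.

On balanced data with all estimates interior, these ANOVA estimators coincide
with REML; the test suite verifies this against a direct restricted-likelihood
maximization of the full Kronecker-structured covariance on a tiny design.

## Mixed models with CAR(1) residuals (`lmm`)

The within/between model regresses `log_bt` on the four emotion scores and
control (cwc at the same or previous beep, plus cmc between-person terms) and
time, with a random intercept and random time slope per subject and a
continuous-time AR(1) residual correlation `cor(e_a, e_b) = rho^|t_a - t_b|`.
No installed mixed-model routine supports this residual structure, so the
marginal Gaussian likelihood is maximized directly: fixed effects are
profiled out by GLS; the remaining 5 variance parameters (log sigma, logit
rho, log-Cholesky of the 2×2 random-effect covariance) are optimized by
multi-start L-BFGS with a Nelder–Mead polish (the profile surface has kinks
where variances hit zero). ML and REML are both available; REML is the
default.

Reported alongside the coefficients: standardized betas
(`B * SD(x)/SD(y)` on the analysis sample), marginal/conditional R²
in the Nakagawa sense with the random-slope extension (random-effect variance
evaluated as the mean of `z' Psi z` over the observed times), ICC
(`psi00 / (psi00 + sigma^2)`), VIFs from the fixed-design correlation
inverse, and AIC/BIC. Degrees of freedom for t-tests follow the common
two-level convention: within-subject terms use `N − J − p1`, between-subject
terms `J − p2 − 1`; no Satterthwaite correction is attempted.

The validation model regresses `log(people+1)` on `log(bt+1)` with random
intercepts and reports the standardized slope with CI.

**Power simulation.** Each replicate draws
`y_ij = r·x_ij + u_j + e_ij` with x standard normal within person, unit
residual variance and random-intercept variance fixed by an ICC of 0.5 (the
within-person test is insensitive to this choice), fits a random-intercept
model by a fast profiled-ML routine (quasi-demeaning transform, scalar search
over the variance ratio — cross-checked against statsmodels `MixedLM`), and
tests the slope at the nominal level. Power is the rejection fraction with a
Wilson interval. At 21 subjects × 42 assessments and r = 0.1 the normal
approximation gives `Phi(0.1·sqrt(882) − 1.96) ≈ 0.84`; the simulation
reproduces this.

## Continuous-time state-space model (`ctssm`)

Two latent processes — social presence (SP) and negative mood (NM) — follow
the linear SDE `d eta = [A eta + c + M chi] dt + G dW`, observed through five
indicators `y = Lambda eta + tau + eps`, with `log_bt` loading 1 on SP and
the four emotion scores loading freely on NM (vigor constrained negative).
Situational control `chi` enters as an instantaneous state impulse `M chi`
at observation times (a zero-order-hold variant would be a trivial change of
the discretized intercept; the impulse convention is the default here because
control is measured at the beep itself).

Estimation is exact maximum likelihood via the Kalman filter with per-gap
discretization: `A_d = expm(A·dt)` and innovation covariance
`S − A_d S A_d'` from the Lyapunov equation `AS + SA' + GG' = 0`. The
filter is vectorized across subjects (padded arrays; missing manifest entries
are handled exactly by masking loading rows, which decouples those
coordinates under the diagonal measurement-error structure). Identification
for point estimation: SP scale pinned by the unit Bluetooth loading; NM scale
pinned by fixing the NM diffusion variance `(GG')_22 = 1` while its four
loadings are free. A `standardized_params()` helper rescales to the
unit-stationary-variance convention for comparison across fits. Population
parameters are shared across subjects; uncertainty comes from a
central-difference Hessian (a parametric bootstrap can be layered on top by
refitting simulated data). Optimization runs seeded multi-start L-BFGS with a
short triage leg per start and a smooth eigenvalue barrier at the drift
stability boundary (a hard cliff there stalls line searches).

By default `from_esm` centers each manifest within subject before z-scoring:
stable trait differences otherwise masquerade as near-zero drift eigenvalues
("infinite" half-lives), and the scientific object here is the within-person
dynamics.

Derived quantities are functionals of `expm(A t)`: the **half-life** of an
auto-effect is the first t where the diagonal entry crosses 0.5 (bracketing +
Brent, 1e-8 days); the **peak cross-lag** is the argmax of the off-diagonal
magnitude (dense 1e-4-day grid over 0–2 days, golden-section refinement).
Both are invariant to diagonal rescaling of the latents. For the
drift matrix used in the worked examples the NM half-life is 0.120 days
(2 h 53 min) and the SP→NM peak lag 0.145 days (3 h 29 min); note that a
single 2×2 drift point estimate implies one shared cross-lag profile for both
directions, so posterior summaries that average over person-varying drift can
legitimately report two different peak lags — only the point-estimate value
and the 3–4 h window are reproducible here.

## Continuous-time hidden Markov model (`cthmm`)

A two-state regime (state 1 "vigorous", state 2 "fatigued") evolves with
covariate-dependent intensities `q12 = a12·exp(b12·z_bt)`,
`q21 = a21·exp(b21·z_ctrl)` (the other two covariate effects are fixed at
hazard ratio 1), covariates piecewise-constant between assessments
(observation-carried-forward), and covariates z-scored so hazard ratios are
per SD. Given the state, the four shifted scores are conditionally
independent zero-inflated negative binomials `(r, p, pi)` per state ×
construct; the score ceiling at 12 is ignored in the likelihood (the NB tail
mass above 12 is reported as a diagnostic and is negligible at fitted
parameter magnitudes). The emission log-mass is tabulated over the integer
support once per parameter evaluation.

Inference is direct ML of the normalized forward recursion over transformed
parameters, with multi-start from a moment heuristic (splitting beeps at the
median vigor score) and post-hoc relabeling so state 1 has the higher
expected vigor; the initial distribution is estimated freely. Summaries:
mean sojourn times `1/|q_ii|`, hazard ratios `exp(beta)` with Wald CIs,
one-day transition probabilities `expm(Q·1)` (closed form for two states),
per-state emission profiles, Viterbi paths and forward–backward smoothing
probabilities.

## Synthetic data (`simulate`)

The generator emulates the study design: 80 subjects, 14 days, 4 prompts/day
at 9:00/13:00/17:00/21:00 with Gaussian jitter (SD 0.015 days ≈ 22 min),
each prompt answered independently with probability 0.768 (≈ 43 answered
beeps per subject). Latent (SP, NM) paths use exact OU transitions between
the irregular beep times, with drift/diffusion/covariate-effect defaults in
the neighbourhood of the dynamics the package is designed to estimate.
Emissions: emotion items are `round(clip(intercept + trait_j + loading·NM +
noise, 1, 4))` summed over 4 items — item-level generation means one dataset
serves the reliability, mixed-model and state-space stages coherently;
Bluetooth counts are negative binomial (integer, overdispersed, mean ≫
median, log skewness pattern ~5 → ~0.3) with log-mean linked to SP plus a
per-subject offset (SD 1.2, giving a `log_bt` ICC near 0.4–0.5); people
counts are Poisson with log-mean linked to `log(bt+1)`; control is a
logistic-transformed OU on the logit scale. Per-subject trait offsets
(construct SDs 0.4–0.6) create the stable between-person differences the
G-study and the mixed models' ICC measure.

A separate regime generator simulates the two-state chain exactly (jump
times within each piecewise-constant interval) with ZINB score emissions,
defaults sitting at the magnitudes of the fitted two-state model (sojourns
10.72/6.20 days, hazard ratios 1.25, published-scale emission triplets).

What the generator does **not** emulate: the absolute Bluetooth level of the
real study (mean ≈ 34 devices; the default link gives ≈ 9 — only the shape
matters to the analyses), discrete mood regimes in the main OU dataset (the
default pipeline's HMM stage therefore tends to separate *people*, not
within-person phases — regime-structured data come from
`generate_cthmm_dataset`), response styles, circadian mean structure, and
missingness that is informative rather than random. Passing tests on this
generator show the estimators recover the mechanisms they model; they do not
certify behaviour under real-data pathologies.

## Numerical choices and problem sizes

- Discretized innovation covariances are symmetrized and eigen-clipped at
  zero if round-off makes them indefinite (with a warning).
- CAR(1) rho is constrained to [0,1) by a logistic transform; fitted values
  on synthetic data are often ~1e-10, consistent with near-zero residual
  autocorrelation once random effects absorb the persistence.
- Variance parameters use log / log-Cholesky transforms throughout; ZINB
  probabilities use logits.
- Wald SEs come from central-difference Hessians of the negative
  log-likelihood in the unconstrained parametrization.
- Recovery studies run at 200 subjects × ~50 beeps (state-space), 80 × 56
  (hidden Markov) and 200 persons × 4 items × 40 occasions (G-theory), with
  optimizer budgets (2 starts, capped iterations) chosen so the full study
  suite completes in minutes while the estimates are already stable at the
  tolerances checked.
- The power simulation uses 1,000 replicates (Monte-Carlo SD ≈ 1.2 points of
  power).

## Known limitations

- Between-person trait structure is not modeled inside the state-space model
  (no person-specific manifest means); it is removed by within-person
  centering instead. Person-varying drift is out of scope.
- The two-level t-test df convention is an approximation; between-person
  p-values at small J are conservative relative to Satterthwaite.
- The unbalanced G-study path is a moment approximation, adequate for mild
  missingness only.
- The CT-HMM assumes conditional independence of the four scores given the
  regime and unbounded count support.
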