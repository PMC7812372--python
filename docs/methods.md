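# Methods

This document records the statistical model, the algorithms, the default
parameter choices, and the known limitations of `audpsych`. The README
covers installation and usage; this file covers *why the numbers are what
they are*.

## 1. Psychometric model

All forced-choice performance is modelled with a four-parameter logistic
psychometric function

```
p(x) = gamma + (1 - gamma - lambda) / (1 + exp(-beta * (x - alpha)))
```

where `alpha` is the midpoint (stimulus units), `beta` the slope
(1/stimulus units), `gamma` the guess rate (fixed by the task's number of
alternatives: 1/2 for 2AFC, 1/3 for 3AFC), and `lambda` the lapse rate.
Stimulus axes may be raw or natural-log transformed (`axis="log"` in the
task registry); the model is always logistic *on the declared axis*, so a
log axis yields a log-logistic function of the physical quantity.

`prob_correct` evaluates the logistic with the overflow-free form
`e = exp(-|z|); f = z >= 0 ? 1/(1+e) : e/(1+e)`, which is exact for all
finite arguments and never raises floating-point warnings. The same
evaluation is used inside the adaptive procedures and the MCMC fitters, so
simulation and inference share one likelihood to machine precision.

`threshold_at_p` inverts the function at a performance fraction `f`
measured between the asymptotes, i.e. it solves
`p(x) = gamma + f * (1 - gamma - lambda)`. The convention matters:
"threshold at 0.75" means 75% of the way from the guess rate to the upper
asymptote, not raw 75% correct.

## 2. Adaptive procedures

### 2.1 Transformed up-down staircase

`staircase_run` implements an n-down-1-up staircase (default 2-down-1-up)
with a larger initial step that shrinks to a final step after a configured
number of initial reversals. The threshold estimate is the mean of the
measurement-phase reversal levels. The 2-down-1-up rule converges on the
stimulus level where `p(x)^2 = 0.5`, i.e. `p = 0.5^(1/2) ≈ 0.7071`
(`updown_target(n)` returns `0.5^(1/n)` generally).

Two bias mechanisms in the mean-of-reversals estimator are worth knowing
about, because they are easy to rediscover the hard way:

1. **Intrinsic step-size bias.** Even at stationarity the mean of the
   reversal levels sits *above* the 70.7% point by an amount that grows
   with `step_size × slope`. Measured on a pure simulation with the exact
   same rule: at `step × slope = 1` the estimate corresponds to ~73.9%
   correct, at 0.5 to ~72.4%, at 0.25 to ~71.6%, and at 0.1 to ~71.1%.
   The final step must therefore be small relative to the psychometric
   spread (`1/beta`) if the estimate is to be read as "the 70.7% point".
2. **Start-level transient.** With a small final step the chain mixes
   slowly, so the influence of the starting level decays over many
   reversals. Shrinking the step without also lengthening the discarded
   burn-in makes the estimate *worse*, not better.

The library defaults (`step 4 → 2`, 2 initial + 8 measurement reversals)
mirror common audiometric practice and are deliberately short; simulation
studies that need an unbiased asymptotic estimate should use a generous
burn-in and a long measurement phase (e.g. 20 initial + 100 measurement
reversals with a final step ≤ 0.25 of the psychometric spread, as
`scripts/acceptance.py` does).

### 2.2 Updated maximum-likelihood (UML) Bayesian procedure

`uml_init`/`uml_update` maintain a discrete posterior over a 3-D grid of
`(alpha, beta, lambda)` (guess rate fixed). Updates are exact Bayesian
multiplications on the grid, so the sequential posterior equals the batch
posterior computed from the whole trial history to floating-point
round-off — this identity is the module's core correctness test.

Stimulus placement uses four *sweetpoints*: the stimulus values minimizing
the variance proxy `p(1-p) / (dp/dtheta)^2` for each free parameter (two
for the slope, below and above the midpoint; the lapse sweetpoint is the
top of the stimulus range). A 2-down-1-up rule moves an index over the
sorted sweetpoints (down after two consecutive correct responses, up after
an error), combining Bayesian placement with up-down robustness.

## 3. Psychometric refitting (`pf_fit`)

`fit_pf` refits trial-level track logs by MCMC on `(alpha, log beta,
log lambda)` with priors: Normal on the midpoint, gamma(shape, rate) on the
slope, gamma truncated below `lapse_upper` (default 0.2) on the lapse. The
sampler is an adaptive random-walk Metropolis, vectorized over chains, with
proposal covariance adapted during warmup only. Convergence is gated on
split-R-hat and bulk ESS (via `arviz`); a failed gate triggers one retry
with doubled draws before the fit is flagged `converged=False`.

Defaults (4 chains, 2000 warmup, 30 000 draws/chain) target a midpoint
ESS of roughly 10 000, enough for stable 99% credible intervals. Thresholds
at arbitrary performance fractions are summarized per-draw and reported as
posterior medians with 99% intervals.

Calibration note: credible-interval coverage is only nominally 99% when
the data-generating parameters are themselves draws from the fitting
priors. Coverage checks against a fixed "true" observer measure something
else (frequentist coverage at a point), and can legitimately sit away from
99% without indicating a bug.

## 4. Derived scores (`scoring`)

- **TCNE** (total cumulative noise exposure): linear-energy units relative
  to a reference exposure of 90 dBA for 8 h/day, 5 days/week, 52
  weeks/year, for one year ≡ 1 unit; +10 dBA multiplies the unit count by
  10 at equal duration, and exposures sum across activities.
  `log_tcne` is `log10` of the unit total.
- **Consonance preference**: per-rater z-scoring of dyad pleasantness
  ratings (constant raters yield NaN and are excluded), then the mean
  z-difference between consonant and dissonant dyads. Affine-invariant in
  each rater's rating scale by construction; practice blocks are excluded.
- **Equal temperament**: `et_frequency(f0, k) = f0 * 2^(k/12)`;
  `lowest_harmonic_rank(f0, edge)` is `ceil(edge / f0)` adjusted so exact
  division still counts the harmonic at the edge as resolved-out.
- **Cognitive PCA**: principal components by eigendecomposition of the
  correlation matrix of the standardized cognitive battery, with a
  deterministic sign convention (largest-magnitude loading positive).
- **Music exposure** is cube-root transformed (`music_transform`) to tame
  its long right tail; a large spike at zero remains by design.

## 5. Robust Bayesian regression (`regression`)

The analysis model is a hierarchical linear regression with:

- **Student-t residuals**, `nu` free with a shifted-exponential prior
  `1 + Exp(mean 29)`, sampled by Metropolis on `log(nu - 1)`;
  `PriorConfig(nu_fixed=np.inf)` reproduces Normal residuals exactly.
- **t(1, 0.1) shrinkage priors** on standardized coefficients of interest
  and broad Normal(0, 100) priors on designated nuisance columns
  (`prior_overrides={"name": "broad"}`).
- **Random subject intercepts** with a half-Cauchy(5) scale prior
  (parameter expansion), and a half-Cauchy(5) residual-scale prior.

Sampling is by Gibbs with the standard scale-mixture augmentations: the
t residual is Normal with a per-observation gamma mixing variance, the
t shrinkage prior is Normal with a per-coefficient mixing variance, and
the half-Cauchy scales use the inverse-gamma mixture representation. All
conditional updates are conjugate except `nu`.

Design construction (`build_design`):

- Continuous covariates are z-standardized; the outcome is z-standardized
  (optionally after a `log` transform, in which case reporting columns
  are exponentiated back to ratio units).
- Categorical factors use **effect coding** with the (numerically last)
  reference level coded −1, so main effects are deviations from the grand
  mean and factor columns sum to zero across levels.
- Interaction columns are products of the *standardized* parents
  (Friedrich's method), so interaction coefficients are on the same
  standardized scale as main effects.
- A design with more columns than rows raises immediately rather than
  producing an unidentifiable fit.

Reporting helpers: `summarize_ci` (posterior medians + 99% CIs, credible
flag = CI excludes 0), `contrast_draws` (arbitrary linear combinations of
coefficient draws), `covariate_slopes_by_factor` (per-level covariate
slopes in natural units per `per` units of the covariate, via
`(main ± code × interaction) × y_sd / x_sd × per`, plus their pairwise
difference), and `factor_level_shifts` (per-level outcome shifts, which
sum to zero across levels by the coding).

Defaults (4 chains, 1000 warmup, 40 000 draws/chain) are sized so the
slowest-mixing shrinkage-class coefficients clear the 10 000-ESS floor on
a ~100-subject, 6-condition dataset; the convergence gate applies R-hat to
every coefficient but the ESS floor only to the shrinkage class, since
broad-prior nuisance columns are not interpreted.

## 6. Synthetic cohort generator (`synthetic_cohort`)

`generate_cohort(n, seed)` draws `n` subjects (n must be divisible by 3)
with:

- Three **balanced age bands** (young/middle/older spanning ~18.8–73.6
  years) assigned by rank so each band has exactly `n/3` subjects, and a
  fixed within-band sex ratio.
- A **Gaussian copula** over nine latent variables (age, four audiometric
  quantities, log-TCNE, music exposure, two cognitive components) with the
  configured pairwise correlations as targets (e.g. age–PT2 ≈ 0.44,
  age–PTA4–12 ≈ 0.84, age–log10TCNE ≈ 0.02); the correlation matrix is
  projected to the nearest positive-definite matrix when needed.
- Truncated-normal audiometric marginals with physiologic caps.

Only the four audiometric quantities that enter any analysis model
(PT 0.5 kHz, PT 2 kHz, PTA 0.125–2, PTA 4–12) are generated directly;
per-octave thresholds are not synthesized.

`generate_outcomes` produces per-task, per-condition thresholds from
linear generating models over the covariates (slopes recorded in the
`SyntheticTruth` sidecar, so recovery experiments have exact targets);
`generate_tracks` produces trial-level adaptive-track logs driven by each
subject's true psychometric function; `generate_dyad_ratings` produces
dyad pleasantness ratings with a known consonance-preference effect.
`cohort_self_check` re-measures the realized correlations and band
balance.

Known limitations, on purpose:

- Copula targets are specified as Pearson correlations on the latent
  normals; after the marginal transforms the realized Pearson correlations
  are mildly attenuated, most visibly for the cognitive principal
  components (the self-check tolerances account for this).
- The PC2 orientation follows the deterministic sign convention above,
  which is arbitrary up to sign and should not be over-interpreted.
- Cross-correlations among the four audiometric quantities are plausible
  placeholders, not measured values; they are nuisance structure only.

## 7. Pipeline (`pipeline_io`)

`model_spec(family)` returns the registered `RegressionSpec` for each of
the nine model families; `condition_factor(family)` names the
within-family condition factor (or `None`). `run_pipeline` executes
generate → outcomes → fit → report with a manifest of stage hashes
(SHA-256 of every written artifact) so a rerun with the same `RunConfig`
is byte-identical. `fit_tracks` groups trial logs by (subject, task) and
refits each with `fit_pf` using priors derived from the task registry.
The `audpsych` console script exposes `generate`, `track`, `fitpf`,
`score`, `run`, `regress`, `contrasts`, and `report` subcommands.

## 8. Numerical choices

- All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; no global seeding.
- Log-density arithmetic throughout (log-sum-exp for grid normalization,
  log-space Metropolis ratios).
- Problem sizes in the test suite (cohort sizes, chain counts, draw
  counts) are the package's own reduced choices for runtime, with
  tolerances stated next to each assertion.
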