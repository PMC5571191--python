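# Methods

## The analysis in brief

The unit of analysis is the individual female and her best breeding
season. From a long table of female-years (pups born, pups recruited) the
package derives, per female: **peak effort** (maximum annual pups,
multiple litters within a calendar year summed), **peak age** (age at
*first* attainment of that maximum; later ties do not move it),
**lifetime pups/recruits**, **primiparity** (first litter at age 1 vs
later; delayed is the reference level), **mast exposure** (any mast year
at ages 1..lifespan), **age at mast** (first adult mast year when a
female spans two — only a handful of females ever do), **mast peak**
(the calendar year of the peak age is a mast year), **pre-peak rate**
(pups at ages below the peak age divided by peak age − 1; defined 0 for
yearling peaks) and **post-peak lifespan/pups**. Non-breeders (zero
lifetime pups) are excluded from every analysis set. The annual table
additionally flags *every* year attaining the maximum (`is_peak_year`),
which is the response of the peak-timing model.

## Mixed-model engine

All models are random-intercept GLMMs estimated by maximum likelihood
under the Laplace approximation. Writing the intercepts of batch *k* as
`b_k = s_k u_k` with spherical `u_k ~ N(0, I)`, the inner step finds the
joint mode of (β, u) by penalized IRLS (Fisher-scoring weights, working
response, step-halving on the penalized deviance); the outer step
maximizes

```
ll(s, φ) = log f(y | β̂, û, φ) − ‖û‖²/2 − ½ log det H_u
```

over the variance parameters with L-BFGS-B, where `H_u` is the penalized
Fisher information of `u` at the mode. Design choices that matter:

* **Parameterization.** Random-effect SDs are optimized directly on
  `[0, ∞)` rather than on the log scale: boundary fits (variance exactly
  0) occur in practice — the lifetime-pups model often estimates a zero
  cohort variance — and must be reachable. The NB size θ and the Gaussian
  residual SD are optimized as logs (interior by construction).
* **Profiled fixed effects.** β is profiled inside the inner PIRLS rather
  than carried by the outer optimizer (the faster of the two standard
  Laplace flavors; on test data it matches lme4's `nAGQ=0` fits to 3–4
  decimals and `nAGQ=1` to ~1%, well inside the Monte-Carlo noise of any
  quantity reported here).
* **Nested structure.** For squirrel-within-cohort intercepts the
  per-female block of every linear system is diagonal and eliminated by a
  Schur complement, so a PIRLS step costs O(n) plus a dense solve of size
  (#cohorts + #fixed effects). `log det H_u` falls out of the same
  elimination.
* **Negative binomial.** NB2, variance `μ + μ²/θ`, θ estimated jointly
  with the variance parameters. Two numerical traps are handled
  explicitly: the NB→Poisson limit is a flat plateau in log θ, so θ is
  seeded from a coarse profile grid and the optimum re-checked against
  that grid afterwards; and for θ > 1e4 the log-likelihood switches to a
  rising-factorial form with `log1p`, since `Γ(y+θ)/Γ(θ)` cancels
  catastrophically (without this the "θ → ∞ equals Poisson" identity
  fails at the 1e-2 level on β).
* **Warm starts.** The outer optimizer re-enters PIRLS hundreds of times;
  warm states store random effects on the `b = s·u` scale, which is
  invariant to the variance step (storing spherical `u` rescales the
  linear predictor catastrophically when `s` moves), and any stalled warm
  run triggers a cold restart.
* **Convergence.** Inner: relative penalized-deviance change < 1e-12
  (tight because the outer finite-difference step of 1e-5 must dominate
  inner noise). Outer: `ftol` 1e-9 with one retry at a coarser step when
  the line search aborts. Both flags are recorded in the `FitResult`.

**Inference.** Wald z for GLMM terms; for the Gaussian LMM, t with
Satterthwaite degrees of freedom computed numerically (gradient of
Var(β̂_j) with respect to the variance parameters against their
observed-information covariance), falling back to residual df — the
method used is recorded. Default CIs are Wald; `bootstrap_ci` replaces
them with percentile intervals from a parametric bootstrap (responses
simulated from the fitted model, fresh random intercepts, full refits;
failure rates above 10% are surfaced). CIs for variance parameters and θ
(`variance_param_ci`) are Wald on the SD/log scale from a numeric
observed information. **Backward selection** drops, one at a time, the
least significant removable term with p ≥ 0.05; quadratics and
interactions are removable before the main effects they contain
(marginality), and the trace records every step. Quadratic terms are
built scale-then-square from predictors standardized to mean 0, unit
sample (n−1) SD within each analysis; `ScalingInfo` inverts the scaling
exactly, which is how the quadratic optimum `−β₁/(2β₂)` is reported in
pups.

## Constrained-resampling null

Lifetime pups ≥ peak effort is an accounting identity, so the regression
of lifetime output on peak effort has an obligate positive component
(slope exactly 1 on the response scale if every female bred once). The
null keeps every covariate and redraws each female's lifetime total, with
replacement, from the empirical distribution of observed lifetime totals
truncated below at her peak — the minimal scheme that honours the floor
while preserving the marginal lifetime distribution; her own value
guarantees a non-empty pool. The selected Poisson GLMM is refitted to
each pseudo-dataset on the identical design (covariate scaling is not
recomputed — only the response moves) and the scaled linear peak-effort
coefficient recorded; the comparison is one-sided exceedance of the
observed slope over the null distribution. An alternative
uniform-over-the-admissible-range scheme is exposed
(`scheme="uniform"`) for sensitivity analysis. When validating the
mechanism on data it generated itself, the generating pool must be passed
explicitly (`pool=`): resampling from an already-resampled response
shifts the marginal upward and flattens second-generation slopes, which
looks like — but is not — an anticonservative test.

## Synthetic data generator

`SimulationConfig` defaults are the study conditions: 24 birth cohorts
(1986–2009) in a 1986–2013 calendar with mast years 1993, 1998, 2005,
2010; adult lifespan truncated-geometric on 1..8 years (p = 0.25, median
≈ 3 breeding events, capped at the end of the study window); first
breeding at age 1 with probability 0.6, else ages 2:3 at weights 8:2;
annual pups Poisson on the log scale with cohort (σ² = 0.02) and female
(σ² = 0.05) intercepts; recruitment binomial per pup at 0.20 (non-mast)
vs 0.41 (mast); and a survival cost of 0.5 expected years of remaining
life applied prospectively from the first year a female's running-maximum
effort lands in a mast year (her remaining lifespan is redrawn binomially
with the reduced mean).

The litter parameters (baseline log-mean 0.7821, mast effect 0.5636) were
calibrated once, at n = 40 000, so that the *marginal* annual-record
means over mast-experienced breeders — zero years before first breeding
and cost-truncated lives included — hit the system's 2.08 (non-mast) and
3.66 (mast) pups; the conditional mast effect lands essentially on
log(3.66/2.08) ≈ 0.565. An optional negative-binomial litter mode with
configurable dispersion supports robustness checks.

What the generator does **not** emulate: spatial/territory structure,
males, density dependence, between-year autocorrelation beyond the mast
calendar, age-specific fecundity trends (a female's expected effort is
flat over her span outside mast years), and overdispersion in *lifetime*
recruits — binomial thinning of Poisson litters is again Poisson, so the
NB lifetime-recruits model correctly drives θ to its Poisson limit on
synthetic data, unlike in real data where θ is finite. Consequently,
passing tests demonstrate the estimation and testing machinery and the
qualitative structure (mast effects, timing, costs, the floor), not
distributional realism of every margin; the NB machinery itself is
validated against data simulated directly from NB GLMMs. The realized
mast-peak deficit in post-peak lifespan (~0.9 years at the 0.5-year
nominal cost) exceeds the nominal cost because mast-peaking females are a
selected group; only the direction of the contrast is a calibration
target.

## Degenerate inputs and edge cases

Inverted calendars, mast years outside the window, all-mast calendars,
probabilities outside [0,1] and negative variances are rejected at
construction. Constant responses, non-binary Bernoulli responses,
rank-deficient designs, missing values and grouping factors with one
level raise before fitting. Constant predictor columns cannot be scaled.
A quadratic fit with β₂ ≥ 0 returns an explicit no-interior-maximum
state rather than a vertex. Pipeline subsets that empty an analysis set
record a skip reason in the report instead of failing the run; the
never-mast subset skips every mast-conditional model by construction.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each run in minutes on a single core: study-scale populations of
400–2000 females for model fits, 100 seeded replicates for coverage
properties, 20 replicates × 200 iterations for the null-test calibration,
and 2000 bootstrap draws only where a closed-form oracle is available.
All random draws flow from explicit integer seeds; identical
configuration and seed reproduce every table byte-for-byte.
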