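# peakeffort

Fitness consequences of peak reproductive effort in a resource-pulse
(masting) system.

Iteroparous females spread reproduction over multiple breeding seasons, and
one of those seasons is their best. In mast-seeding systems — here, North
American red squirrels relying on episodic white spruce seed crops — the
payoff for a given annual effort swings enormously between years: juvenile
recruitment roughly doubles in a mast year. This package implements an
individual-level analysis of how the *height* (maximum annual pups, "peak
effort") and *timing* (did the peak land in a mast year?) of a female's
best season shape her lifetime reproductive success, together with a
life-history simulator that reproduces the system's statistical structure
so every stage is testable without field data.

## What it computes

For each female with annual records (pups born, pups recruited), the
package derives peak effort, peak age (first attainment of the maximum),
lifetime totals, primiparity, mast-exposure flags and post-peak metrics,
then fits the analysis battery:

* **Lifetime pups** `~ Poisson(log)`, and **lifetime recruits**
  `~ NB(log)`: peak effort + peak effort², peak age + peak age², lifespan,
  primiparity, with a birth-cohort random intercept. Negative quadratics
  place the fitness-maximizing effort at an interior optimum
  `x* = −β₁/(2β₂)` (scaled), back-converted to pups.
* **Peak timing**: P(peak year) `~ Bernoulli(logit)` on the mast flag over
  all annual records of mast-experienced females, squirrel-within-cohort
  intercepts; plus Poisson/NB models for annual pups and recruits.
* **Mast-peak fitness and costs**: lifetime recruits on the mast-peak flag;
  mast-peak probability on age at mast (± quadratic) and pre-peak rate;
  post-peak lifespan (Gaussian LMM, Satterthwaite t) and post-peak pups
  (Poisson) on mast peak × peak effort + peak age.
* **Constrained-resampling null**: lifetime pups ≥ peak effort by
  construction, so a positive slope is partly obligate. The null redraws
  each female's lifetime total from the observed lifetime distribution
  truncated at her own peak and refits the selected Poisson GLMM; the real
  slope is compared with the upper tail of the resulting slope
  distribution.

All mixed models are fitted by an in-package Laplace engine (penalized
IRLS for the joint fixed/random mode, bounded quasi-Newton over variance
parameters, boundary variance 0 reachable), with Wald z / Satterthwaite t
tests, backward selection respecting marginality, and parametric-bootstrap
CIs. At zero random-effect variance each family collapses onto the
classical GLM, which the test suite verifies against statsmodels' IRLS.

## Worked example

```python
import peakeffort as pe

cfg = pe.SimulationConfig(n_females=1000, seed=42)   # calibrated defaults
histories = pe.simulate_population(cfg)
summaries = pe.summarize_females(histories, cfg.calendar)
breeders = pe.build_analysis_sets(summaries)["full_set"]

spec = pe.ModelSpec(
    "lifetime_pups", "poisson",
    ("peak_effort", "peak_effort^2", "peak_age", "peak_age^2",
     "lifespan", "primiparity"),
    "cohort_intercept", ("peak_effort", "peak_age", "lifespan"))
final_spec, fit, trace = pe.backward_select(spec, breeders)
print(fit.summary().round(3))
print(pe.vertex_in_natural_units(fit, "peak_effort"))
```

prints (seed 42):

```
         term   beta    se    stat     p  ci_2.5  ci_97.5
  (Intercept)  1.744 0.025  69.419 0.000   1.695    1.793
  peak_effort  0.534 0.020  26.500 0.000   0.494    0.573
peak_effort^2 -0.101 0.009 -11.149 0.000  -0.119   -0.083
     peak_age -0.046 0.014  -3.306 0.001  -0.072   -0.019
     lifespan  0.381 0.015  25.619 0.000   0.352    0.411
  primiparity  0.201 0.029   6.944 0.000   0.144    0.258
VertexResult(term='peak_effort', has_maximum=True,
             scaled_vertex=2.64, natural_vertex=8.9)
```

Read: on the log scale, one SD of peak effort buys a 0.53 increase in
expected lifetime pups near the mean, the negative quadratic bends the
curve over at about 9 pups, longer-lived and yearling-primiparous females
do better, and the cohort variance is ~0 in this replicate. The scripts in
`examples/` walk through simulation, the lifetime models, the null test
and the full pipeline (`run_full_analysis`), each printing and explaining
its numbers.

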