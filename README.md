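# contnb — decision curve analysis and the continuous net benefit

`contnb` evaluates the clinical utility of risk prediction models.  It is
aimed at biostatisticians and prediction-model researchers who validate
models (e.g. 10-year cardiovascular risk scores) and need to know not just
how well a model discriminates, but how much *benefit* acting on it would
deliver — across one decision threshold, several, or a whole continuum.

## The metric

The standard net benefit of treating everyone with score ≥ t is

```
NB(t) = TP(t) − t/(1−t) · FP(t)
```

in true positives per capita (TP, FP are per-capita rates; the decision
curve plots NB(t) against t, alongside treat-all and treat-none).  When a
model informs many decisions with different thresholds, or one decision
whose optimal threshold varies across patients, `contnb` computes the
**continuous net benefit**

```
NB_cont = ∫ ω(t) · ( TP(t)/t − FP(t)/(1−t) ) dt,      ∫ ω(t)/t dt = 1,
```

where the weighting ω(t) is the harmonic mean of the true-positive benefit
and false-positive harm of the decision made at threshold t (optionally
times a density of thresholds across the population).  Under the stated
normalization the value is in true positives: the gain over treating no
one, equivalent to correctly identifying and fully treating that many event
cases.  Special weightings recover familiar quantities exactly — a
normalized point mass at t* gives NB(t*); a uniform weighting makes model
*differences* equal mean log-likelihood differences; the parabola t(1−t)
makes them half the Brier-score difference.  Integration is exact over the
step structure of TP and FP (no threshold grid); see `docs/methods.md`.

## Worked example

```python
import numpy as np
import contnb as cb

scores = np.array([0.8, 0.6, 0.4, 0.2])
outcomes = np.array([1, 1, 0, 0])

nb = cb.net_benefit(scores, outcomes, t=0.5)
print(f"NB(0.5) = {nb.value:.3f} true positives per capita")

# continuous net benefit under a half-Gaussian weighting centred at the
# 10% statin threshold (nonzero below it), normalized
w = cb.half_gaussian(mean=0.10, sd=0.02).normalize()
curve = cb.performance_curve(scores, outcomes)
res = cb.continuous_net_benefit(curve, w)
print(f"continuous NB = {res.per_100:.2f} true positives per 100 people")

cohort = cb.Cohort(outcomes, {"model": scores})
ci = cb.bootstrap_ci(
    lambda c: cb.continuous_net_benefit(
        cb.performance_curve(c.scores["model"], c.outcomes), w
    ).value,
    cohort, n_boot=2000, seed=7,
)
print(f"95% CI: [{100*ci.ci_low:.2f}, {100*ci.ci_high:.2f}] per 100 people")
```

prints

```
NB(0.5) = 0.500 true positives per capita
continuous NB = 45.53 true positives per 100 people
95% CI: [-8.94, 100.00] per 100 people
```

At threshold 0.5 the model treats both event cases and neither non-case, so
NB is the full incidence (0.5).  The continuous net benefit weights
thresholds just below 10%, where this tiny cohort's model still separates
cases from non-cases; the very wide bootstrap interval is what resampling
four people deserves.

## Command line

```
contnb simulate --n 4000 --seed 1 --out cohort.csv
contnb dca --input cohort.csv --outcome outcome \
    --scores full,small,dichotomised,marker_based --grid "1%:30%:1%" --out dc.csv
contnb cnb --input cohort.csv --outcome outcome --scores full,small \
    --weighting weighting.yaml --bootstrap 500 --seed 1
contnb verify --input cohort.csv --outcome outcome --score-a full --score-b small
contnb example multi_intervention --seed 1 --out report.json
```

`simulate` writes a synthetic cardiovascular-style cohort (logistic true
risks, 15% incidence by default) with four competing policy columns;
`example` runs a complete validation workflow (net benefit at the 10%
statin threshold, continuous net benefit for overall management under the
half-Gaussian weighting, uniform-area summaries, or a lognormal population
of thresholds).  Weighting configs are YAML/JSON, e.g.

```yaml
components:
  - kind: point_mass
    params: {at: "10%"}
  - kind: half_gaussian
    params: {mean: "10%", sd: "2%"}
normalize: true
```

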