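# Methods

## The problem

Decision curve analysis evaluates a risk prediction model by the *net
benefit* of acting on its scores at a threshold probability t: everyone with
score ≥ t is treated, and

    NB(t) = TP(t) − t/(1−t) · FP(t),

where TP(t), FP(t) are per-capita true/false positive proportions and the
benefit of one correctly treated event case is rescaled to 1.  The threshold
encodes the harm–benefit trade-off: the clinically optimal t* satisfies
(1−t*)/t* = (a−c)/(d−b) with a, b, c, d the per-patient utilities of true
positive, false positive, false negative and true negative classifications.

A single threshold is the wrong summary when a model informs many decisions
at once (lifestyle advice, monitoring, drug prescription, each with its own
threshold) or when the optimal threshold varies across patients.  The
*continuous net benefit* summarizes value over thresholds:

    NB_cont = ∫ ω(t) · ( TP(t)/t − FP(t)/(1−t) ) dt,

where ω(t) is a nonnegative weighting function.  The integrand, up to a
constant, is the sum of the net benefit in the treated and in the untreated
at threshold t; ω(t) is the harmonic mean of the true-positive benefit
a′(t) − c and the false-positive harm d − b′(t) of the decision whose
optimal threshold is t — high only where *both* are non-negligible, and
driven by the smaller of the two.  With the normalization
∫ ω(t)/t dt = 1 the metric is in units of true positives (per capita; the
interfaces report per 100 people): the gain, relative to treating no one,
equivalent to correctly identifying and fully treating that many event
cases.  Treat-none has continuous net benefit exactly 0 under every
weighting; treat-all and treat-none are always reported alongside models.

For a single intervention whose optimal threshold varies across the
population with density p(t*), the expected net benefit uses
ω_E(t) = p(t) / (1/(a*−c*) + 1/(d*−b*)).  Because (1−t)/t = g/h ties the
benefit g and harm h at each threshold, one of the two curves determines
the other; with constant harm the weighting reduces to p(t)(1−t), with
constant benefit to p(t)·t.  These two special cases are exactly the two
"area under the net benefit curve" conventions, which can rank models in
*opposite orders* on the same data (the test suite carries a frozen
five-person instance) — the reason the utility structure, not just the
threshold distribution, must be specified.

Special weightings recover familiar quantities, which double as independent
oracles for the integrator:

* point mass at t*, normalized → NB(t*) exactly (unnormalized → NB(t*)/t*);
* uniform ω ≡ 1 on (0,1) → differences in continuous net benefit equal
  differences in mean Bernoulli log-likelihood;
* parabola ω = t(1−t) → differences equal half the Brier-score difference;
* any normalized ω on a perfect model → the outcome incidence π.

## Exact integration over the step structure

TP(t) and FP(t) are step functions with jumps only at observed score values
(classification rule: score ≥ t is positive, so each rate is constant on
the interval (p(j), p(j+1)] between consecutive sorted unique scores).  The
integral is therefore computed *exactly* as a finite sum: for each constant
segment, tp · ∫ω/t − fp · ∫ω/(1−t), plus mass·(TP/t − FP/(1−t)) for point
masses, with no threshold grid anywhere in a result.  Grids exist only in
decision-curve output and in test oracles.

Per-segment kernel integrals (∫ω, ∫ω/t, ∫ω/(1−t)) are closed-form for
constant, polynomial and piecewise-linear densities (log terms), which is
what makes the likelihood identity hold to ~1e−14 and the Brier identity to
machine precision.  Gaussian, lognormal and arbitrary callable densities use
a composite Gauss–Legendre rule (16 nodes per panel), with arithmetic panels
at the density's own smoothness scale (sd/2 for Gaussian shapes; the
log-scale sd for lognormal) and geometric panels (log-width ≤ 0.25) toward
an endpoint where the 1/t or 1/(1−t) kernel is singular, so the kernel is
analytic well inside every panel.  This is deterministic and agrees with a
10⁶-point midpoint sum to ~1e−12 on the normalization integrals used in
testing.

Degenerate and divergent cases are explicit, never silent:

* if a density is positive at t = 0 while ∫ω/t is required (equivalently at
  t = 1 for ∫ω/(1−t)), a `DivergenceError` is raised naming the remedy
  (bounded support or the difference form).  The uniform weighting on (0,1)
  therefore has no *absolute* continuous net benefit; its *difference*
  between two models is computed on the merged step partition, where
  segments on which the models classify identically cancel before
  integration — finite whenever both models' scores lie strictly inside
  (0,1), and scores of exactly 0/1 raise an error advising clipping
  (clipping constant 1e−10, configurable, applied only in the likelihood
  oracle).
* densities vanishing at the singular endpoint (lognormal, polynomials with
  zero constant term) are integrable; their singular-kernel integrals start
  at 1e−10 rather than 0, an error far below every tolerance used.
* ties among scores collapse into a single breakpoint; scores exactly 0 or
  1 are allowed everywhere except the log-likelihood.

## Weighting-function conventions

* **Half-Gaussian** (the "overall management" weighting): the N(mean, sd²)
  pdf on one side of the mean, zero on the other, no ×2 factor (scale is
  irrelevant after normalization).  Default support is truncated below at
  max(mean − 5·sd, 0.001): a Gaussian tail is strictly positive at t = 0,
  where the normalization integral diverges logarithmically, and thresholds
  below 0.1% are clinically meaningless in the intended applications.
* **Lognormal threshold distribution**: "mean" is by default the
  *arithmetic* mean of the distribution (log-location μ = ln(mean) − σ²/2);
  `mean_kind="log"` instead reads it as exp(μ), i.e. the median.  Both are
  exposed because elicited summaries are often ambiguous between the two.
* **Point masses** are represented discretely and handled exactly, never
  approximated by narrow densities.
* Weightings are stored **unnormalized** by default and normalized
  explicitly (the CLI normalizes unless the config says otherwise), so the
  raw area-under-net-benefit integrals remain expressible.
* Tabulated (t, ω) points are linearly interpolated with exact per-piece
  integrals, supporting clinician-elicited sketches of importance;
  components of a config are summed, so a point mass plus a density (one
  decision at a fixed threshold plus a continuum below it) is a first-class
  weighting.

## Bootstrap inference

Percentile bootstrap (default 2000 resamples for intervals), resampling
individuals so all score columns stay paired.  Optimism correction (default
500 resamples) refits the supplied model on each resample, contrasts its
apparent performance with its performance on the original cohort, and
subtracts the mean gap from the apparent estimate.  The percentile method
and replicate counts are package defaults chosen for simplicity and
stability of 95% intervals, not claims about any particular study; all
randomness flows from one integer seed through a counter-based Philox
generator, so identical seeds give identical results.  A metric failure on
a degenerate resample (e.g. no events) redraws the resample, up to 10
times, then errors.

## Synthetic cohorts

The generator emulates a cardiovascular primary-prevention validation
sample: four standardized continuous risk factors (effects 0.8, 0.5, 0.4,
0.3 on the log-odds scale — one dominant and several moderate predictors)
and four binary high-risk markers (effects 0.7, 0.9, 0.5, 0.6; prevalences
30%, 10%, 20%, 15%, roughly smoking/diabetes-like), a logistic true model
whose intercept is solved by bisection (tolerance 1e−6) so the mean true
risk equals the target incidence (default 15%, a typical 10-year event
rate), Bernoulli outcomes, and default n = 4000 — large enough for stable
decision curves at thresholds of 5–20% while keeping full test runs fast.
Optional miscalibration shifts/scales reported scores on the logit scale.

Four policy archetypes are refit on each cohort: a full logistic model, a
small model on two predictors, a dichotomised version of the full model
(scores collapsed to the observed event rate below/at-or-above the 10%
threshold — a valid probability score that by construction classifies, and
therefore scores, identically to the full model at the 10% threshold), and
a marker-based rule (score 1 if any marker present).  Logistic fits use
unpenalized maximum likelihood with a ridge-penalized fallback on
separation or non-convergence.

What the generator does *not* emulate: real covariate distributions and
correlations, non-logistic risk surfaces, censoring or competing risks, and
measured-with-error predictors.  Passing tests on these cohorts show the
*metrics* behave as the theory dictates (identities, invariances, coverage
close to nominal, stable policy rankings); they do not validate any
clinical model.

## Problem sizes used in the checked properties

Identity checks use 100 random cohorts of n = 50; integrator-versus-Riemann
checks use n = 100 cohorts against 10⁵-point midpoint sums (agreement
within 1e−4); bootstrap coverage uses 200 simulated cohorts of n = 1000
with 500 resamples (nominal 95%, accepted 91–99%); workflow-ranking checks
use 20 cohorts of n = 4000.  These sizes give Monte-Carlo error comfortably
inside each tolerance while keeping the default suite quick.

## Known limitations

* Rates are estimated from observed outcomes in a validation sample assumed
  representative of the untreated counterfactual, as in standard
  decision-curve practice.
* The threshold is assumed independent of model performance at that
  threshold (no subgroup-specific performance).
* Survival/censored outcomes, competing risks, and monetary
  cost-effectiveness are out of scope.
* Combining interventions requires the user-supplied relative value of
  their true-positive benefits; it is never inferred from data.
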