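"""Synthetic cohorts for testing and worked examples.

Emulates a cardiovascular primary-prevention setting: a binary 10-year
event outcome generated from a logistic model on a few continuous risk
factors (standardized, e.g. age, blood pressure, cholesterol) and a few
binary high-risk markers (e.g. smoking, diabetes).  The logistic intercept
is solved numerically so the mean true risk hits a target incidence.  Four
competing scoring policies are derived from each cohort:

* ``full`` — logistic regression refit on all predictors;
* ``small`` — logistic regression on a subset of predictors;
* ``dichotomised`` — the full model's scores collapsed to two values (the
  observed event rate below/at-or-above the 10% threshold), so it agrees
  with the full model exactly at a 10% decision threshold;
* ``marker_based`` — score 1 if any designated binary marker is present,
  else 0.

These are emulations of the archetypes used in cardiovascular model
validation studies, not refits of any published model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import ConfigError
from .performance import Cohort

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "generate_cohort",
    "make_policies",
    "simulate_cohort_with_policies",
    "sample_thresholds",
    "fit_logistic",
]

DICHOTOMY_THRESHOLD = 0.10


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cardiovascular cohort.

    Defaults give a cohort of 4000 with 15% ten-year incidence, four
    standardized continuous risk factors with decreasing effects and four
    binary markers at plausible prevalences — roughly the size, case mix
    and discrimination of a primary-prevention validation sample.
    ``miscalibration`` shifts/scales reported scores on the logit scale:
    reported = expit(shift + slope * logit(true_risk)).
    """

    n: int = 4000
    target_incidence: float = 0.15
    continuous_effects: tuple[float, ...] = (0.8, 0.5, 0.4, 0.3)
    binary_effects: tuple[float, ...] = (0.7, 0.9, 0.5, 0.6)
    marker_prevalences: tuple[float, ...] = (0.30, 0.10, 0.20, 0.15)
    miscalibration: tuple[float, float] = (0.0, 1.0)
    small_model_predictors: tuple[str, ...] = ("x1", "x2")
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ConfigError("n must be at least 2")
        if not (0.0 < self.target_incidence < 1.0):
            raise ConfigError("target_incidence must lie in (0, 1)")
        if len(self.binary_effects) != len(self.marker_prevalences):
            raise ConfigError("need one prevalence per binary marker")
        if any(not (0.0 < q < 1.0) for q in self.marker_prevalences):
            raise ConfigError("marker prevalences must lie in (0, 1)")
        if self.miscalibration[1] <= 0:
            raise ConfigError("miscalibration slope must be positive")

    @property
    def continuous_names(self) -> list[str]:
        return [f"x{i+1}" for i in range(len(self.continuous_effects))]

    @property
    def marker_names(self) -> list[str]:
        return [f"m{i+1}" for i in range(len(self.binary_effects))]

    @property
    def predictor_names(self) -> list[str]:
        return self.continuous_names + self.marker_names


@dataclass(frozen=True)
class SimulatedCohort:
    predictors: pd.DataFrame
    outcomes: np.ndarray
    true_risks: np.ndarray
    reported_risks: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return int(self.outcomes.size)


def _solve_intercept(linear: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + linear)) = target, by bisection."""

    def gap(b0):
        return float(np.mean(expit(b0 + linear))) - target

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ConfigError("target incidence unattainable for these effects")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-6))


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw predictors, true logistic risks and Bernoulli outcomes.

    Deterministic given ``config.seed`` (Philox counter-based stream).
    """
    rng = np.random.Generator(np.random.Philox(config.seed))
    n = config.n
    x = rng.standard_normal((n, len(config.continuous_effects)))
    m = (rng.random((n, len(config.binary_effects))) < np.asarray(config.marker_prevalences)).astype(float)
    linear = x @ np.asarray(config.continuous_effects) + m @ np.asarray(config.binary_effects)
    b0 = _solve_intercept(linear, config.target_incidence)
    true_risks = expit(b0 + linear)
    outcomes = (rng.random(n) < true_risks).astype(float)

    shift, slope = config.miscalibration
    if shift == 0.0 and slope == 1.0:
        reported = true_risks.copy()
    else:
        reported = expit(shift + slope * logit(true_risks))

    predictors = pd.DataFrame(
        np.hstack([x, m]), columns=config.predictor_names
    )
    return SimulatedCohort(
        predictors=predictors,
        outcomes=outcomes,
        true_risks=true_risks,
        reported_risks=reported,
        config=config,
    )


def fit_logistic(X: np.ndarray, y: np.ndarray):
    """Unpenalized logistic fit; ridge fallback on separation/non-convergence.

    Returns a predict(X) -> probabilities callable.
    """
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("error", RuntimeWarning)
            res = sm.Logit(np.asarray(y, dtype=float), Xc).fit(disp=0, maxiter=200)
        beta = res.params

        def predict(Xnew):
            Xn = sm.add_constant(np.asarray(Xnew, dtype=float), has_constant="add")
            return expit(Xn @ beta)

        return predict
    except Exception:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, max_iter=1000)  # ridge-penalized
        clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))

        def predict(Xnew):
            return clf.predict_proba(np.asarray(Xnew, dtype=float))[:, 1]

        return predict


def _dichotomise(scores: np.ndarray, outcomes: np.ndarray, t: float = DICHOTOMY_THRESHOLD) -> np.ndarray:
    """Collapse scores to the observed event rate below/at-or-above t.

    Keeps the policy a valid probability score; when the two group rates
    straddle t, it classifies identically to the original scores at t.
    """
    high = scores >= t
    out = np.empty_like(scores)
    for mask in (high, ~high):
        out[mask] = outcomes[mask].mean() if mask.any() else 0.0
    return np.clip(out, 0.0, 1.0)


def make_policies(sim: SimulatedCohort, seed: int | None = None) -> dict[str, np.ndarray]:
    """Fit the four competing policies on a simulated cohort."""
    cfg = sim.config
    y = sim.outcomes
    X_full = sim.predictors[cfg.predictor_names].to_numpy()
    X_small = sim.predictors[list(cfg.small_model_predictors)].to_numpy()

    full = fit_logistic(X_full, y)(X_full)
    small = fit_logistic(X_small, y)(X_small)
    dichotomised = _dichotomise(full, y)
    markers = sim.predictors[cfg.marker_names].to_numpy()
    marker_based = (markers.sum(axis=1) > 0).astype(float)
    return {
        "full": np.clip(full, 0.0, 1.0),
        "small": np.clip(small, 0.0, 1.0),
        "dichotomised": dichotomised,
        "marker_based": marker_based,
    }


def simulate_cohort_with_policies(config: SimulationConfig) -> tuple[Cohort, SimulatedCohort]:
    """Convenience: generate a cohort and package it with its four policies."""
    sim = generate_cohort(config)
    return Cohort(sim.outcomes, make_policies(sim)), sim


def sample_thresholds(
    kind: str, params: dict, n: int, seed: int = 0
) -> np.ndarray:
    """Draw optimal thresholds for a population.

    ``kind='lognormal'`` takes ``mean`` (arithmetic, default 0.12) and
    ``sdlog`` (default 0.3); ``kind='point'`` takes ``at``.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    if kind == "lognormal":
        mean = float(params.get("mean", 0.12))
        sdlog = float(params.get("sdlog", 0.3))
        if mean <= 0 or sdlog <= 0:
            raise ConfigError("mean and sdlog must be positive")
        scale = mean * np.exp(-0.5 * sdlog**2)
        return stats.lognorm.rvs(sdlog, scale=scale, size=n, random_state=rng)
    if kind == "point":
        at = float(params["at"])
        if not (0.0 < at < 1.0):
            raise ConfigError("degenerate threshold must lie in (0, 1)")
        return np.full(n, at)
    raise ConfigError(f"unknown threshold distribution kind {kind!r}")
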