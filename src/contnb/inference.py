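"""Bootstrap confidence intervals and optimism correction.

Resampling is by rows (individuals), keeping all score columns of a cohort
together so paired model comparisons survive resampling.  Intervals are
percentile intervals; optimism correction follows the internal-validation
recipe of refitting the model on each resample and contrasting apparent
with test performance on the original cohort.  All randomness flows from a
single integer seed through a counter-based Philox generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import InputError
from .performance import Cohort

__all__ = ["BootstrapResult", "bootstrap_ci", "optimism_corrected"]

_MAX_REDRAWS = 10


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int
    optimism: float | None = None

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise InputError("ci_low exceeds ci_high")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _resample_stat(stat, cohort: Cohort, rng) -> float:
    """Evaluate stat on a fresh resample, redrawing on failure (capped)."""
    n = cohort.n
    for attempt in range(_MAX_REDRAWS + 1):
        idx = rng.integers(0, n, n)
        try:
            return float(stat(cohort.take(idx)))
        except Exception:
            if attempt == _MAX_REDRAWS:
                raise
    raise AssertionError("unreachable")


def bootstrap_ci(
    metric: Callable[[Cohort], float],
    cohort: Cohort,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap interval for any cohort-level metric.

    ``metric`` maps a :class:`Cohort` to a scalar.  A metric failure on a
    degenerate resample (e.g. no events) is redrawn, up to 10 times.
    """
    if n_boot < 2:
        raise InputError("n_boot must be at least 2")
    if not (0.0 < level < 1.0):
        raise InputError("level must lie in (0, 1)")
    rng = _rng(seed)
    estimate = float(metric(cohort))
    values = np.array([_resample_stat(metric, cohort, rng) for _ in range(n_boot)])
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return BootstrapResult(
        estimate=estimate,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )


def optimism_corrected(
    metric: Callable[[np.ndarray, np.ndarray], float],
    model_fitter: Callable[[Cohort], Callable[[Cohort], np.ndarray]],
    cohort: Cohort,
    n_boot: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap optimism correction for an internally validated model.

    ``model_fitter(cohort)`` returns a prediction function mapping any
    cohort to a score vector; ``metric(scores, outcomes)`` evaluates it.
    For each resample the model is refit, its apparent performance on the
    resample is contrasted with its performance back on the original
    cohort, and the mean gap (the optimism) is subtracted from the
    apparent estimate.  The fitter must be deterministic given the data.
    """
    if n_boot < 2:
        raise InputError("n_boot must be at least 2")
    rng = _rng(seed)
    predict = model_fitter(cohort)
    apparent = float(metric(predict(cohort), cohort.outcomes))

    gaps = []
    for _ in range(n_boot):
        def one_gap(resample: Cohort) -> float:
            fit_b = model_fitter(resample)
            apparent_b = float(metric(fit_b(resample), resample.outcomes))
            test_b = float(metric(fit_b(cohort), cohort.outcomes))
            return apparent_b - test_b

        gaps.append(_resample_stat(one_gap, cohort, rng))
    optimism = float(np.mean(gaps))
    corrected = apparent - optimism
    return BootstrapResult(
        estimate=corrected,
        ci_low=corrected,
        ci_high=corrected,
        level=1.0,
        n_boot=n_boot,
        seed=seed,
        optimism=optimism,
    )
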