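"""Proper-scoring-rule oracles tied to specific weighting choices.

Two exact identities connect the continuous net benefit to familiar
performance metrics, for any pair of models on the same cohort:

* uniform weighting w(t) = 1 on (0, 1): the difference in continuous net
  benefit equals the difference in mean log-likelihood;
* parabolic weighting w(t) = t(1-t): the difference equals half the
  Brier-score difference (with the sign such that lower Brier wins).

These serve both as interpretations (maximum likelihood is "all thresholds
equally important") and as independent numerical oracles for the
step-exact integrator.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .netbenefit import continuous_net_benefit_difference
from .performance import Cohort, _validate_outcomes, _validate_scores, performance_curve
from .weighting import parabola, uniform

__all__ = [
    "mean_log_likelihood",
    "brier_score",
    "clip_scores",
    "verify_equivalences",
    "DEFAULT_CLIP",
]

DEFAULT_CLIP = 1e-10


def clip_scores(scores, eps: float = DEFAULT_CLIP) -> np.ndarray:
    """Clip scores into [eps, 1-eps] so log terms stay finite."""
    return np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)


def mean_log_likelihood(scores, outcomes) -> float:
    """Per-capita Bernoulli log-likelihood of the scores.

    The per-capita scale is what makes the uniform-weighting identity hold
    against per-capita TP/FP; scores exactly 0 or 1 must be clipped first
    (see :func:`clip_scores`).
    """
    y = _validate_outcomes(outcomes)
    p = _validate_scores(scores, y.size)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise DomainError(
            "scores of exactly 0 or 1 have infinite log terms; clip them "
            "into (0, 1) first (clip_scores)"
        )
    return float(np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def brier_score(scores, outcomes) -> float:
    """Mean squared error between scores and outcomes."""
    y = _validate_outcomes(outcomes)
    p = _validate_scores(scores, y.size)
    return float(np.mean((p - y) ** 2))


def verify_equivalences(
    cohort: Cohort, model_a: str, model_b: str, tol: float = 1e-9
) -> dict:
    """Check both scoring-rule identities on a cohort of two models.

    Returns a report dict with the two absolute discrepancies and a
    ``passed`` flag; the likelihood identity is checked on clipped scores.
    """
    pa, pb = cohort.scores[model_a], cohort.scores[model_b]
    y = cohort.outcomes
    pa_c, pb_c = clip_scores(pa), clip_scores(pb)
    curve_a, curve_b = performance_curve(pa_c, y), performance_curve(pb_c, y)

    d_cnb_uniform = continuous_net_benefit_difference(curve_a, curve_b, uniform())
    d_loglik = mean_log_likelihood(pa_c, y) - mean_log_likelihood(pb_c, y)
    likelihood_gap = abs(d_cnb_uniform - d_loglik)

    curve_a2, curve_b2 = performance_curve(pa, y), performance_curve(pb, y)
    d_cnb_parabola = continuous_net_benefit_difference(curve_a2, curve_b2, parabola())
    d_brier = 0.5 * (brier_score(pb, y) - brier_score(pa, y))
    brier_gap = abs(d_cnb_parabola - d_brier)

    return {
        "model_a": model_a,
        "model_b": model_b,
        "uniform_vs_log_likelihood": {
            "cnb_difference": d_cnb_uniform,
            "log_likelihood_difference": d_loglik,
            "discrepancy": likelihood_gap,
        },
        "parabola_vs_brier": {
            "cnb_difference": d_cnb_parabola,
            "half_brier_difference": d_brier,
            "discrepancy": brier_gap,
        },
        "tol": tol,
        "passed": bool(likelihood_gap < tol and brier_gap < tol),
    }
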