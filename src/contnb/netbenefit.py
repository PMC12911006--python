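"""Net-benefit metrics: single-threshold, combined, and continuous.

The standard net benefit of a risk-threshold policy at threshold t is

    NB(t) = TP(t) - t/(1-t) * FP(t)

in units of true positives per capita (the benefit of correctly treating
one individual with the outcome is rescaled to 1).  The continuous net
benefit integrates the rescaled quantity TP(t)/t - FP(t)/(1-t) against a
weighting function over thresholds, summarizing a model's value across a
continuum of decisions or a population of optimal thresholds.  Treat-none
is the implicit baseline: its value is 0 under every metric here.

All integration is exact with respect to the step structure of TP(t) and
FP(t): the integral is a finite sum of per-segment weighting moments, with
no threshold grid.  Grids appear only in decision-curve output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DivergenceError, DomainError, InputError
from .performance import (
    Cohort,
    PerformanceCurve,
    classification_rates,
    performance_curve,
)
from .weighting import PointMass, WeightingFunction

__all__ = [
    "NetBenefitResult",
    "net_benefit",
    "net_benefit_alt",
    "decision_curve",
    "combine",
    "continuous_net_benefit",
    "continuous_net_benefit_difference",
    "aunb",
    "aunb_alt",
    "TREAT_ALL",
    "TREAT_NONE",
]

TREAT_ALL = "treat_all"
TREAT_NONE = "treat_none"

PER_CAPITA = "true positives per capita"
PER_100 = "true positives per 100 people"


@dataclass(frozen=True)
class NetBenefitResult:
    """A net-benefit value, its units, and what produced it."""

    value: float
    units: str = PER_CAPITA
    threshold: float | None = None
    weighting: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def per_100(self) -> float:
        """Value rescaled to 'true positives per 100 people'."""
        if self.units == PER_100:
            return self.value
        return 100.0 * self.value

    def with_ci(self, low: float, high: float) -> "NetBenefitResult":
        return replace(self, ci_low=low, ci_high=high)


def _reference_scores(name: str, n: int) -> np.ndarray:
    if name == TREAT_ALL:
        return np.ones(n)
    if name == TREAT_NONE:
        return np.zeros(n)
    raise InputError(f"unknown reference policy {name!r}")


def net_benefit(scores, outcomes, t: float) -> NetBenefitResult:
    """Standard net benefit NB(t) = TP(t) - t/(1-t) FP(t), per capita."""
    r = classification_rates(scores, outcomes, t)
    value = r.tp - (t / (1.0 - t)) * r.fp
    return NetBenefitResult(value=value, threshold=float(t))


def net_benefit_alt(scores, outcomes, t: float) -> NetBenefitResult:
    """Alternative scaling (1-t)/t TP(t) - FP(t).

    This fixes the harm of a false positive (rather than the benefit of a
    true positive) at 1; at any single threshold it ranks models exactly as
    NB does, but areas under the two curves can rank models differently.
    """
    r = classification_rates(scores, outcomes, t)
    value = ((1.0 - t) / t) * r.tp - r.fp
    return NetBenefitResult(
        value=value, units="avoided false positives per capita", threshold=float(t)
    )


def decision_curve(
    cohort: Cohort,
    grid: Sequence[float],
    policies: Sequence[str] | None = None,
    include_references: bool = True,
) -> pd.DataFrame:
    """Net benefit of each policy at each grid threshold (long format).

    Always appends the treat-all and treat-none reference rows unless
    ``include_references`` is disabled.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise InputError("threshold grid must be non-empty")
    if np.any((grid <= 0.0) | (grid >= 1.0)):
        raise DomainError("grid thresholds must lie strictly inside (0, 1)")
    names = list(policies) if policies is not None else cohort.policies
    rows = []
    columns = {name: cohort.scores[name] for name in names}
    if include_references:
        columns[TREAT_ALL] = _reference_scores(TREAT_ALL, cohort.n)
        columns[TREAT_NONE] = _reference_scores(TREAT_NONE, cohort.n)
    for name, scores in columns.items():
        for t in grid:
            nb = net_benefit(scores, cohort.outcomes, float(t))
            rows.append({"policy": name, "threshold": float(t), "net_benefit": nb.value})
    return pd.DataFrame(rows)


def combine(
    nb1: NetBenefitResult, nb2: NetBenefitResult, relative_value: float
) -> NetBenefitResult:
    """Total net benefit of two model-informed decisions on one cohort.

    ``relative_value`` is the ratio of the true-positive benefit of the
    second intervention to the first ((a2-c2)/(a1-c1)); the result stays in
    the units of the first intervention's true positives.
    """
    if relative_value < 0:
        raise DomainError("relative_value must be nonnegative")
    return NetBenefitResult(
        value=nb1.value + relative_value * nb2.value,
        units=f"combined ({nb1.units}, reference intervention 1)",
        weighting=f"combine(rv={relative_value})",
    )


def _as_curve(curve_or_scores, outcomes=None) -> PerformanceCurve:
    if isinstance(curve_or_scores, PerformanceCurve):
        return curve_or_scores
    if outcomes is None:
        raise InputError("outcomes required when passing raw scores")
    return performance_curve(curve_or_scores, outcomes)


def _segment_edges(curve: PerformanceCurve, lo: float, hi: float) -> np.ndarray:
    inner = curve.edges[(curve.edges > lo) & (curve.edges < hi)]
    return np.concatenate([[lo], inner, [hi]])


def _mass_term(curve: PerformanceCurve, m: PointMass) -> float:
    tp, fp = curve.rates_at(m.location)
    return m.mass * (tp / m.location - fp / (1.0 - m.location))


def continuous_net_benefit(
    curve: PerformanceCurve, weighting: WeightingFunction
) -> NetBenefitResult:
    """Weighted integral of TP(t)/t - FP(t)/(1-t) plus point-mass terms.

    Exact over the score-induced step partition: each constant piece of the
    performance curve contributes tp * ∫w/t - fp * ∫w/(1-t) over the piece,
    with per-component closed forms where available and adaptive quadrature
    otherwise.  Raises :class:`DivergenceError` when a required integral
    diverges (e.g. uniform weighting touching t=0 with TP > 0 there);
    the difference form or a truncated support is the remedy.
    """
    total = 0.0
    for comp in weighting.components:
        lo, hi = comp.support
        edges = _segment_edges(curve, lo, hi)
        for a, b in zip(edges[:-1], edges[1:]):
            tp, fp = curve.rates_at(0.5 * (a + b))
            if tp != 0.0:
                total += tp * comp.moment(a, b, "inv_t")
            if fp != 0.0:
                total -= fp * comp.moment(a, b, "inv_1mt")
    for m in weighting.point_masses:
        total += _mass_term(curve, m)
    units = PER_CAPITA if weighting.normalized else PER_CAPITA + " (unnormalized weighting)"
    return NetBenefitResult(value=total, units=units, weighting=_describe(weighting))


def continuous_net_benefit_difference(
    curve1: PerformanceCurve, curve2: PerformanceCurve, weighting: WeightingFunction
) -> float:
    """Continuous net benefit of model 1 minus model 2.

    Computed on the merged step partition so that segments where the two
    models classify identically drop out *before* integration; this keeps
    the difference finite under the uniform weighting on (0, 1), whose
    absolute integrals diverge (and makes the uniform-weighting difference
    equal the mean log-likelihood difference exactly).
    """
    total = 0.0
    for comp in weighting.components:
        lo, hi = comp.support
        inner = np.unique(
            np.concatenate(
                [
                    curve1.edges[(curve1.edges > lo) & (curve1.edges < hi)],
                    curve2.edges[(curve2.edges > lo) & (curve2.edges < hi)],
                ]
            )
        )
        edges = np.concatenate([[lo], inner, [hi]])
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            tp1, fp1 = curve1.rates_at(mid)
            tp2, fp2 = curve2.rates_at(mid)
            dtp, dfp = tp1 - tp2, fp1 - fp2
            try:
                if dtp != 0.0:
                    total += dtp * comp.moment(a, b, "inv_t")
                if dfp != 0.0:
                    total -= dfp * comp.moment(a, b, "inv_1mt")
            except DivergenceError as exc:
                raise DivergenceError(
                    str(exc) + "; for score-vector differences this occurs when a "
                    "model outputs scores exactly 0 or 1 — clip scores into (0, 1)"
                ) from None
    for m in weighting.point_masses:
        total += _mass_term(curve1, m) - _mass_term(curve2, m)
    return total


def _nb_from_rates(tp: float, fp: float, t: float) -> float:
    return tp - (t / (1.0 - t)) * fp


def _nb_alt_from_rates(tp: float, fp: float, t: float) -> float:
    return ((1.0 - t) / t) * tp - fp


def _area_under(curve: PerformanceCurve, p: WeightingFunction, alt: bool) -> float:
    """Integral of p(t) * NB(t) (or NB_alt) over the step partition.

    Uses t/(1-t) = 1/(1-t) - 1 and (1-t)/t = 1/t - 1 to express both areas
    through the same three kernel moments the rest of the package uses.
    """
    total = 0.0
    for comp in p.components:
        lo, hi = comp.support
        edges = _segment_edges(curve, lo, hi)
        for a, b in zip(edges[:-1], edges[1:]):
            tp, fp = curve.rates_at(0.5 * (a + b))
            if tp == 0.0 and fp == 0.0:
                continue
            m_one = comp.moment(a, b, "one")
            if alt:
                if tp != 0.0:
                    total += tp * (comp.moment(a, b, "inv_t") - m_one)
                if fp != 0.0:
                    total -= fp * m_one
            else:
                if tp != 0.0:
                    total += tp * m_one
                if fp != 0.0:
                    total -= fp * (comp.moment(a, b, "inv_1mt") - m_one)
    for m in p.point_masses:
        tp, fp = curve.rates_at(m.location)
        f = _nb_alt_from_rates if alt else _nb_from_rates
        total += m.mass * f(tp, fp, m.location)
    return total


def aunb(scores, outcomes, p: WeightingFunction) -> float:
    """Area under the net benefit curve against a threshold density p.

    This is the expected NB across a population of optimal thresholds under
    the assumption that true-positive benefit is constant across people;
    it equals the continuous net benefit with weighting p(t)*t.
    """
    return _area_under(_as_curve(scores, outcomes), p, alt=False)


def aunb_alt(scores, outcomes, p: WeightingFunction) -> float:
    """Area under the alternative net benefit curve against density p.

    Assumes constant false-positive harm instead; equals the continuous
    net benefit with weighting p(t)*(1-t).  Can rank models differently
    from :func:`aunb` — the reason a weighting function must be chosen
    deliberately.
    """
    return _area_under(_as_curve(scores, outcomes), p, alt=True)


def _describe(w: WeightingFunction) -> str:
    parts = [type(c).__name__ + str(c.support) for c in w.components]
    parts += [f"mass({m.mass:g}@{m.location:g})" for m in w.point_masses]
    tag = "+".join(parts)
    return ("normalized " if w.normalized else "") + tag
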