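"""Empirical classification performance of risk-score policies.

A *policy* assigns treatment to everyone whose risk score is at or above a
threshold probability ``t``.  This module turns a cohort of scores and binary
outcomes into exact per-capita true/false positive rates, either at a single
threshold or as a piecewise-constant function of the threshold (a
:class:`PerformanceCurve`).  The curve representation is exact: TP(t) and
FP(t) are step functions with jumps only at observed score values, so
downstream integrals can be computed segment by segment without a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, InputError

__all__ = [
    "Cohort",
    "ClassificationRates",
    "PerformanceCurve",
    "classification_rates",
    "incidence",
    "performance_curve",
]


def _validate_outcomes(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise InputError("outcomes must be a non-empty 1-d vector")
    if not np.all(np.isin(y, (0.0, 1.0))):
        bad = np.flatnonzero(~np.isin(y, (0.0, 1.0)))
        raise InputError(
            f"outcomes must contain only 0 and 1; offending rows: {bad[:10].tolist()}"
        )
    return y


def _validate_scores(scores, n: int | None = None) -> np.ndarray:
    p = np.asarray(scores, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("scores must be a non-empty 1-d vector")
    if n is not None and p.size != n:
        raise InputError(f"length mismatch: {p.size} scores for {n} outcomes")
    if not np.all(np.isfinite(p)):
        bad = np.flatnonzero(~np.isfinite(p))
        raise InputError(f"scores must be finite; offending rows: {bad[:10].tolist()}")
    if p.min() < 0.0 or p.max() > 1.0:
        bad = np.flatnonzero((p < 0.0) | (p > 1.0))
        raise InputError(
            f"scores must lie in [0, 1]; offending rows: {bad[:10].tolist()}"
        )
    return p


def incidence(outcomes) -> float:
    """Proportion of individuals with the outcome (pi = P(Y=1))."""
    return float(_validate_outcomes(outcomes).mean())


@dataclass(frozen=True)
class Cohort:
    """One row per individual: a binary outcome and named risk-score columns.

    Scores are probabilities in [0, 1]; the outcome is 0/1.  All policy
    columns are kept together so that bootstrap resampling preserves the
    pairing between competing models.
    """

    outcomes: np.ndarray
    scores: Mapping[str, np.ndarray]

    def __post_init__(self):
        y = _validate_outcomes(self.outcomes)
        object.__setattr__(self, "outcomes", y)
        validated = {}
        for name, p in self.scores.items():
            validated[name] = _validate_scores(p, y.size)
        object.__setattr__(self, "scores", validated)

    @property
    def n(self) -> int:
        return int(self.outcomes.size)

    @property
    def incidence(self) -> float:
        return float(self.outcomes.mean())

    @property
    def policies(self) -> list[str]:
        return list(self.scores)

    def take(self, index) -> "Cohort":
        """Row subset/resample; keeps every score column aligned."""
        idx = np.asarray(index, dtype=np.intp)
        return Cohort(
            self.outcomes[idx], {k: v[idx] for k, v in self.scores.items()}
        )

    def to_frame(self, outcome_column: str = "outcome") -> pd.DataFrame:
        data = {outcome_column: self.outcomes.astype(int)}
        data.update({k: v for k, v in self.scores.items()})
        return pd.DataFrame(data)

    def to_csv(self, path, outcome_column: str = "outcome") -> None:
        self.to_frame(outcome_column).to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, outcome_column: str, score_columns: list[str]
    ) -> "Cohort":
        missing = [c for c in [outcome_column, *score_columns] if c not in frame]
        if missing:
            raise InputError(f"missing columns: {missing}")
        return cls(
            frame[outcome_column].to_numpy(),
            {c: frame[c].to_numpy() for c in score_columns},
        )

    @classmethod
    def from_csv(cls, path, outcome_column: str, score_columns: list[str]) -> "Cohort":
        return cls.from_frame(pd.read_csv(path), outcome_column, score_columns)


@dataclass(frozen=True)
class ClassificationRates:
    """Per-capita classification rates of the rule ``score >= t``."""

    t: float
    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def incidence(self) -> float:
        return self.tp + self.fn


def classification_rates(scores, outcomes, t: float) -> ClassificationRates:
    """Exact per-capita TP/FP/FN/TN of the positivity rule ``score >= t``.

    ``t`` must lie strictly inside (0, 1): at t=0 everyone is positive by
    convention of the rule only if every score is 0-inclusive, and the net
    benefit weight t/(1-t) is undefined at the endpoints anyway.
    """
    if not (0.0 < t < 1.0):
        raise DomainError(f"threshold must lie in (0, 1), got {t}")
    y = _validate_outcomes(outcomes)
    p = _validate_scores(scores, y.size)
    pos = p >= t
    n = y.size
    tp = float(np.count_nonzero(pos & (y == 1))) / n
    fp = float(np.count_nonzero(pos & (y == 0))) / n
    fn = float(np.count_nonzero(~pos & (y == 1))) / n
    tn = float(np.count_nonzero(~pos & (y == 0))) / n
    return ClassificationRates(t=float(t), tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class PerformanceCurve:
    """TP(t) and FP(t) as exact step functions of the threshold.

    ``edges`` partitions [0, 1]; on each open interval between consecutive
    edges the rates are constant (the classification rule ``score >= t``
    makes TP left-continuous: constant on (p_(j), p_(j+1)]).  ``breakpoints``
    are the unique observed scores.
    """

    breakpoints: np.ndarray
    edges: np.ndarray
    tp_segments: np.ndarray
    fp_segments: np.ndarray
    incidence: float
    # cumulative positive / total counts from each unique score upwards
    _tail_pos: np.ndarray = field(repr=False, default=None)
    _tail_all: np.ndarray = field(repr=False, default=None)
    _n: int = field(repr=False, default=0)

    def rates_at(self, t: float) -> tuple[float, float]:
        """(TP(t), FP(t)) at any t in (0, 1), exact under the >= rule."""
        if not (0.0 < t < 1.0):
            raise DomainError(f"threshold must lie in (0, 1), got {t}")
        k = int(np.searchsorted(self.breakpoints, t, side="left"))
        if k == self.breakpoints.size:
            return 0.0, 0.0
        tp = self._tail_pos[k] / self._n
        fp = (self._tail_all[k] - self._tail_pos[k]) / self._n
        return float(tp), float(fp)

    def rates(self, ts) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (TP, FP) at an array of thresholds in (0, 1)."""
        ts = np.asarray(ts, dtype=float)
        if np.any((ts <= 0.0) | (ts >= 1.0)):
            raise DomainError("thresholds must lie in (0, 1)")
        k = np.searchsorted(self.breakpoints, ts, side="left")
        inside = k < self.breakpoints.size
        kk = np.minimum(k, self.breakpoints.size - 1)
        tp_counts = np.where(inside, self._tail_pos[kk], 0.0)
        all_counts = np.where(inside, self._tail_all[kk], 0.0)
        return tp_counts / self._n, (all_counts - tp_counts) / self._n

    def segments(self) -> Iterator[tuple[float, float, float, float]]:
        """Yield (lo, hi, tp, fp) for each constant piece of the curve."""
        for j in range(self.edges.size - 1):
            yield (
                float(self.edges[j]),
                float(self.edges[j + 1]),
                float(self.tp_segments[j]),
                float(self.fp_segments[j]),
            )


def performance_curve(scores, outcomes) -> PerformanceCurve:
    """Build the exact step representation of TP(t), FP(t) for one policy."""
    y = _validate_outcomes(outcomes)
    p = _validate_scores(scores, y.size)
    n = y.size
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    uniq, first = np.unique(ps, return_index=True)
    # tail sums: counts of individuals with score >= uniq[k]
    pos_cum = np.concatenate([[0.0], np.cumsum(ys)])
    all_cum = np.arange(n + 1, dtype=float)
    tail_pos = pos_cum[-1] - pos_cum[first]
    tail_all = all_cum[-1] - all_cum[first]

    edges = np.unique(np.concatenate([[0.0], uniq, [1.0]]))
    mids = 0.5 * (edges[:-1] + edges[1:])
    # rates constant on each open inter-edge interval; evaluate at midpoints
    k = np.searchsorted(uniq, mids, side="left")
    inside = k < uniq.size
    kk = np.minimum(k, uniq.size - 1)
    tp_counts = np.where(inside, tail_pos[kk], 0.0)
    all_counts = np.where(inside, tail_all[kk], 0.0)
    tp_seg = tp_counts / n
    fp_seg = (all_counts - tp_counts) / n  # counts subtract exactly
    return PerformanceCurve(
        breakpoints=uniq,
        edges=edges,
        tp_segments=tp_seg,
        fp_segments=fp_seg,
        incidence=float(y.mean()),
        _tail_pos=tail_pos,
        _tail_all=tail_all,
        _n=n,
    )
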