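"""Threshold weighting functions for the continuous net benefit.

A weighting function assigns an *importance* to each threshold probability
t in (0, 1).  Importance is the harmonic mean of the utility gained per true
positive (a' - c, e.g. QALYs added by treating someone who needed it) and
the utility lost per false positive (d - b'): a threshold only matters when
both the benefit of acting correctly and the harm of acting wrongly are
non-negligible.  A weighting function here is a sum of nonnegative density
components on (0, 1) plus a finite set of point masses (a point mass at t*
recovers the single-threshold net benefit).

The normalization convention makes the integral of w(t)/t equal 1, which
puts the continuous net benefit in units of (combined) true positives.

Integrals of each component against the kernels 1, 1/t and 1/(1-t) are the
only quantities the integrator ever needs; components with polynomial or
constant densities supply them in closed form (log terms), the rest use
adaptive quadrature.
"""

from __future__ import annotations

import abc
import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats

from .errors import ConfigError, DivergenceError, DomainError

__all__ = [
    "WeightingFunction",
    "PointMass",
    "DensityComponent",
    "UniformDensity",
    "PolynomialDensity",
    "GaussianDensity",
    "LogNormalDensity",
    "TabulatedDensity",
    "CallableDensity",
    "importance",
    "threshold_from_utilities",
    "weighting_from_utilities",
    "weighting_from_threshold_distribution",
    "uniform",
    "parabola",
    "point_mass",
    "half_gaussian",
    "lognormal",
    "from_table",
    "builtin_weighting",
    "from_config",
]

Kernel = Literal["one", "inv_t", "inv_1mt"]

# composite Gauss-Legendre quadrature for non-closed-form densities:
# 16 nodes per panel, arithmetic panels at the component's smoothness scale,
# plus geometric panels toward the endpoint where the kernel is singular
# (panel log-width <= _LOG_STEP keeps 1/t analytic well inside each panel)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)
_LOG_STEP = 0.25
_EPS_T = 1e-10  # singular-kernel integrals start here when density(0)=0


def importance(benefit: float, harm: float) -> float:
    """Harmonic mean of true-positive benefit and false-positive harm.

    Both arguments are utility differences (benefit = a' - c, harm = d - b')
    and must be positive.  The result is symmetric, bounded by the smaller
    argument, and equals half of either when they coincide — so the
    importance of a threshold is driven by whichever of benefit or harm is
    smaller.
    """
    if benefit <= 0 or harm <= 0:
        raise DomainError("benefit and harm must both be positive")
    return 1.0 / (1.0 / benefit + 1.0 / harm)


def threshold_from_utilities(benefit: float, harm: float) -> float:
    """Optimal threshold t* with (1 - t*)/t* = benefit/harm, i.e. h/(h+g)."""
    if benefit <= 0 or harm <= 0:
        raise DomainError("benefit and harm must both be positive")
    return harm / (harm + benefit)


def _clip_interval(a: float, b: float, lo: float, hi: float):
    a2, b2 = max(a, lo), min(b, hi)
    if b2 <= a2:
        return None
    return a2, b2


class DensityComponent(abc.ABC):
    """One nonnegative density piece of a weighting function.

    Subclasses define the unit-scale density and, where closed forms exist,
    the moments against the three kernels; ``scale`` multiplies everything.
    """

    support: tuple[float, float]
    scale: float

    def density(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.support
        inside = (t >= lo) & (t <= hi)
        out = np.where(inside, self._density_unit(np.clip(t, lo, hi)), 0.0)
        return self.scale * out

    @abc.abstractmethod
    def _density_unit(self, t):
        """Density at unit scale, assuming t inside the support."""

    def _check_divergence(self, a: float, b: float, kernel: Kernel) -> None:
        if kernel == "inv_t" and a <= 0.0 and float(self._density_unit(0.0)) > 0.0:
            raise DivergenceError(
                "integral of weight/t diverges: the density is positive at "
                "t=0; use a support bounded away from 0 or the difference "
                "form of the continuous net benefit"
            )
        if kernel == "inv_1mt" and b >= 1.0 and float(self._density_unit(1.0)) > 0.0:
            raise DivergenceError(
                "integral of weight/(1-t) diverges: the density is positive "
                "at t=1; use a support bounded away from 1"
            )

    def moment(self, a: float, b: float, kernel: Kernel = "one") -> float:
        """Integral of density(t) * kernel(t) over [a, b] ∩ support."""
        clipped = _clip_interval(a, b, *self.support)
        if clipped is None:
            return 0.0
        a, b = clipped
        self._check_divergence(a, b, kernel)
        return self.scale * self._moment_unit(a, b, kernel)

    def _scale_hint(self) -> float:
        """Length scale over which the density varies appreciably."""
        lo, hi = self.support
        return (hi - lo) / 64.0

    def _moment_unit(self, a: float, b: float, kernel: Kernel) -> float:
        if kernel == "inv_t":
            a = max(a, _EPS_T)
        elif kernel == "inv_1mt":
            b = min(b, 1.0 - _EPS_T)
        if b <= a:
            return 0.0
        h = max(min(self._scale_hint(), b - a), (b - a) / 4096.0)
        edges = np.linspace(a, b, int(np.ceil((b - a) / h)) + 1)
        if kernel == "inv_t":
            m = int(np.ceil(np.log(b / a) / _LOG_STEP))
            geo = a * np.exp(np.linspace(0.0, np.log(b / a), m + 1))
            edges = np.unique(np.concatenate([edges, geo]))
        elif kernel == "inv_1mt":
            span = np.log((1.0 - a) / (1.0 - b))
            m = int(np.ceil(span / _LOG_STEP))
            geo = 1.0 - (1.0 - b) * np.exp(np.linspace(span, 0.0, m + 1))
            edges = np.unique(np.concatenate([edges, geo]))
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * np.diff(edges)
        ts = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
        vals = np.asarray(self._density_unit(ts), dtype=float)
        if kernel == "inv_t":
            vals = vals / ts
        elif kernel == "inv_1mt":
            vals = vals / (1.0 - ts)
        weights = (half[:, None] * _GL_WEIGHTS[None, :]).ravel()
        return float(np.sum(vals * weights))

    def scaled(self, c: float) -> "DensityComponent":
        return dataclasses.replace(self, scale=self.scale * c)


def _poly_moment(poly: Polynomial, a: float, b: float, kernel: Kernel) -> float:
    """Exact integral of poly(t)*kernel(t) over [a, b] via log closed forms."""
    if kernel == "one":
        P = poly.integ()
        return float(P(b) - P(a))
    if kernel == "inv_t":
        c0 = poly.coef[0]
        rest = Polynomial(poly.coef[1:]) if poly.coef.size > 1 else Polynomial([0.0])
        P = rest.integ()
        log_term = c0 * math.log(b / a) if c0 != 0.0 else 0.0
        return float(P(b) - P(a)) + log_term
    # inv_1mt: poly(t)/(1-t) = -Q(t) + poly(1)/(1-t), poly - poly(1) = Q*(t-1)
    r = float(poly(1.0))
    quot = (poly - r) // Polynomial([-1.0, 1.0])
    P = quot.integ()
    log_term = r * math.log((1.0 - a) / (1.0 - b)) if r != 0.0 else 0.0
    return -float(P(b) - P(a)) + log_term


@dataclass(frozen=True)
class UniformDensity(DensityComponent):
    """Constant density on an interval; moments are exact (log terms)."""

    support: tuple[float, float]
    scale: float = 1.0

    def __post_init__(self):
        lo, hi = self.support
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"support must satisfy 0 <= lo < hi <= 1, got {self.support}")

    def _density_unit(self, t):
        return np.ones_like(np.asarray(t, dtype=float))

    def _moment_unit(self, a, b, kernel):
        if kernel == "one":
            return b - a
        if kernel == "inv_t":
            return math.log(b / a)
        return math.log((1.0 - a) / (1.0 - b))


@dataclass(frozen=True)
class PolynomialDensity(DensityComponent):
    """Polynomial density (ascending coefficients); moments are exact."""

    coeffs: tuple[float, ...]
    support: tuple[float, float] = (0.0, 1.0)
    scale: float = 1.0

    def __post_init__(self):
        lo, hi = self.support
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"invalid support {self.support}")

    @property
    def _poly(self) -> Polynomial:
        return Polynomial(np.asarray(self.coeffs, dtype=float))

    def _density_unit(self, t):
        return self._poly(np.asarray(t, dtype=float))

    def _moment_unit(self, a, b, kernel):
        return _poly_moment(self._poly, a, b, kernel)


@dataclass(frozen=True)
class GaussianDensity(DensityComponent):
    """Gaussian pdf shape restricted to an interval (e.g. a half-Gaussian).

    The unit-scale density is the N(mean, sd^2) pdf itself; no renormalizing
    factor for the truncation is applied, since overall scale is irrelevant
    once the weighting is normalized.
    """

    mean: float
    sd: float
    support: tuple[float, float]
    scale: float = 1.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigError("sd must be positive")
        lo, hi = self.support
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"invalid support {self.support}")

    def _density_unit(self, t):
        z = (np.asarray(t, dtype=float) - self.mean) / self.sd
        return np.exp(-0.5 * z * z) / (self.sd * math.sqrt(2.0 * math.pi))

    def _scale_hint(self):
        return self.sd / 2.0


@dataclass(frozen=True)
class LogNormalDensity(DensityComponent):
    """Lognormal threshold density.

    ``mean`` is by default the arithmetic mean of the distribution, so the
    log-scale location is mu = ln(mean) - sdlog^2/2; pass
    ``mean_kind='log'`` to treat ``mean`` as exp(mu) directly (i.e. the
    median).  The pdf vanishes faster than any power at t=0, so the 1/t
    kernel is integrable on supports touching 0.
    """

    mean: float
    sdlog: float
    support: tuple[float, float] = (0.0, 1.0)
    mean_kind: Literal["arithmetic", "log"] = "arithmetic"
    scale: float = 1.0

    def __post_init__(self):
        if self.mean <= 0 or self.sdlog <= 0:
            raise ConfigError("mean and sdlog must be positive")
        lo, hi = self.support
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"invalid support {self.support}")

    @property
    def log_scale(self) -> float:
        if self.mean_kind == "arithmetic":
            return self.mean * math.exp(-0.5 * self.sdlog**2)
        return self.mean

    def _density_unit(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0.0
        z = (np.log(t[pos]) - math.log(self.log_scale)) / self.sdlog
        out[pos] = np.exp(-0.5 * z * z) / (
            t[pos] * self.sdlog * math.sqrt(2.0 * math.pi)
        )
        return out

    def _scale_hint(self):
        return self.log_scale * self.sdlog / 2.0

    def frozen(self) -> stats.rv_continuous:
        return stats.lognorm(self.sdlog, scale=self.log_scale)


@dataclass(frozen=True)
class TabulatedDensity(DensityComponent):
    """Piecewise-linear density through elicited (t, w) points.

    Supports the workflow where clinicians sketch a plausible importance
    curve over the decision-relevant range; moments are exact per linear
    piece.
    """

    ts: tuple[float, ...]
    ws: tuple[float, ...]
    scale: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.ts, dtype=float)
        w = np.asarray(self.ws, dtype=float)
        if t.size != w.size or t.size < 2:
            raise ConfigError("need at least two (t, w) points of equal length")
        if np.any(np.diff(t) <= 0):
            raise ConfigError("tabulated t values must be strictly increasing")
        if t[0] < 0 or t[-1] > 1:
            raise ConfigError("tabulated t values must lie in [0, 1]")
        if np.any(w < 0):
            raise ConfigError("tabulated weights must be nonnegative")

    @property
    def support(self) -> tuple[float, float]:
        return (self.ts[0], self.ts[-1])

    def _density_unit(self, t):
        return np.interp(np.asarray(t, dtype=float), self.ts, self.ws)

    def _moment_unit(self, a, b, kernel):
        total = 0.0
        t, w = np.asarray(self.ts), np.asarray(self.ws)
        for j in range(t.size - 1):
            seg = _clip_interval(a, b, t[j], t[j + 1])
            if seg is None:
                continue
            slope = (w[j + 1] - w[j]) / (t[j + 1] - t[j])
            poly = Polynomial([w[j] - slope * t[j], slope])
            total += _poly_moment(poly, *seg, kernel)
        return total


@dataclass(frozen=True)
class CallableDensity(DensityComponent):
    """Arbitrary vectorizable density function; moments by quadrature."""

    fn: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]
    scale: float = 1.0
    label: str = "callable"

    def _density_unit(self, t):
        return np.asarray(self.fn(np.asarray(t, dtype=float)), dtype=float)


@dataclass(frozen=True)
class PointMass:
    location: float
    mass: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.location < 1.0):
            raise ConfigError(f"point mass location must lie in (0, 1), got {self.location}")
        if self.mass <= 0:
            raise ConfigError("point mass must be positive")


@dataclass(frozen=True)
class WeightingFunction:
    """Sum of density components plus point masses over thresholds.

    Stored unnormalized by default; :meth:`normalize` rescales so that the
    integral of w(t)/t (including mass_k / t_k terms) equals 1, which fixes
    the units of the continuous net benefit as true positives.
    """

    components: tuple[DensityComponent, ...] = ()
    point_masses: tuple[PointMass, ...] = ()
    normalized: bool = False
    normalization_constant: float | None = None

    def __post_init__(self):
        if not self.components and not self.point_masses:
            raise ConfigError("weighting function needs at least one component or mass")

    @property
    def support(self) -> tuple[float, float]:
        los = [c.support[0] for c in self.components] + [m.location for m in self.point_masses]
        his = [c.support[1] for c in self.components] + [m.location for m in self.point_masses]
        return (min(los), max(his))

    def density(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.components:
            out = out + c.density(t)
        return out

    def moment(self, a: float, b: float, kernel: Kernel = "one") -> float:
        """Integral of the continuous part times the kernel over [a, b]."""
        return sum(c.moment(a, b, kernel) for c in self.components)

    def normalization_integral(self) -> float:
        """Integral of w(t)/t plus sum of mass/location over the support."""
        z = sum(c.moment(*c.support, "inv_t") for c in self.components)
        z += sum(m.mass / m.location for m in self.point_masses)
        return z

    def normalize(self) -> "WeightingFunction":
        z = self.normalization_integral()
        if not math.isfinite(z) or z <= 0.0:
            raise DivergenceError(f"normalization integral is {z}; cannot normalize")
        return WeightingFunction(
            components=tuple(c.scaled(1.0 / z) for c in self.components),
            point_masses=tuple(
                PointMass(m.location, m.mass / z) for m in self.point_masses
            ),
            normalized=True,
            normalization_constant=z,
        )

    def scaled(self, c: float) -> "WeightingFunction":
        if c <= 0:
            raise DomainError("scale factor must be positive")
        return WeightingFunction(
            components=tuple(comp.scaled(c) for comp in self.components),
            point_masses=tuple(PointMass(m.location, m.mass * c) for m in self.point_masses),
            normalized=False,
        )

    def __add__(self, other: "WeightingFunction") -> "WeightingFunction":
        return WeightingFunction(
            components=self.components + other.components,
            point_masses=self.point_masses + other.point_masses,
            normalized=False,
        )


# ---------------------------------------------------------------------------
# constructors


def uniform(support: tuple[float, float] = (0.0, 1.0)) -> WeightingFunction:
    """Equal importance on an interval (w = 1)."""
    return WeightingFunction(components=(UniformDensity(tuple(support)),))


def parabola(support: tuple[float, float] = (0.0, 1.0)) -> WeightingFunction:
    """w(t) = t(1-t): the weighting under which continuous-net-benefit
    differences equal half the (negative) Brier-score difference."""
    return WeightingFunction(
        components=(PolynomialDensity((0.0, 1.0, -1.0), tuple(support)),)
    )


def point_mass(location: float, mass: float = 1.0) -> WeightingFunction:
    """All importance at a single threshold; normalized, it recovers the
    standard net benefit at that threshold."""
    return WeightingFunction(point_masses=(PointMass(location, mass),))


def half_gaussian(
    mean: float,
    sd: float,
    side: Literal["below", "above"] = "below",
    support: tuple[float, float] | None = None,
) -> WeightingFunction:
    """Gaussian-shaped importance on one side of ``mean``.

    With ``side='below'`` the density is the N(mean, sd^2) pdf for t <= mean
    and zero above.  The default support is truncated below at
    max(mean - 5 sd, 0.001): the Gaussian tail is strictly positive at t=0,
    where the normalization integral of w/t would diverge, and thresholds
    that many standard deviations out carry negligible weight.
    """
    if sd <= 0:
        raise ConfigError("sd must be positive")
    if support is None:
        if side == "below":
            support = (max(mean - 5.0 * sd, 1e-3), mean)
        else:
            support = (mean, min(mean + 5.0 * sd, 1.0))
    return WeightingFunction(components=(GaussianDensity(mean, sd, tuple(support)),))


def lognormal(
    mean: float = 0.12,
    sdlog: float = 0.3,
    support: tuple[float, float] = (0.0, 1.0),
    mean_kind: Literal["arithmetic", "log"] = "arithmetic",
) -> WeightingFunction:
    """Lognormal threshold density (see :class:`LogNormalDensity`)."""
    return WeightingFunction(
        components=(LogNormalDensity(mean, sdlog, tuple(support), mean_kind),)
    )


def from_table(points: Sequence[Sequence[float]]) -> WeightingFunction:
    """Piecewise-linear weighting through (t, w) pairs."""
    pts = sorted((float(t), float(w)) for t, w in points)
    ts = tuple(t for t, _ in pts)
    ws = tuple(w for _, w in pts)
    return WeightingFunction(components=(TabulatedDensity(ts, ws),))


def weighting_from_utilities(
    harm_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    benefit_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    support: tuple[float, float] = (0.0, 1.0),
) -> WeightingFunction:
    """Importance curve from a threshold-indexed utility curve.

    At threshold t the benefit g(t) = a'(t) - c and harm h(t) = d - b'(t)
    are tied by (1-t)/t = g/h, so only one is free.  The harmonic-mean
    importance then simplifies to h(t)(1-t), equivalently g(t) t.  Exactly
    one of ``harm_curve`` or ``benefit_curve`` must be given; the curve must
    be positive on the support.
    """
    if (harm_curve is None) == (benefit_curve is None):
        raise ConfigError("give exactly one of harm_curve or benefit_curve")

    if harm_curve is not None:
        fn = lambda t: np.asarray(harm_curve(t), dtype=float) * (1.0 - t)
        label = "harm_curve*(1-t)"
        probe = harm_curve
    else:
        fn = lambda t: np.asarray(benefit_curve(t), dtype=float) * t
        label = "benefit_curve*t"
        probe = benefit_curve
    _check_positive_curve(probe, support)
    return WeightingFunction(
        components=(CallableDensity(fn, tuple(support), label=label),)
    )


def weighting_from_threshold_distribution(
    p: Callable[[np.ndarray], np.ndarray] | WeightingFunction,
    harm_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    benefit_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    support: tuple[float, float] = (0.0, 1.0),
) -> WeightingFunction:
    """Weighting for a population with a distribution of optimal thresholds.

    ``p`` is the density of optimal thresholds across individuals; the
    result is p(t) times the harmonic-mean importance at t, i.e.
    p(t) h(t) (1-t) when the false-positive harm curve is supplied (constant
    harm reproduces the alternative area-under-net-benefit weighting
    p(t)(1-t); constant true-positive benefit reproduces p(t) t).
    """
    if (harm_curve is None) and (benefit_curve is None):
        harm_curve = lambda t: np.ones_like(np.asarray(t, dtype=float))
    if (harm_curve is None) == (benefit_curve is None):
        raise ConfigError("give at most one of harm_curve or benefit_curve")

    if isinstance(p, WeightingFunction):
        if p.point_masses:
            raise ConfigError("threshold distribution must be a pure density here")
        p_fn = p.density
    else:
        p_fn = p

    if harm_curve is not None:
        fn = lambda t: (
            np.asarray(p_fn(t), dtype=float)
            * np.asarray(harm_curve(t), dtype=float)
            * (1.0 - t)
        )
        probe = harm_curve
    else:
        fn = lambda t: (
            np.asarray(p_fn(t), dtype=float)
            * np.asarray(benefit_curve(t), dtype=float)
            * t
        )
        probe = benefit_curve
    _check_positive_curve(probe, support)
    return WeightingFunction(
        components=(CallableDensity(fn, tuple(support), label="p*importance"),)
    )


def _check_positive_curve(curve, support, n: int = 33) -> None:
    lo, hi = support
    ts = np.linspace(lo + 1e-9, hi - 1e-9, n)
    vals = np.asarray(curve(ts), dtype=float)
    if np.any(vals <= 0):
        raise DomainError("utility curve must be positive on the support")


# ---------------------------------------------------------------------------
# config layer

_BUILTINS = {"uniform", "parabola", "point_mass", "half_gaussian", "lognormal", "from_table"}


def builtin_weighting(kind: str, params: dict | None = None, support=None) -> WeightingFunction:
    """Construct a named weighting family from plain parameters."""
    params = dict(params or {})
    if kind not in _BUILTINS:
        raise ConfigError(f"unknown weighting kind {kind!r}; choose from {sorted(_BUILTINS)}")
    try:
        if kind == "uniform":
            return uniform(tuple(support) if support else (0.0, 1.0))
        if kind == "parabola":
            return parabola(tuple(support) if support else (0.0, 1.0))
        if kind == "point_mass":
            return point_mass(float(params["at"]), float(params.get("mass", 1.0)))
        if kind == "half_gaussian":
            return half_gaussian(
                float(params["mean"]),
                float(params["sd"]),
                params.get("side", "below"),
                tuple(support) if support else None,
            )
        if kind == "lognormal":
            return lognormal(
                float(params.get("mean", 0.12)),
                float(params.get("sdlog", 0.3)),
                tuple(support) if support else (0.0, 1.0),
                params.get("mean_kind", "arithmetic"),
            )
        return from_table(params["points"])
    except KeyError as exc:
        raise ConfigError(f"missing parameter {exc} for weighting kind {kind!r}") from None


def _parse_prob(x) -> float:
    """Accept 0.1, '0.1' or '10%'."""
    if isinstance(x, str) and x.strip().endswith("%"):
        return float(x.strip().rstrip("%")) / 100.0
    return float(x)


def from_config(spec) -> WeightingFunction:
    """Build a weighting function from a config dict, YAML/JSON file or path.

    A spec is either a single component
    ``{kind, params: {...}, support: [lo, hi], normalize: bool}`` or
    ``{components: [spec, ...], normalize: bool}`` whose components are
    summed (e.g. a point mass at 10% plus a half-Gaussian below it).
    Probabilities may be written as percent strings ('10%').
    """
    if isinstance(spec, (str, Path)):
        text = Path(spec).read_text()
        try:
            spec = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            spec = yaml.safe_load(text)
    if not isinstance(spec, dict):
        raise ConfigError("weighting config must be a mapping")

    normalize = bool(spec.get("normalize", True))

    def build_one(entry: dict) -> WeightingFunction:
        kind = entry.get("kind")
        if kind is None:
            raise ConfigError("weighting component needs a 'kind'")
        support = entry.get("support")
        if support is not None:
            support = [_parse_prob(v) for v in support]
        params = {
            k: (_parse_prob(v) if k in {"at", "mean", "sd"} else v)
            for k, v in dict(entry.get("params", {})).items()
        }
        return builtin_weighting(kind, params, support)

    if "components" in spec:
        parts = [build_one(e) for e in spec["components"]]
        if not parts:
            raise ConfigError("empty components list")
        wf = parts[0]
        for part in parts[1:]:
            wf = wf + part
    else:
        wf = build_one(spec)
    return wf.normalize() if normalize else wf
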