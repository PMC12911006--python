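import numpy as np
import pytest

import contnb as cb


@pytest.fixture
def toy():
    """Four-person cohort used throughout: hand-countable rates."""
    return np.array([0.8, 0.6, 0.4, 0.2]), np.array([1, 1, 0, 0])


def random_cohort(rng, n=50, lo=0.01, hi=0.99):
    """Random scores in (lo, hi) and Bernoulli(0.5)-ish outcomes with both
    classes present."""
    while True:
        y = rng.integers(0, 2, n)
        if 0 < y.sum() < n:
            break
    return rng.uniform(lo, hi, n), y


def random_weighting(rng, min_lo=0.02, allow_mass=True):
    """A random normalizable weighting: one density family on a random
    bounded support, optionally plus a point mass."""
    lo = rng.uniform(min_lo, 0.4)
    hi = rng.uniform(lo + 0.05, 0.95)
    kind = rng.integers(0, 4)
    if kind == 0:
        w = cb.uniform((lo, hi))
    elif kind == 1:
        w = cb.parabola((lo, hi))
    elif kind == 2:
        w = cb.half_gaussian(mean=hi, sd=(hi - lo) / 3, support=(lo, hi))
    else:
        w = cb.lognormal(mean=rng.uniform(0.08, 0.3), sdlog=rng.uniform(0.2, 0.6), support=(lo, hi))
    if allow_mass and rng.random() < 0.5:
        w = w + cb.point_mass(rng.uniform(0.05, 0.9), rng.uniform(0.1, 2.0))
    return w


def riemann_cnb(scores, outcomes, w, npts=100_000):
    """Midpoint Riemann-sum oracle for the continuous net benefit of the
    continuous part of a weighting (no point masses)."""
    assert not w.point_masses
    lo, hi = w.support
    ts = lo + (np.arange(npts) + 0.5) * (hi - lo) / npts
    curve = cb.performance_curve(scores, outcomes)
    tp, fp = curve.rates(ts)
    dens = w.density(ts)
    return float(np.sum(dens * (tp / ts - fp / (1.0 - ts))) * (hi - lo) / npts)


@pytest.fixture
def make_cohort():
    return random_cohort


@pytest.fixture
def make_weighting():
    return random_weighting


@pytest.fixture
def riemann_oracle():
    return riemann_cnb
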