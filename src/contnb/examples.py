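"""Two end-to-end validation workflows on synthetic cohorts.

Mirrors the structure of a cardiovascular model-validation study:

* ``multi_intervention`` — a model informs several decisions at once:
  statin prescription at a fixed 10% threshold (point-mass weighting) and
  overall patient management below that threshold (half-Gaussian weighting
  with mean 10% and sd 2%, nonzero below 10%), plus a uniformly weighted
  area under the net benefit between 5% and 10% as a sensitivity check.

* ``threshold_distribution`` — a single intervention whose optimal
  threshold varies across the population, modelled as a lognormal with
  arithmetic mean 0.12 and log-sd 0.3 under constant false-positive harm,
  plus a uniform area between 5% and 20%.

Both report per-policy values in true positives per 100 people, with
optional percentile bootstrap intervals.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import weighting as wt
from .inference import bootstrap_ci
from .netbenefit import (
    TREAT_ALL,
    TREAT_NONE,
    aunb,
    continuous_net_benefit,
    net_benefit,
    performance_curve,
)
from .performance import Cohort
from .simulate import SimulationConfig, simulate_cohort_with_policies
from .weighting import UniformDensity, WeightingFunction

__all__ = [
    "STATIN_THRESHOLD",
    "management_weighting",
    "uniform_threshold_density",
    "lognormal_harm_constant_weighting",
    "run_example",
]

STATIN_THRESHOLD = 0.10


def management_weighting() -> WeightingFunction:
    """Half-Gaussian importance below the 10% statin threshold, normalized.

    Mean 10%, sd 2%: lifestyle/monitoring interventions intensify as risk
    approaches the treatment threshold, and thresholds below ~5% carry
    negligible weight.
    """
    return wt.half_gaussian(mean=0.10, sd=0.02, side="below").normalize()


def uniform_threshold_density(lo: float, hi: float) -> WeightingFunction:
    """Uniform probability density over [lo, hi] (integrates to 1)."""
    return WeightingFunction(
        components=(UniformDensity((lo, hi), scale=1.0 / (hi - lo)),)
    )


def lognormal_harm_constant_weighting(
    mean: float = 0.12, sdlog: float = 0.3
) -> WeightingFunction:
    """Normalized weighting for a lognormal population of thresholds with
    constant false-positive harm: density p(t) * (1 - t)."""
    dens = wt.LogNormalDensity(mean, sdlog)
    w = wt.weighting_from_threshold_distribution(
        lambda t: dens._density_unit(t), support=(0.0, 1.0)
    )
    return w.normalize()


def _with_references(cohort: Cohort) -> dict[str, np.ndarray]:
    cols = dict(cohort.scores)
    cols[TREAT_ALL] = np.ones(cohort.n)
    cols[TREAT_NONE] = np.zeros(cohort.n)
    return cols


def _metric_table(
    cohort: Cohort,
    metrics: dict,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Evaluate each (metric name -> scores,outcomes -> per-capita value)
    for every policy, per 100 people, with optional bootstrap CIs."""
    out: dict = {}
    for mname, fn in metrics.items():
        rows = {}
        for policy, scores in _with_references(cohort).items():
            value = fn(scores, cohort.outcomes)
            row = {"value_per_100": 100.0 * value}
            if n_boot:
                sub = Cohort(cohort.outcomes, {"s": scores})
                res = bootstrap_ci(
                    lambda c: fn(c.scores["s"], c.outcomes),
                    sub,
                    n_boot=n_boot,
                    level=level,
                    seed=seed,
                )
                row["ci_low_per_100"] = 100.0 * res.ci_low
                row["ci_high_per_100"] = 100.0 * res.ci_high
            rows[policy] = row
        out[mname] = rows
    return out


def run_example(
    which: str,
    seed: int = 0,
    n: int = 4000,
    n_boot: int = 0,
    level: float = 0.95,
) -> dict:
    """Run one of the two example workflows on a fresh synthetic cohort.

    Returns a JSON-serializable report; ``n_boot=0`` skips intervals.
    """
    config = SimulationConfig(n=n, seed=seed)
    cohort, _sim = simulate_cohort_with_policies(config)

    def nb_at(t):
        return lambda s, y: net_benefit(s, y, t).value

    def cnb_under(w):
        return lambda s, y: continuous_net_benefit(performance_curve(s, y), w).value

    def uniform_area(lo, hi):
        p = uniform_threshold_density(lo, hi)
        return lambda s, y: aunb(s, y, p)

    if which == "multi_intervention":
        w_mgmt = management_weighting()
        metrics = {
            "statins_nb_at_10pct": nb_at(STATIN_THRESHOLD),
            "management_cnb_half_gaussian": cnb_under(w_mgmt),
            "uniform_area_5_to_10pct": uniform_area(0.05, 0.10),
            "uniform_area_5_to_20pct": uniform_area(0.05, 0.20),
        }
        weighting_info = {
            "management": {
                "kind": "half_gaussian",
                "mean": 0.10,
                "sd": 0.02,
                "side": "below",
                "normalization_constant": management_weighting().normalization_constant,
            }
        }
    elif which == "threshold_distribution":
        w_pop = lognormal_harm_constant_weighting()
        metrics = {
            "statins_nb_at_10pct": nb_at(STATIN_THRESHOLD),
            "expected_nb_lognormal_thresholds": cnb_under(w_pop),
            "uniform_area_5_to_20pct": uniform_area(0.05, 0.20),
        }
        weighting_info = {
            "population_thresholds": {
                "kind": "lognormal",
                "mean": 0.12,
                "sdlog": 0.3,
                "harm": "constant",
                "normalization_constant": w_pop.normalization_constant,
            }
        }
    else:
        raise ValueError(f"unknown example {which!r}")

    report = {
        "example": which,
        "seed": seed,
        "n": n,
        "incidence": cohort.incidence,
        "units": "true positives per 100 people",
        "weightings": weighting_info,
        "results": _metric_table(cohort, metrics, n_boot=n_boot, level=level, seed=seed),
    }
    return report
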