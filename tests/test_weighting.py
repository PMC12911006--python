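import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import contnb as cb
from contnb.errors import ConfigError, DivergenceError, DomainError
from contnb.weighting import (
    GaussianDensity,
    LogNormalDensity,
    PolynomialDensity,
    TabulatedDensity,
    UniformDensity,
)

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


class TestImportance:
    @pytest.mark.parametrize(
        "benefit, harm, expected",
        [(10, 1, 10 / 11), (5, 0.1, 1 / (1 / 5 + 10)), (3, 3, 1.5)],
    )
    def test_values(self, benefit, harm, expected):
        assert cb.importance(benefit, harm) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(g=positive, h=positive)
    def test_symmetric_and_bounded(self, g, h):
        v = cb.importance(g, h)
        assert v == pytest.approx(cb.importance(h, g), rel=1e-12)
        assert v <= min(g, h)

    @pytest.mark.parametrize("g,h", [(0, 1), (1, 0), (-1, 2)])
    def test_domain(self, g, h):
        with pytest.raises(DomainError):
            cb.importance(g, h)


class TestThresholdFromUtilities:
    def test_nine_to_one_gives_ten_percent(self):
        # balanced utilities with benefit:harm of 9:1 give t* = 10%
        # regardless of absolute scale
        assert cb.threshold_from_utilities(9, 1) == pytest.approx(0.1)
        assert cb.threshold_from_utilities(0.009, 0.001) == pytest.approx(0.1)

    def test_symmetry(self):
        assert cb.threshold_from_utilities(2.5, 2.5) == 0.5

    def test_consistency_with_importance_identity(self):
        # (1-t*)/t* equals the benefit/harm ratio
        g, h = 7.0, 3.0
        t = cb.threshold_from_utilities(g, h)
        assert (1 - t) / t == pytest.approx(g / h, rel=1e-12)


class TestWeightingFromUtilities:
    ts = np.linspace(0.05, 0.95, 31)

    def test_constant_harm_gives_one_minus_t(self):
        w = cb.weighting_from_utilities(harm_curve=lambda t: np.ones_like(t))
        assert np.allclose(w.density(self.ts), 1 - self.ts)

    def test_constant_benefit_gives_t(self):
        w = cb.weighting_from_utilities(benefit_curve=lambda t: np.ones_like(t))
        assert np.allclose(w.density(self.ts), self.ts)

    def test_linear_harm_gives_brier_parabola(self):
        w = cb.weighting_from_utilities(harm_curve=lambda t: t)
        assert np.allclose(w.density(self.ts), self.ts * (1 - self.ts))

    @pytest.mark.parametrize("seed", range(5))
    def test_harm_and_benefit_forms_agree(self, seed):
        # h(t)(1-t) == g(t) t when g is derived from h via (1-t)/t = g/h
        rng = np.random.default_rng(seed)
        coefs = rng.uniform(0.5, 2.0, 3)
        h = lambda t: coefs[0] + coefs[1] * t + coefs[2] * t**2
        g = lambda t: h(t) * (1 - t) / t
        wh = cb.weighting_from_utilities(harm_curve=h, support=(0.05, 0.95))
        wg = cb.weighting_from_utilities(benefit_curve=g, support=(0.05, 0.95))
        assert np.allclose(wh.density(self.ts), wg.density(self.ts), rtol=1e-12)

    def test_nonpositive_curve_rejected(self):
        with pytest.raises(DomainError):
            cb.weighting_from_utilities(harm_curve=lambda t: t - 0.5)


class TestThresholdDistributionWeighting:
    def test_constant_harm_reproduces_alt_area_weighting(self):
        p = lambda t: 2.0 * t  # arbitrary density shape
        w = cb.weighting_from_threshold_distribution(p)
        ts = np.linspace(0.1, 0.9, 17)
        assert np.allclose(w.density(ts), 2 * ts * (1 - ts))

    def test_constant_benefit_reproduces_area_weighting(self):
        p = lambda t: np.ones_like(t)
        w = cb.weighting_from_threshold_distribution(
            p, benefit_curve=lambda t: np.ones_like(t)
        )
        ts = np.linspace(0.1, 0.9, 17)
        assert np.allclose(w.density(ts), ts)


class TestBuiltins:
    def test_point_mass(self):
        w = cb.point_mass(0.1)
        assert w.point_masses[0].location == 0.1
        assert not w.components

    def test_half_gaussian_zero_above_mean(self):
        w = cb.half_gaussian(0.10, 0.02)
        assert w.density(0.12) == 0.0
        assert w.density(0.09) > 0
        # shape follows the N(0.10, 0.02^2) pdf below the mean
        from scipy import stats

        assert w.density(0.08) == pytest.approx(stats.norm.pdf(0.08, 0.10, 0.02))

    def test_parabola_peak_at_half(self):
        w = cb.parabola()
        ts = np.linspace(0.01, 0.99, 99)
        assert ts[np.argmax(w.density(ts))] == pytest.approx(0.5, abs=0.01)

    def test_lognormal_mean_parameterizations(self):
        arith = cb.lognormal(0.12, 0.3).components[0]
        logp = cb.lognormal(0.12, 0.3, mean_kind="log").components[0]
        assert arith.frozen().mean() == pytest.approx(0.12, rel=1e-12)
        assert logp.frozen().median() == pytest.approx(0.12, rel=1e-12)

    @pytest.mark.parametrize(
        "kind, params, support",
        [
            ("half_gaussian", {"mean": 0.1, "sd": -1}, None),
            ("uniform", {}, (0.5, 0.2)),
            ("uniform", {}, (-0.1, 0.5)),
            ("point_mass", {"at": 1.5}, None),
        ],
    )
    def test_invalid_params(self, kind, params, support):
        with pytest.raises(ConfigError):
            cb.builtin_weighting(kind, params, support)


class TestNormalize:
    def test_point_mass_mass_becomes_location(self):
        w = cb.point_mass(0.1, mass=7.3).normalize()
        assert w.point_masses[0].mass == pytest.approx(0.1, rel=1e-12)
        assert w.normalization_integral() == pytest.approx(1.0, abs=1e-9)

    def test_density_t_already_normalized(self):
        w = cb.WeightingFunction(
            components=(PolynomialDensity((0.0, 1.0), (0.0, 1.0)),)
        )
        assert w.normalization_integral() == pytest.approx(1.0, abs=1e-12)
        wn = w.normalize()
        assert wn.components[0].scale == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_normalize_against_fine_grid(self, seed, make_weighting):
        """Quadrature normalization agrees with an independent 1e6-point
        midpoint sum for supports bounded away from 0."""
        rng = np.random.default_rng(seed)
        w = make_weighting(rng, min_lo=0.02, allow_mass=True)
        z = w.normalization_integral()
        lo, hi = min(c.support[0] for c in w.components), max(
            c.support[1] for c in w.components
        )
        n = 1_000_000
        ts = lo + (np.arange(n) + 0.5) * (hi - lo) / n
        z_grid = float(np.sum(w.density(ts) / ts) * (hi - lo) / n)
        z_grid += sum(m.mass / m.location for m in w.point_masses)
        assert z == pytest.approx(z_grid, abs=1e-8 * max(1.0, abs(z)))
        assert w.normalize().normalization_integral() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_and_shape_preserving(self):
        w = cb.half_gaussian(0.10, 0.02).normalize()
        w2 = w.normalize()
        ts = np.linspace(0.05, 0.0999, 20)
        ratio = w.density(ts) / w2.density(ts)
        assert np.allclose(ratio, ratio[0], rtol=1e-12)
        assert w2.normalization_integral() == pytest.approx(1.0, abs=1e-10)

    def test_divergent_uniform_support_touching_zero(self):
        with pytest.raises(DivergenceError):
            cb.uniform((0.0, 0.1)).normalize()

    def test_scaling_preserves_density_ratios(self):
        w = cb.parabola((0.2, 0.8))
        ws = w.scaled(3.5)
        ts = np.linspace(0.25, 0.75, 9)
        assert np.allclose(ws.density(ts), 3.5 * w.density(ts), rtol=1e-14)


class TestMoments:
    """Closed-form kernel moments against brute quadrature."""

    kernels = ["one", "inv_t", "inv_1mt"]

    @pytest.mark.parametrize("kernel", kernels)
    @pytest.mark.parametrize(
        "comp",
        [
            UniformDensity((0.1, 0.6), scale=2.0),
            PolynomialDensity((0.5, 1.0, -0.8), (0.05, 0.9), scale=1.3),
            TabulatedDensity((0.1, 0.3, 0.7), (0.2, 1.0, 0.1)),
        ],
        ids=["uniform", "poly", "tabulated"],
    )
    def test_against_quadrature(self, comp, kernel):
        from scipy import integrate

        lo, hi = comp.support
        a, b = lo + 0.01, hi - 0.01
        kern = {"one": lambda t: 1.0, "inv_t": lambda t: 1 / t, "inv_1mt": lambda t: 1 / (1 - t)}[kernel]
        knots = [k for k in getattr(comp, "ts", ()) if a < k < b]  # kinks hurt quad
        ref, _ = integrate.quad(
            lambda t: float(comp.density(t)) * kern(t), a, b, limit=200,
            points=knots or None,
        )
        assert comp.moment(a, b, kernel) == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_moment_outside_support_is_zero(self):
        comp = UniformDensity((0.4, 0.6))
        assert comp.moment(0.1, 0.3, "inv_t") == 0.0

    @pytest.mark.parametrize(
        "comp",
        [
            UniformDensity((0.0, 0.3)),
            PolynomialDensity((1.0, 1.0), (0.0, 0.5)),
            GaussianDensity(0.1, 0.05, (0.0, 0.1)),
        ],
        ids=["uniform", "poly-const", "gaussian"],
    )
    def test_divergent_inv_t_at_zero(self, comp):
        with pytest.raises(DivergenceError):
            comp.moment(0.0, comp.support[1], "inv_t")

    def test_lognormal_integrable_at_zero(self):
        comp = LogNormalDensity(0.12, 0.3)
        assert comp.moment(0.0, 0.5, "inv_t") > 0  # vanishes fast enough at 0


class TestConfig:
    def test_single_component_yaml(self, tmp_path):
        path = tmp_path / "w.yaml"
        path.write_text("kind: point_mass\nparams: {at: '10%'}\nnormalize: true\n")
        w = cb.from_config(path)
        assert w.normalized
        assert w.point_masses[0].location == pytest.approx(0.10)
        assert w.point_masses[0].mass == pytest.approx(0.10)

    def test_summed_components(self):
        w = cb.from_config(
            {
                "components": [
                    {"kind": "point_mass", "params": {"at": 0.10}},
                    {"kind": "half_gaussian", "params": {"mean": 0.10, "sd": 0.02}},
                ],
                "normalize": False,
            }
        )
        assert len(w.components) == 1 and len(w.point_masses) == 1

    def test_from_table(self):
        w = cb.from_config(
            {"kind": "from_table", "params": {"points": [[0.05, 0.0], [0.1, 1.0], [0.2, 0.5]]}, "normalize": False}
        )
        assert w.density(0.1) == pytest.approx(1.0)
        assert w.density(0.15) == pytest.approx(0.75)

    def test_percent_strings_in_support(self):
        w = cb.from_config({"kind": "uniform", "support": ["5%", "20%"], "normalize": False})
        assert w.support == (0.05, 0.20)

    def test_unknown_kind(self):
        with pytest.raises(ConfigError):
            cb.from_config({"kind": "triangle"})
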