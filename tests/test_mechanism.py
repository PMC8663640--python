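"""Bounded Laplace mechanism: density, CDF, sampler, scale, privacy audit.

Analytic pieces are pinned against independent scipy quadrature; the
sampler against its own analytic CDF with a Kolmogorov-Smirnov test.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from ldptab import (
    BoundedLaplaceSpec,
    PrivacyBudget,
    ScaleMode,
    bounded_laplace_cdf,
    bounded_laplace_ppf,
    noise_scale,
    normalizing_constant,
    privacy_loss_ratio,
    sample_bounded_laplace,
    sample_conventional_laplace,
)
from ldptab.mechanism import _delta_c


def laplace_density(x, q, b):
    return np.exp(-np.abs(x - q) / b) / (2.0 * b)


def quad_mass(q, b, lo, hi):
    # the density has a kink at q; tell the integrator about it
    val, _ = integrate.quad(laplace_density, lo, hi, args=(q, b),
                            points=[q], limit=200)
    return val


class TestNormalizingConstant:
    @pytest.mark.parametrize("q,b", [(0.0, 20.0), (-1.0, 20.0), (0.3, 0.5),
                                     (1.0, 2.0), (-0.7, 0.05)])
    def test_matches_quadrature(self, q, b):
        spec = BoundedLaplaceSpec(b=b)
        assert normalizing_constant(q, spec) == pytest.approx(
            quad_mass(q, b, -1, 1), abs=1e-9
        )

    def test_known_values(self):
        assert normalizing_constant(0.0, BoundedLaplaceSpec(b=20.0)) == pytest.approx(
            1 - math.exp(-1 / 20), abs=1e-12
        )
        assert normalizing_constant(-1.0, BoundedLaplaceSpec(b=20.0)) == pytest.approx(
            1 - 0.5 * (1 + math.exp(-0.1)), abs=1e-12
        )

    def test_limiting_behavior(self):
        assert normalizing_constant(0.0, BoundedLaplaceSpec(b=1e6)) < 1e-5
        assert normalizing_constant(0.0, BoundedLaplaceSpec(b=1e-3)) == pytest.approx(1.0)

    def test_center_outside_domain_raises(self):
        with pytest.raises(ValueError, match="outside"):
            normalizing_constant(1.5, BoundedLaplaceSpec(b=1.0))

    def test_density_integrates_to_one(self, rng):
        for _ in range(20):
            q = rng.uniform(-1, 1)
            b = 10 ** rng.uniform(-2, 2)
            spec = BoundedLaplaceSpec(b=b)
            c = normalizing_constant(q, spec)
            val, _ = integrate.quad(
                lambda x: laplace_density(x, q, b) / c, -1, 1,
                points=[q], limit=200,
            )
            assert val == pytest.approx(1.0, abs=1e-8)


class TestCdfAndInverse:
    @pytest.mark.parametrize("q,b", [(0.0, 20.0), (-1.0, 20.0), (-0.3, 0.5),
                                     (0.9, 0.1)])
    def test_endpoints_and_monotonicity(self, q, b):
        spec = BoundedLaplaceSpec(b=b)
        assert bounded_laplace_cdf(-1.0, q, spec) == pytest.approx(0.0, abs=1e-12)
        assert bounded_laplace_cdf(1.0, q, spec) == pytest.approx(1.0, abs=1e-12)
        x = np.linspace(-1, 1, 500)
        assert np.all(np.diff(bounded_laplace_cdf(x, q, spec)) > 0)

    def test_symmetric_center_has_median_at_zero(self):
        assert bounded_laplace_cdf(0.0, 0.0, BoundedLaplaceSpec(b=3.0)) == pytest.approx(0.5)

    def test_cdf_matches_quadrature_at_pinned_point(self):
        q, b = -1.0, 20.0
        spec = BoundedLaplaceSpec(b=b)
        c = normalizing_constant(q, spec)
        expected = quad_mass(q, b, -1, 0.0) / c
        assert bounded_laplace_cdf(0.0, q, spec) == pytest.approx(expected, abs=1e-9)

    def test_clamps_outside_domain(self):
        spec = BoundedLaplaceSpec(b=1.0)
        assert bounded_laplace_cdf(-5.0, 0.0, spec) == 0.0
        assert bounded_laplace_cdf(5.0, 0.0, spec) == 1.0

    @pytest.mark.parametrize("q,b", [(0.0, 20.0), (-1.0, 0.5), (0.6, 2.0),
                                     (1.0, 0.01)])
    def test_round_trip_on_dense_grid(self, q, b):
        spec = BoundedLaplaceSpec(b=b)
        u = np.linspace(0.0, 1.0, 10_000)
        err = np.abs(bounded_laplace_cdf(bounded_laplace_ppf(u, q, spec), q, spec) - u)
        assert err.max() <= 1e-9

    def test_ppf_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            bounded_laplace_ppf(1.2, 0.0, BoundedLaplaceSpec(b=1.0))


class TestBoundedSampler:
    def test_support_never_leaves_domain(self, rng):
        spec = BoundedLaplaceSpec(b=20.0)  # eps=0.1 naive
        for q in (-1.0, -0.5, 0.0, 0.5, 1.0):
            x = sample_bounded_laplace(np.full(100_000, q), spec, rng)
            assert x.min() >= -1.0 and x.max() <= 1.0

    def test_tiny_scale_collapses_to_center(self, rng):
        spec = BoundedLaplaceSpec(b=1e-9)
        x = sample_bounded_laplace(np.full(1000, 0.37), spec, rng)
        assert np.max(np.abs(x - 0.37)) < 1e-6

    def test_ks_against_analytic_cdf(self, rng):
        q, b = -0.3, 0.5
        spec = BoundedLaplaceSpec(b=b)
        x = sample_bounded_laplace(np.full(100_000, q), spec, rng)
        res = stats.kstest(x, lambda v: bounded_laplace_cdf(v, q, spec))
        assert res.pvalue > 0.01

    def test_variance_nondecreasing_in_scale(self, rng):
        # Monte-Carlo monotonicity of spread with the noise scale
        n = 200_000
        prev = -1.0
        for b in (0.05, 0.2, 1.0, 5.0):
            x = sample_bounded_laplace(np.full(n, 0.2), BoundedLaplaceSpec(b=b), rng)
            v = x.var()
            se = np.sqrt(2.0 / n) * v  # rough SE of a variance estimate
            assert v > prev - 3 * se
            prev = v


class TestConventionalSampler:
    def test_mean_unbiased(self, rng):
        n, q, b = 100_000, 0.4, 2.0
        x = sample_conventional_laplace(np.full(n, q), b, rng)
        assert abs(x.mean() - q) < 4 * b / np.sqrt(n)

    def test_out_of_range_fraction_matches_tail_mass(self, rng):
        # P(|X| > 1) = e^{-1/b} for X ~ Laplace(0, b); b=20 is eps=0.1
        n, b = 200_000, 20.0
        x = sample_conventional_laplace(np.zeros(n), b, rng)
        frac = np.mean(np.abs(x) > 1.0)
        assert frac == pytest.approx(math.exp(-1 / 20), abs=0.01)

    def test_bounded_vs_conventional_contrast(self, rng):
        # at eps=0.1 the conventional sampler escapes the domain, the bounded never
        b = 20.0
        conv = sample_conventional_laplace(np.zeros(10_000), b, rng)
        bound = sample_bounded_laplace(np.zeros(10_000), BoundedLaplaceSpec(b=b), rng)
        assert np.mean(np.abs(conv) > 1.0) > 0.9
        assert np.all(np.abs(bound) <= 1.0)


class TestNoiseScale:
    @pytest.mark.parametrize("eps,expected", [(0.1, 20.0), (1000.0, 0.002)])
    def test_naive_is_sensitivity_over_epsilon(self, eps, expected):
        assert noise_scale(PrivacyBudget(epsilon=eps)) == pytest.approx(expected)

    def test_calibrated_solves_the_fixed_point(self):
        # independent residual check: b* = sensitivity / (eps - ln dC(b*)),
        # with dC computed by a dense grid over centers
        budget = PrivacyBudget(epsilon=1.0)
        b = noise_scale(budget, ScaleMode.CALIBRATED)
        qs = np.linspace(-1, 1, 20_001)
        cs = normalizing_constant(qs, BoundedLaplaceSpec(b=b))
        dc = cs.max() / cs.min()
        assert dc == pytest.approx(_delta_c(b, -1.0, 1.0), rel=1e-9)
        assert b == pytest.approx(budget.sensitivity / (budget.epsilon - math.log(dc)),
                                  abs=1e-6)

    def test_calibrated_exceeds_naive(self):
        for eps in (0.1, 1.0, 10.0):
            budget = PrivacyBudget(epsilon=eps)
            assert noise_scale(budget, "calibrated") > noise_scale(budget, "naive")

    def test_budget_validation(self):
        with pytest.raises(ValueError):
            PrivacyBudget(epsilon=0.0)
        with pytest.raises(ValueError):
            PrivacyBudget(epsilon=1.0, delta=1.0)


class TestPrivacyLossRatio:
    def test_identical_centers_give_one(self):
        spec = BoundedLaplaceSpec(b=2.0)
        assert privacy_loss_ratio(spec, 0.3, 0.3) == pytest.approx(1.0)

    @pytest.mark.parametrize("q1,q2,b", [(0.0, -1.0, 20.0), (-1.0, 0.5, 2.0),
                                         (0.9, -0.9, 0.7)])
    def test_closed_form_matches_grid_search(self, q1, q2, b):
        spec = BoundedLaplaceSpec(b=b)
        x = np.linspace(-1, 1, 200_001)
        c1 = normalizing_constant(q1, spec)
        c2 = normalizing_constant(q2, spec)
        ratio = (laplace_density(x, q1, b) / c1) / (laplace_density(x, q2, b) / c2)
        assert privacy_loss_ratio(spec, q1, q2) == pytest.approx(ratio.max(), rel=1e-6)

    def test_naive_scale_is_exactly_tight_at_the_endpoint_pair(self):
        # sensitivity = domain width: the normalizing constants cancel at
        # (l, u) and the worst-case log-ratio equals epsilon exactly, so
        # the naive scale already achieves pure epsilon-DP on this geometry
        eps = 0.1
        spec = BoundedLaplaceSpec(b=noise_scale(PrivacyBudget(epsilon=eps)))
        qs = np.linspace(-1, 1, 50)
        worst = max(
            math.log(privacy_loss_ratio(spec, q1, q2))
            for q1 in qs for q2 in qs
        )
        assert worst == pytest.approx(eps, abs=1e-12)

    def test_calibrated_scale_passes_the_audit(self):
        eps = 0.1
        b = noise_scale(PrivacyBudget(epsilon=eps), "calibrated")
        spec = BoundedLaplaceSpec(b=b)
        qs = np.linspace(-1, 1, 50)
        worst = max(
            math.log(privacy_loss_ratio(spec, q1, q2))
            for q1 in qs for q2 in qs
        )
        assert worst <= eps + 1e-9
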