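"""Closed-form point-measurement model: steady state, accumulation time,
cost, precision and the lambda-optimized trade-off."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphocost.errors import (
    DomainError,
    InvalidParameterError,
    SingularInputError,
)
from morphocost.lattice import LatticeConfig, pde_accumulation_time, pde_oracle
from morphocost.params import CostParams, SddParams
from morphocost.pointmodel import (
    LARGE_L_OPTIMAL_RATIO,
    accumulation_time,
    cost_point,
    normalized_product_point,
    optimal_lambda_point,
    positional_error_point,
    positional_variance,
    steady_state_profile,
    threshold_fraction,
    tradeoff_point,
)

COST = CostParams()


def make_params(L_over_lam=50.0, lam=1.0, jin=1.0, **kw):
    return SddParams.from_lambda(L=L_over_lam * lam, lam=lam, jin=jin, **kw)


class TestSteadyState:
    def test_source_amplitude_large_L(self):
        p = make_params(50.0)
        rho0 = steady_state_profile(p, [0.0]).rho[0]
        assert rho0 == pytest.approx(p.jin / math.sqrt(p.D * p.kd), rel=1e-12)

    def test_exponential_decay_large_L(self):
        p = make_params(50.0)
        prof = steady_state_profile(p, [0.0, p.lam])
        assert prof.rho[1] / prof.rho[0] == pytest.approx(math.exp(-1.0), rel=1e-10)

    def test_profile_is_decreasing_and_flat_at_far_wall(self):
        p = make_params(5.0)
        x = np.linspace(0.0, p.L, 201)
        rho = steady_state_profile(p, x).rho
        assert np.all(np.diff(rho) < 0)
        # reflecting wall: one-sided slope at L is ~0 relative to bulk slope
        slope_end = (rho[-1] - rho[-2]) / (x[-1] - x[-2])
        slope_bulk = (rho[1] - rho[0]) / (x[1] - x[0])
        assert abs(slope_end / slope_bulk) < 1e-2

    def test_flux_balance(self):
        # conservation: total degradation equals influx at steady state
        from scipy.integrate import quad

        p = make_params(7.0, lam=2.0, jin=3.5)
        total, _ = quad(lambda x: steady_state_profile(p, [x]).rho[0], 0.0, p.L,
                        limit=200)
        assert p.kd * total == pytest.approx(p.jin, rel=1e-8)

    def test_matches_pde_long_time_limit(self):
        # method-of-lines integration of the dynamics reaches the closed form
        cfg = LatticeConfig(n_cells=25, hop_rate=25.0, kd=1.0, injection_rate=100.0)
        res = pde_oracle(cfg, 50.0, dt=0.01, n_sub=100)
        p = SddParams.from_lambda(L=25.0, lam=5.0, jin=100.0)
        rho = steady_state_profile(p, res.x).rho
        np.testing.assert_allclose(res.counts[-1], rho / 100.0, rtol=1e-6)

    def test_no_overflow_for_huge_systems(self):
        p = make_params(5000.0)
        rho = steady_state_profile(p, [0.0, 10.0 * p.lam]).rho
        assert np.all(np.isfinite(rho))
        assert rho[1] / rho[0] == pytest.approx(math.exp(-10.0), rel=1e-9)

    def test_domain_and_parameter_errors(self):
        p = make_params(5.0)
        with pytest.raises(DomainError):
            steady_state_profile(p, [-0.1])
        with pytest.raises(DomainError):
            steady_state_profile(p, [p.L + 0.1])
        with pytest.raises(InvalidParameterError):
            SddParams(L=1.0, lcell=1.0, vcell=1.0, D=math.nan, kd=1.0, jin=1.0)
        with pytest.raises(InvalidParameterError):
            SddParams(L=-1.0, lcell=1.0, vcell=1.0, D=1.0, kd=1.0, jin=1.0)


class TestAccumulationTime:
    def test_source_end_limit(self):
        p = make_params(100.0, kd=2.0)
        assert accumulation_time(p, 0.0) == pytest.approx(1.0 / (2.0 * 2.0), rel=1e-9)

    def test_linear_growth_large_L(self):
        p = make_params(100.0)
        assert accumulation_time(p, 10.0 * p.lam) == pytest.approx(
            (1.0 + 10.0) / 2.0, rel=1e-6
        )

    def test_monotone_in_x(self):
        p = make_params(5.0)
        taus = accumulation_time(p, np.linspace(0.0, p.L, 50))
        assert np.all(np.diff(taus) >= 0)

    def test_matches_pde_quadrature(self):
        # independent route: time-integrate the relaxation deficit
        cfg = LatticeConfig(n_cells=25, hop_rate=25.0, kd=1.0, injection_rate=100.0)
        res = pde_oracle(cfg, 40.0, dt=0.005, n_sub=30)
        p = SddParams.from_lambda(L=25.0, lam=5.0, jin=100.0)
        for x in (2.5, 7.5, 12.5, 17.5, 22.5):
            assert pde_accumulation_time(res, x) == pytest.approx(
                accumulation_time(p, x), rel=1e-4
            )


class TestCost:
    def test_linear_in_jin(self):
        p = make_params(5.0)
        c1 = cost_point(p, COST, 2.0)
        c2 = cost_point(p.with_(jin=2.0 * p.jin), COST, 2.0)
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_source_end_large_L(self):
        p = make_params(100.0, jin=7.0)
        assert cost_point(p, COST, 0.0) == pytest.approx(p.nm / 2.0, rel=1e-9)

    def test_bicoid_geometry_f_factor(self):
        # f(0.4 L; lam = 0.2 L) for the Bicoid configuration
        p = SddParams.from_lambda(L=1.0, lam=0.2)
        f = cost_point(p, COST, 0.4) / p.nm
        assert f == pytest.approx(1.5076, abs=5e-4)


class TestPositionalError:
    def test_inverse_production_scaling(self):
        p = make_params(5.0)
        e1 = positional_error_point(p, 2.0)
        e2 = positional_error_point(p.with_(jin=0.5 * p.jin), 2.0)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_functional_form_large_L(self):
        p = make_params(200.0)
        x = np.linspace(2.0, 40.0, 20)
        e2 = positional_error_point(p, x)
        combo = e2 * x**2 * np.exp(-x / p.lam)
        assert np.ptp(combo) / combo[0] < 1e-9

    def test_singular_endpoints(self):
        p = make_params(5.0)
        with pytest.raises(SingularInputError):
            positional_error_point(p, 0.0)
        with pytest.raises(SingularInputError):
            positional_error_point(p, p.L)

    def test_consistent_with_poisson_slope_route(self):
        # sigma_x^2 = sigma_rho^2/slope^2 with Poisson concentration noise
        p = make_params(60.0, lam=2.0, jin=3.0, vcell=4.0)
        x = 10.0
        rho = steady_state_profile(p, [x]).rho[0]
        slope = -rho / p.lam  # exponential regime
        sigma_rho_sq = rho / p.vcell
        eps2 = positional_variance(slope, sigma_rho_sq) / x**2
        assert eps2 == pytest.approx(positional_error_point(p, x), rel=1e-4)


class TestPositionalVariance:
    def test_examples_and_errors(self):
        assert positional_variance(-2.0, 4.0) == 1.0
        assert positional_variance(3.0, 0.0) == 0.0
        with pytest.raises(SingularInputError):
            positional_variance(0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            positional_variance(1.0, -1.0)


class TestTradeoff:
    def test_production_cancellation(self):
        p1 = make_params(5.0, jin=1.0)
        p2 = make_params(5.0, jin=1e6, vcell=13.0)
        r1 = tradeoff_point(p1, COST, 2.0)
        r2 = tradeoff_point(p2, COST, 2.0)
        assert r1.product == pytest.approx(r2.product, rel=1e-12)
        assert r1.product == pytest.approx(r1.cost * r1.precision_sq, rel=1e-12)

    def test_bicoid_normalized_product(self):
        p = SddParams.from_lambda(L=1.0, lam=0.2, jin=3.0)
        r = tradeoff_point(p, COST, 0.4)
        # direct evaluation of cost x error at the Bicoid geometry
        assert r.product_normalized == pytest.approx(0.561137, abs=1e-5)
        assert round(r.product_normalized, 1) == 0.6
        assert r.product >= r.product_min

    def test_unit_system_invariance(self):
        um = SddParams(L=500.0, lcell=10.0, vcell=8.0, D=100.0, kd=0.01, jin=5.0)
        cell = SddParams(L=50.0, lcell=1.0, vcell=1.0, D=100.0, kd=1.0, jin=5.0)
        r_um = tradeoff_point(um, COST, 200.0)
        r_cell = tradeoff_point(cell, COST, 20.0)
        assert r_um.product_normalized == pytest.approx(
            r_cell.product_normalized, rel=1e-10
        )


class TestOptimalLambda:
    def test_closed_form_root_large_L(self):
        # stationarity of (1+s) s^-3 e^s gives s^2 - s - 3 = 0
        s = 0.5 * (1.0 + math.sqrt(13.0))
        assert s * s - s - 3.0 == pytest.approx(0.0, abs=1e-12)
        lam_min, _ = optimal_lambda_point(1.0, 50.0)
        assert lam_min == pytest.approx(LARGE_L_OPTIMAL_RATIO, rel=1e-6)

    def test_local_optimality(self):
        lam_min, prod_min = optimal_lambda_point(0.4, 1.0)
        for bump in (1 - 1e-3, 1 + 1e-3):
            assert normalized_product_point(0.4, lam_min * bump, 1.0) >= prod_min

    def test_monotone_in_boundary_position(self):
        xbs = np.linspace(0.05, 0.5, 23)
        lam_mins, prods = zip(*(optimal_lambda_point(xb, 1.0) for xb in xbs))
        assert np.all(np.diff(lam_mins) > 0)
        assert np.all(np.diff(prods) > 0)

    def test_large_L_formula_consistency(self):
        # finite-L product approaches the exponential-limit expression
        xb, lam = 1.0, 0.45
        finite = normalized_product_point(xb, lam, 60.0 * lam)
        s = xb / lam
        # pi/(alpha_o L/lcell) = (x/2L)(1+s) s^-3 e^s in the large-L limit
        exponential = (xb / (2.0 * 60.0 * lam)) * (1 + s) * s**-3 * math.exp(s)
        assert finite == pytest.approx(exponential, rel=1e-6)


class TestThresholdFraction:
    @pytest.mark.parametrize(
        "lam_over_xb, expected",
        [(1.0, math.exp(-1.0)), (LARGE_L_OPTIMAL_RATIO, 0.1000), (0.5, math.exp(-2.0))],
    )
    def test_values(self, lam_over_xb, expected):
        assert threshold_fraction(1.0, lam_over_xb) == pytest.approx(expected, abs=2e-4)


@given(
    lam=st.floats(0.5, 4.0),
    l_ratio=st.floats(5.0, 80.0),
    jin=st.floats(0.1, 1e5),
    vcell=st.floats(0.1, 50.0),
)
def test_product_production_invariance_property(lam, l_ratio, jin, vcell):
    """pi_o never depends on the production amplitude or cell volume."""
    base = make_params(l_ratio, lam=lam)
    scaled = make_params(l_ratio, lam=lam, jin=jin, vcell=vcell)
    xb = 0.4 * base.L
    r0 = tradeoff_point(base, COST, xb)
    r1 = tradeoff_point(scaled, COST, xb)
    assert r1.product == pytest.approx(r0.product, rel=1e-12)


@given(l_ratio=st.floats(3.0, 60.0), lam=st.floats(0.3, 3.0))
def test_flux_balance_property(l_ratio, lam):
    """Depletion integrates to the influx for any parameter set."""
    from scipy.integrate import quad

    p = make_params(l_ratio, lam=lam, jin=2.7)
    total, _ = quad(lambda x: steady_state_profile(p, [x]).rho[0], 0.0, p.L,
                    limit=200)
    assert p.kd * total == pytest.approx(p.jin, rel=1e-8)
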