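"""Reversible-kinetics lattice: entropy production, relaxation time, and
the dissipation-speed-precision trade-off."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from morphocost.errors import InvalidParameterError, NoSteadyStateError
from morphocost.lattice import LatticeConfig, lattice_steady_state
from morphocost.params import SddParams
from morphocost.pointmodel import accumulation_time
from morphocost.thermo import (
    ReversibleRates,
    detailed_balance_rates,
    entropy_production_rate,
    estimate_entropy_rate_ssa,
    generator_matrix,
    optimal_hop_reversible,
    relaxation_time_reversible,
    sample_reversible_counts,
    steady_state_reversible,
    tradeoff_reversible,
)

NESS = ReversibleRates(synth_fwd=100.0, synth_rev=0.2, deg_fwd=1.0, deg_rev=0.05,
                       hop_fwd=9.0, hop_rev=9.0, n_cells=30)


class TestDetailedBalance:
    def test_equilibrium_profile_and_zero_entropy(self):
        db = detailed_balance_rates(8, occupancy=5.0)
        ss = steady_state_reversible(db)
        np.testing.assert_allclose(ss, 5.0, rtol=1e-12)
        report = entropy_production_rate(db, ss)
        assert not report.divergent
        assert abs(report.rate) < 1e-10
        # zero net flux edge by edge
        assert db.synth_fwd == pytest.approx(db.synth_rev * ss[0])
        assert db.deg_fwd * ss[3] == pytest.approx(db.deg_rev)

    def test_degenerate_tradeoff_flag(self):
        r = tradeoff_reversible(detailed_balance_rates(8), 3.5)
        assert r.degenerate
        assert r.product == 0.0


class TestEntropyProduction:
    def test_single_unbalanced_edge(self):
        # only the synthesis edge carries flux: J+=2, J-=1 -> (2-1) ln 2
        rates = ReversibleRates(synth_fwd=2.0, synth_rev=1.0, deg_fwd=0.0,
                                deg_rev=0.0, hop_fwd=1.0, hop_rev=1.0, n_cells=3)
        ss = np.ones(3)
        report = entropy_production_rate(rates, ss)
        assert report.rate == pytest.approx(math.log(2.0), rel=1e-12)

    def test_nonnegative_on_random_networks(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            r = ReversibleRates(*rng.uniform(0.05, 10.0, size=6), n_cells=6)
            report = entropy_production_rate(r)
            assert report.rate >= -1e-12

    def test_divergent_flagged_not_infinite_silently(self):
        rates = ReversibleRates(synth_fwd=10.0, synth_rev=0.0, deg_fwd=1.0,
                                deg_rev=0.0, hop_fwd=2.0, hop_rev=2.0, n_cells=5)
        assert rates.is_irreversible
        report = entropy_production_rate(rates)
        assert report.divergent
        assert math.isinf(report.rate)
        assert any("synthesis" in e for e in report.divergent_edges)

    def test_path_estimator_matches_stationary_rate(self):
        rates = ReversibleRates(synth_fwd=20.0, synth_rev=0.5, deg_fwd=1.0,
                                deg_rev=0.3, hop_fwd=3.0, hop_rev=2.0, n_cells=5)
        theory = entropy_production_rate(rates).rate
        ests = np.array([
            estimate_entropy_rate_ssa(rates, 20.0, 2020.0, seed=1000 + i)
            for i in range(8)
        ])
        se = ests.std(ddof=1) / math.sqrt(ests.size)
        assert abs(ests.mean() - theory) < 3.0 * se

    def test_estimator_requires_reversibility(self):
        rates = ReversibleRates(synth_fwd=10.0, synth_rev=0.0, deg_fwd=1.0,
                                deg_rev=0.0, hop_fwd=2.0, hop_rev=2.0, n_cells=5)
        with pytest.raises(InvalidParameterError):
            estimate_entropy_rate_ssa(rates, 1.0, 10.0, seed=1)


class TestSteadyState:
    def test_irreversible_limit_matches_lattice_closed_form(self):
        rates = ReversibleRates(synth_fwd=100.0, synth_rev=0.0, deg_fwd=1.0,
                                deg_rev=0.0, hop_fwd=25.0, hop_rev=25.0, n_cells=50)
        cfg = LatticeConfig(n_cells=50, hop_rate=25.0, kd=1.0, injection_rate=100.0)
        np.testing.assert_allclose(
            steady_state_reversible(rates), lattice_steady_state(cfg), rtol=1e-8
        )

    def test_no_removal_raises(self):
        with pytest.raises(NoSteadyStateError):
            steady_state_reversible(
                ReversibleRates(synth_fwd=1.0, synth_rev=0.0, deg_fwd=0.0,
                                deg_rev=0.0, hop_fwd=1.0, hop_rev=1.0, n_cells=5)
            )

    def test_dense_solver_cross_check(self):
        A, b = generator_matrix(NESS)
        dense = np.linalg.solve(A, -b)
        np.testing.assert_allclose(steady_state_reversible(NESS), dense, rtol=1e-10)


class TestRelaxationTime:
    def test_resolvent_matches_ode_quadrature(self):
        ss = steady_state_reversible(NESS)
        A, b = generator_matrix(NESS)
        sol = solve_ivp(lambda t, u: A @ u + b, (0.0, 80.0), np.zeros(NESS.n_cells),
                        rtol=1e-11, atol=1e-13, method="LSODA", dense_output=True)
        ts = np.linspace(0.0, 80.0, 40001)
        traj = sol.sol(ts)
        for x in (5.5, 12.5, 20.5):
            i = int(x)
            quad = np.trapezoid(1.0 - traj[i] / ss[i], ts)
            assert relaxation_time_reversible(NESS, x, ss) == pytest.approx(
                quad, rel=1e-6
            )

    def test_irreversible_limit_recovers_accumulation_time(self):
        rates = ReversibleRates(synth_fwd=100.0, synth_rev=0.0, deg_fwd=1.0,
                                deg_rev=0.0, hop_fwd=25.0, hop_rev=25.0, n_cells=200)
        ss = steady_state_reversible(rates)
        p = SddParams.from_lambda(L=200.0, lam=5.0, jin=100.0)
        for x in (10.5, 30.5, 60.5):
            tau = relaxation_time_reversible(rates, x, ss)
            # continuum formula, up to O((lcell/lam)^2) lattice discretization
            assert tau == pytest.approx(accumulation_time(p, x), rel=0.01)

    def test_continuous_in_reverse_synthesis(self):
        taus = []
        for sr in np.linspace(0.05, 0.4, 8):
            r = ReversibleRates(synth_fwd=100.0, synth_rev=sr, deg_fwd=1.0,
                                deg_rev=0.05, hop_fwd=9.0, hop_rev=9.0, n_cells=30)
            taus.append(relaxation_time_reversible(r, 10.5))
        assert np.all(np.abs(np.diff(taus)) < 0.2)


class TestTradeoff:
    def test_product_assembly_and_positivity(self):
        r = tradeoff_reversible(NESS, 10.5)
        assert r.product == pytest.approx(
            r.entropy_rate * r.tau_rev * r.epsilon_rev_sq, rel=1e-12
        )
        assert r.entropy_rate > 0 and r.tau_rev > 0 and r.epsilon_rev_sq > 0

    def test_irreversible_limit_flagged(self):
        rates = ReversibleRates(synth_fwd=10.0, synth_rev=0.0, deg_fwd=1.0,
                                deg_rev=0.0, hop_fwd=4.0, hop_rev=4.0, n_cells=20)
        r = tradeoff_reversible(rates, 5.5)
        assert r.irreversible and math.isinf(r.product)

    def test_near_irreversible_dissipation_tracks_cost(self):
        # S_dot tau(x) is proportional to the molecule-count cost C(x)/alpha_o
        # across positions (the affinity per event is position-independent)
        eps = 1e-8
        rates = ReversibleRates(synth_fwd=100.0, synth_rev=eps, deg_fwd=1.0,
                                deg_rev=eps, hop_fwd=25.0, hop_rev=25.0, n_cells=50)
        ss = steady_state_reversible(rates)
        sdot = entropy_production_rate(rates, ss).rate
        p = SddParams.from_lambda(L=50.0, lam=5.0, jin=100.0)
        ratios = []
        for x in (5.5, 10.5, 15.5, 20.5):
            tau = relaxation_time_reversible(rates, x, ss)
            cost_molecules = p.nm * p.kd * accumulation_time(p, x)
            ratios.append(sdot * tau / cost_molecules)
        ratios = np.asarray(ratios)
        assert np.ptp(ratios) / ratios.mean() < 0.05

    def test_minimized_product_monotone_in_boundary(self):
        prods = [optimal_hop_reversible(NESS, xb)[1] for xb in (6.5, 10.5, 14.5, 18.5)]
        assert np.all(np.diff(prods) > 0)


class TestPoissonStationarity:
    def test_reversible_ssa_fano_near_one(self):
        rates = ReversibleRates(synth_fwd=30.0, synth_rev=0.5, deg_fwd=1.0,
                                deg_rev=0.5, hop_fwd=3.0, hop_rev=2.0, n_cells=5)
        times = 20.0 + 2.0 * np.arange(1500)
        counts = sample_reversible_counts(rates, times, seed=314).astype(float)
        fano = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        assert np.all(fano > 0.9) and np.all(fano < 1.1)
        # and the means agree with the linear solve
        ss = steady_state_reversible(rates)
        np.testing.assert_allclose(counts.mean(axis=0), ss, rtol=0.1)
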