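"""Shared fixtures: the expensive stochastic ensembles are simulated once
per session and reused by the unit and validation tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morphocost.lattice import (
    STANDARD_FIXTURE,
    LatticeConfig,
    simulate_ensemble,
    simulate_ssa,
    window_average_counts,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def stationary_run():
    """One long run of the standard fixture, sampled past burn-in.

    4000 snapshots spaced 2/kd after a 30/kd burn-in: enough effective
    samples that per-cell Fano factors resolve to ~+-0.02 (1 s.e.).
    """
    burnin, spacing, n_snap = 30.0, 2.0, 4000
    times = burnin + spacing * np.arange(n_snap)
    run = simulate_ssa(STANDARD_FIXTURE, times[-1], sample_times=times)
    return {"run": run, "burnin": burnin, "spacing": spacing}


@pytest.fixture(scope="session")
def relaxation_runs():
    """600 zero-start replicates of the standard fixture out to 12/kd."""
    times = np.linspace(0.0, 12.0, 121)
    return simulate_ensemble(STANDARD_FIXTURE, 600, 12.0, sample_times=times)


#: lattice used for the window-average validation: lam = 2 lcell keeps the
#: event rate low enough for 500 independent 200/kd measurements.
WINDOW_CONFIG = LatticeConfig(
    n_cells=50, hop_rate=4.0, kd=1.0, injection_rate=100.0, seed=77
)
WINDOW_X, WINDOW_A, WINDOW_T, WINDOW_BURNIN = 5.0, 0.5, 200.0, 30.0


@pytest.fixture(scope="session")
def window_samples():
    """500 independent space-time window averages m_i(x), with geometry."""
    seeds = np.random.SeedSequence(WINDOW_CONFIG.seed).generate_state(500)
    t_end = WINDOW_BURNIN + WINDOW_T
    times = np.arange(0.0, t_end + 0.05, 0.05)
    samples = []
    for sd in seeds:
        run = simulate_ssa(WINDOW_CONFIG.with_seed(int(sd)), times[-1],
                           sample_times=times)
        samples.append(
            window_average_counts(run, WINDOW_X, WINDOW_A, WINDOW_T, WINDOW_BURNIN)
        )
    return {
        "samples": np.asarray(samples),
        "config": WINDOW_CONFIG,
        "x": WINDOW_X,
        "a": WINDOW_A,
        "T": WINDOW_T,
    }
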