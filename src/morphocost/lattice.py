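"""Particle-level lattice simulator and deterministic PDE oracle.

The synthetic-data generator of the package: an exact (Gillespie) stochastic
simulation of the birth-hop-death lattice whose continuum limit is the SDD
reaction-diffusion equation.  Molecules are injected into cell 0 at a
constant rate, hop symmetrically between nearest neighbours (reflecting
walls at both ends) and are degraded everywhere at first order.  Because all
reactions are of zeroth or first order, the stationary law is
product-form Poisson cell by cell -- the statistical structure the analytic
precision formulas assume (variance = mean, i.e. Fano factor 1).

The module also provides a tau-leaping approximation, a deterministic
method-of-lines integrator of the continuum equation (the "PDE oracle"),
ensemble moment estimators, an empirical accumulation-time estimator, and
the space-time window-average sampler used to validate the sensor-model
variance formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import (
    DomainError,
    EstimationError,
    InvalidParameterError,
    NumericalError,
    ResourceBudgetError,
    ValidityError,
)
from .pointmodel import accumulation_f

__all__ = [
    "LatticeConfig",
    "SimResult",
    "EnsembleStats",
    "PdeResult",
    "STANDARD_FIXTURE",
    "simulate_ssa",
    "simulate_ensemble",
    "simulate_tau_leap",
    "estimate_stationary_moments",
    "estimate_accumulation_time",
    "window_average_counts",
    "pde_oracle",
    "pde_accumulation_time",
    "lattice_steady_state",
    "lattice_config_from_config",
    "run_to_csv",
    "run_to_parquet",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Configuration of the stochastic lattice.

    ``hop_rate`` is the per-molecule nearest-neighbour hop rate
    ``D / lcell^2``; ``injection_rate`` is ``vcell * jin / lcell``, the
    molecule injection rate into cell 0.  The implied decay length in cell
    units is ``sqrt(hop_rate / kd)``.
    """

    n_cells: int
    hop_rate: float
    kd: float
    injection_rate: float
    lcell: float = 1.0
    seed: int = 0
    event_budget: float = 4e9

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise InvalidParameterError("need at least 3 cells")
        for name in ("hop_rate", "kd", "injection_rate", "lcell"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be positive, got {v!r}")
        if not (0 <= int(self.seed) < 2**32):
            raise InvalidParameterError("seed must fit in uint32")

    @property
    def lam(self) -> float:
        """Decay length sqrt(D/kd) in length units."""
        return math.sqrt(self.hop_rate / self.kd) * self.lcell

    @property
    def L(self) -> float:
        return self.n_cells * self.lcell

    @property
    def cell_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.lcell

    def with_seed(self, seed: int) -> "LatticeConfig":
        return LatticeConfig(
            n_cells=self.n_cells, hop_rate=self.hop_rate, kd=self.kd,
            injection_rate=self.injection_rate, lcell=self.lcell,
            seed=int(seed), event_budget=self.event_budget,
        )


#: fixed fixture used throughout the validation suite: 50 cells,
#: lam = 5 lcell (hop = 25 kd), nm = 10^3 molecules, documented seed.
STANDARD_FIXTURE = LatticeConfig(
    n_cells=50, hop_rate=25.0, kd=1.0, injection_rate=1000.0, seed=20210817
)


@dataclass(frozen=True)
class SimResult:
    """Sampled trajectory of one stochastic (or tau-leap) run."""

    times: np.ndarray
    counts: np.ndarray  # shape (n_samples, n_cells), integers
    seed: int
    config: LatticeConfig
    method: str = "ssa"

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be nonnegative")


@dataclass(frozen=True)
class EnsembleStats:
    """Per-cell stationary moments estimated from an ensemble of runs."""

    n_runs: int
    n_samples: int
    mean: np.ndarray
    variance: np.ndarray
    fano: np.ndarray
    se_mean: np.ndarray
    se_fano: np.ndarray
    window_samples: np.ndarray | None = None


def _expected_events(config: LatticeConfig, t_end: float) -> float:
    n_ss = config.injection_rate / config.kd
    per_molecule = config.kd + 2.0 * config.hop_rate
    return t_end * (config.injection_rate + n_ss * per_molecule)


def _sample_times(t_end: float, sample_times, n_samples: int) -> np.ndarray:
    if sample_times is None:
        return np.linspace(0.0, t_end, n_samples)
    st = np.asarray(sample_times, dtype=float)
    if st.ndim != 1 or st.size == 0 or np.any(np.diff(st) < 0) or st[0] < 0:
        raise InvalidParameterError("sample_times must be a nondecreasing 1D array")
    if st[-1] > t_end:
        raise DomainError("sample times extend beyond t_end")
    return st


def simulate_ssa(
    config: LatticeConfig,
    t_end: float,
    *,
    sample_times: Sequence[float] | np.ndarray | None = None,
    n_samples: int = 201,
) -> SimResult:
    """Exact event-driven simulation from the all-zero initial state.

    Snapshots of the per-cell counts are recorded at ``sample_times``
    (default: uniform grid on [0, t_end]).  Runs whose expected event count
    exceeds ``config.event_budget`` are refused; use
    :func:`simulate_tau_leap` for such regimes.
    """
    from ._kernels import ssa_lattice

    if t_end <= 0:
        raise InvalidParameterError("t_end must be positive")
    expected = _expected_events(config, t_end)
    if expected > config.event_budget:
        raise ResourceBudgetError(
            f"~{expected:.2g} expected events exceed the budget "
            f"{config.event_budget:.2g}; consider simulate_tau_leap"
        )
    st = _sample_times(t_end, sample_times, n_samples)
    out = np.zeros((st.size, config.n_cells), dtype=np.int64)
    ssa_lattice(
        np.uint32(config.seed), config.n_cells, config.injection_rate,
        config.hop_rate, config.kd, st, out,
    )
    return SimResult(times=st, counts=out, seed=config.seed, config=config)


def simulate_ensemble(
    config: LatticeConfig,
    n_runs: int,
    t_end: float,
    *,
    sample_times: Sequence[float] | np.ndarray | None = None,
    n_samples: int = 201,
) -> list[SimResult]:
    """Independent SSA replicates with per-run seeds spawned from the config seed."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_runs)
    return [
        simulate_ssa(config.with_seed(int(s)), t_end,
                     sample_times=sample_times, n_samples=n_samples)
        for s in seeds
    ]


def simulate_tau_leap(
    config: LatticeConfig,
    t_end: float,
    dt: float,
    *,
    sample_times: Sequence[float] | np.ndarray | None = None,
    n_samples: int = 201,
) -> SimResult:
    """Poisson tau-leaping approximation of the lattice dynamics.

    Each step draws Poisson event counts for every channel at the current
    propensities.  A step that would drive any count negative is retried
    at a halved step size; after 10 halvings of a single step a
    :class:`NumericalError` is raised.  Converges to the SSA moments as
    ``dt -> 0``.
    """
    if t_end <= 0 or dt <= 0:
        raise InvalidParameterError("t_end and dt must be positive")
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    st = _sample_times(t_end, sample_times, n_samples)
    n = config.n_cells
    counts = np.zeros(n, dtype=np.int64)
    out = np.zeros((st.size, n), dtype=np.int64)
    t = 0.0
    si = 0
    while si < st.size:
        while si < st.size and st[si] <= t:
            out[si] = counts
            si += 1
        if si >= st.size:
            break
        # draw all channels; retry this one step at smaller dt on negativity
        step = dt
        halvings = 0
        while True:
            births = rng.poisson(config.injection_rate * step)
            deaths = rng.poisson(config.kd * counts * step)
            hop_r = rng.poisson(config.hop_rate * counts[:-1] * step)
            hop_l = rng.poisson(config.hop_rate * counts[1:] * step)
            new = counts.copy()
            new[0] += births
            new -= deaths
            new[:-1] += hop_l - hop_r
            new[1:] += hop_r - hop_l
            if np.all(new >= 0):
                counts = new
                t += step
                break
            halvings += 1
            if halvings > 10:
                raise NumericalError("tau-leap step halved 10 times; dt too large")
            step /= 2.0
    return SimResult(times=st, counts=out, seed=config.seed,
                     config=config, method="tau_leap")


def lattice_steady_state(config: LatticeConfig) -> np.ndarray:
    """Exact mean occupancy of the discrete lattice at stationarity.

    Closed form of the three-term recurrence: interior cells satisfy
    ``h(n_{i-1}+n_{i+1}) = (2h+kd) n_i``, solved by ``cosh(mu (m0 + N-1-i))``
    with ``cosh(mu) = 1 + kd/2h``; the reflecting and source boundaries fix
    ``m0`` and the amplitude.  This is the discrete analogue of the cosh
    steady-state profile and converges to it as ``lcell/lam -> 0``.
    """
    h, kd, inj, n = config.hop_rate, config.kd, config.injection_rate, config.n_cells
    mu = math.acosh(1.0 + kd / (2.0 * h))
    m0 = math.atanh(kd / (2.0 * h * math.sinh(mu))) / mu
    idx = np.arange(n)
    shape = np.cosh(mu * (m0 + (n - 1 - idx)))
    denom = (h + kd) * shape[0] - h * shape[1]
    return inj * shape / denom


def estimate_stationary_moments(
    runs: Sequence[SimResult],
    t_burnin: float,
    *,
    spacing: float | None = None,
) -> EnsembleStats:
    """Per-cell mean/variance/Fano across runs and decorrelated times.

    ``t_burnin`` must be at least five times the slowest accumulation time
    of the lattice; samples closer than ``spacing`` (default ``2/kd``) are
    thinned out before pooling.
    """
    if len(runs) == 0:
        raise EstimationError("empty run list")
    config = runs[0].config
    tau_max = accumulation_f(config.L, config.lam, config.L) / config.kd
    if t_burnin < 5.0 * tau_max:
        raise ValidityError(
            f"t_burnin={t_burnin} below 5*max accumulation time = {5 * tau_max:.3g}"
        )
    if spacing is None:
        spacing = 2.0 / config.kd
    pooled = []
    for run in runs:
        keep = run.times >= t_burnin
        times = run.times[keep]
        counts = run.counts[keep]
        if times.size == 0:
            continue
        sel = [0]
        for k in range(1, times.size):
            if times[k] - times[sel[-1]] >= spacing * (1 - 1e-12):
                sel.append(k)
        pooled.append(counts[sel])
    if not pooled:
        raise EstimationError("no samples past burn-in")
    data = np.concatenate(pooled, axis=0).astype(float)
    n = data.shape[0]
    if n < 2:
        raise EstimationError("need at least 2 post-burn-in samples")
    mean = data.mean(axis=0)
    var = data.var(axis=0, ddof=1)
    if np.any(mean <= 0):
        raise EstimationError("some cells recorded no molecules; extend sampling")
    fano = var / mean
    return EnsembleStats(
        n_runs=len(runs),
        n_samples=n,
        mean=mean,
        variance=var,
        fano=fano,
        se_mean=np.sqrt(var / n),
        se_fano=np.sqrt(2.0 / n) * np.ones_like(fano),
    )


def estimate_accumulation_time(
    runs: Sequence[SimResult],
    x: float,
    *,
    n_bootstrap: int = 200,
    bootstrap_seed: int = 7,
) -> tuple[float, float]:
    """Empirical accumulation time at ``x`` from zero-start trajectories.

    Integrates the ensemble-mean relaxation deficit
    ``R(x,t) = 1 - <count(t)> / count_ss`` by the trapezoid rule, with the
    exact discrete stationary mean as reference.  Returns
    ``(estimate, bootstrap standard error)`` (resampling whole runs).
    """
    if len(runs) == 0:
        raise EstimationError("empty run list")
    config = runs[0].config
    if np.any(runs[0].counts[0] != 0):
        raise ValidityError("runs must start from the all-zero state")
    t_end = runs[0].times[-1]
    if t_end < 10.0 / config.kd:
        raise ValidityError(f"t_end={t_end} below 10/kd; deficit tail too large")
    cell = int(x / config.lcell)
    if not (0 <= cell < config.n_cells):
        raise DomainError(f"x={x} outside the lattice")
    times = runs[0].times
    traj = np.stack([r.counts[:, cell] for r in runs]).astype(float)  # (runs, t)
    ss = lattice_steady_state(config)[cell]

    def integral(mat: np.ndarray) -> float:
        deficit = 1.0 - mat.mean(axis=0) / ss
        return float(np.trapezoid(deficit, times))

    est = integral(traj)
    rng = np.random.default_rng(bootstrap_seed)
    n = traj.shape[0]
    boots = np.array([
        integral(traj[rng.integers(0, n, n)]) for _ in range(n_bootstrap)
    ])
    return est, float(boots.std(ddof=1))


def window_average_counts(
    run: SimResult, x: float, a: float, T: float, t_start: float
) -> float:
    """One space-time-averaged count sample m_i(x) from a trajectory.

    Cells partially covered by ``(x-a, x+a)`` contribute with fractional
    weight equal to their overlap length; the time average runs over the
    recorded snapshots in ``[t_start, t_start+T]`` (piecewise-constant
    interpolation when the interval contains no snapshot).
    """
    config = run.config
    if T < 0:
        raise InvalidParameterError("T must be nonnegative")
    if x - a < 0 or x + a > config.L:
        raise DomainError("window extends outside the lattice")
    if t_start < 0 or t_start + T > run.times[-1] * (1 + 1e-12):
        raise DomainError("averaging interval outside the recorded trajectory")
    edges = np.arange(config.n_cells + 1) * config.lcell
    overlap = np.minimum(edges[1:], x + a) - np.maximum(edges[:-1], x - a)
    weights = np.clip(overlap, 0.0, None) / config.lcell
    series = run.counts @ weights
    inside = (run.times >= t_start) & (run.times <= t_start + T)
    if not np.any(inside):
        k = int(np.searchsorted(run.times, t_start, side="right")) - 1
        return float(series[max(k, 0)])
    return float(series[inside].mean())


# ---------------------------------------------------------------------------
# deterministic PDE oracle


@dataclass(frozen=True)
class PdeResult:
    """Deterministic method-of-lines trajectory (counts per sub-cell)."""

    times: np.ndarray
    x: np.ndarray
    counts: np.ndarray  # (n_times, n_grid)
    config: LatticeConfig
    n_sub: int


def pde_oracle(
    config: LatticeConfig,
    t_end: float,
    dt: float | None = None,
    *,
    n_sub: int = 1,
    source: np.ndarray | None = None,
) -> PdeResult:
    """Integrate the continuum SDD equation (method of lines).

    Conservative second-order finite volumes on each lattice cell split
    into ``n_sub`` sub-cells; the source is the injection flux into the
    first sub-cell (or an explicit per-sub-cell ``source`` array in
    molecules/time).  Time stepping is Crank-Nicolson (A-stable, second
    order), so ``dt`` is an accuracy knob, not a stability constraint; it
    must still resolve the kinetics (``dt <= 0.5/kd`` enforced).  The
    long-time limit reproduces the closed-form steady state.
    """
    if t_end <= 0:
        raise InvalidParameterError("t_end must be positive")
    if dt is None:
        dt = 0.01 / config.kd
    if dt > 0.5 / config.kd:
        raise ValidityError("dt must satisfy dt <= 0.5/kd to resolve the kinetics")
    n = config.n_cells * n_sub
    h = config.lcell / n_sub
    D = config.hop_rate * config.lcell**2
    w = D / h**2
    b = np.zeros(n)
    if source is None:
        b[0] = config.injection_rate
    else:
        src = np.asarray(source, dtype=float)
        if src.shape != (n,):
            raise InvalidParameterError(f"source must have shape ({n},)")
        b[:] = src
    # tridiagonal generator A: du/dt = A u + b
    main = -(2.0 * w + config.kd) * np.ones(n)
    main[0] = -(w + config.kd)
    main[-1] = -(w + config.kd)
    off = w * np.ones(n - 1)

    n_steps = max(3, int(math.ceil(t_end / dt)))
    dt = t_end / n_steps
    # Crank-Nicolson: (I - dt/2 A) u' = (I + dt/2 A) u + dt b
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * dt * off
    ab[1] = 1.0 - 0.5 * dt * main
    ab[2, :-1] = -0.5 * dt * off
    # Rannacher startup: two backward-Euler steps damp the stiff content of
    # the nonsmooth initial state that trapezoidal stepping barely decays
    ab_be = np.zeros((3, n))
    ab_be[0, 1:] = -dt * off
    ab_be[1] = 1.0 - dt * main
    ab_be[2, :-1] = -dt * off

    u = np.zeros(n)
    times = np.linspace(0.0, t_end, n_steps + 1)
    traj = np.zeros((n_steps + 1, n))
    prev_norm = 0.0
    for k in range(1, n_steps + 1):
        if k <= 2:
            u = solve_banded((1, 1), ab_be, u + dt * b)
        else:
            Au = main * u
            Au[:-1] += off * u[1:]
            Au[1:] += off * u[:-1]
            rhs = u + 0.5 * dt * Au + dt * b
            u = solve_banded((1, 1), ab, rhs)
        norm = float(np.abs(u).sum())
        if not math.isfinite(norm) or norm > 1e12 * (prev_norm + 1.0) + 1e15:
            raise NumericalError("PDE integration blew up")
        prev_norm = norm
        traj[k] = u
    xg = (np.arange(n) + 0.5) * h
    return PdeResult(times=times, x=xg, counts=traj, config=config, n_sub=n_sub)


def pde_accumulation_time(result: PdeResult, x: float) -> float:
    """Accumulation time by quadrature of the deterministic deficit.

    ``tau = int_0^T (1 - u(x,t)/u(x,T)) dt`` with the final profile as the
    stationary reference; ``T`` must be long enough that the residual decay
    is negligible (use ``t_end >~ 40/kd``).
    """
    # linear interpolation between the two bracketing sub-cell centres
    j = int(np.clip(np.searchsorted(result.x, x), 1, result.x.size - 1))
    w = (x - result.x[j - 1]) / (result.x[j] - result.x[j - 1])
    w = float(np.clip(w, 0.0, 1.0))
    series = (1.0 - w) * result.counts[:, j - 1] + w * result.counts[:, j]
    ss = series[-1]
    if ss <= 0:
        raise EstimationError("no steady-state mass at requested position")
    deficit = 1.0 - series / ss
    return float(np.trapezoid(deficit, result.times))


def _run_frame(run: SimResult):
    import pandas as pd

    nt, nc = run.counts.shape
    return pd.DataFrame({
        "time": np.repeat(run.times, nc),
        "cell": np.tile(np.arange(nc), nt),
        "count": run.counts.ravel(),
    })


def run_to_csv(run: SimResult, path: str | Path) -> None:
    """Export a trajectory in long form (time, cell, count) as CSV."""
    _run_frame(run).to_csv(path, index=False)


def run_to_parquet(run: SimResult, path: str | Path) -> None:
    """Columnar (Parquet) export of a trajectory, for large ensembles."""
    _run_frame(run).to_parquet(path, index=False)


def lattice_config_from_config(config) -> LatticeConfig:
    """Build a :class:`LatticeConfig` from a mapping or TOML/YAML path.

    Keys mirror the field names under an optional ``lattice`` table.
    """
    from .params import load_config

    if not hasattr(config, "get"):
        config = load_config(config)
    table = config.get("lattice", config)
    known = ("n_cells", "hop_rate", "kd", "injection_rate", "lcell", "seed",
             "event_budget")
    kwargs = {k: table[k] for k in known if k in table}
    kwargs["n_cells"] = int(kwargs.get("n_cells", 0))
    kwargs["seed"] = int(kwargs.get("seed", 0))
    return LatticeConfig(**kwargs)
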