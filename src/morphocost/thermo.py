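"""Reversible-kinetics lattice model and its entropy-production trade-off.

The irreversible SDD lattice treats synthesis and degradation as one-way
steps, so its thermodynamic cost has to be assigned per molecule.  Making
every elementary step bidirectional -- synthesis into cell 0 at rate ``ks``
with a first-order reverse ``ks_rev``, degradation ``kd`` per molecule with
a zeroth-order reverse ``kd_rev`` in every cell, and forward/backward hop
rates ``hop_f``/``hop_r`` -- yields a genuine nonequilibrium steady state
whose dissipation is well defined:

    S_dot_tot = sum_edges (J+ - J-) ln(J+ / J-)    [k_B / time],

nonnegative, and zero exactly at detailed balance.  Because the network
contains only zeroth- and first-order reactions, the stationary law is
product-form Poisson, the mean-field equations are linear, and both the
steady state and the relaxation time

    tau_rev(x) = int_0^inf R(x, t) dt = (-A^-1 n_ss)_x / n_ss(x)

follow from banded linear solves.  The three-way trade-off between
dissipation, speed and precision is scored by the product

    pi_o_rev(x) = S_dot_tot * tau_rev(x) * eps_rev^2(x),

whose lower bound (over the hop rate, the decay-length dial of this model)
is model-specific and position-dependent; it is computed numerically.

In the strict irreversible limit (``ks_rev = kd_rev = 0``) the entropy
production diverges; this is reported as a structured result, not an
exception, since the irreversible model is the main-text limit of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import minimize_scalar

from .errors import (
    DomainError,
    InvalidParameterError,
    NoSteadyStateError,
    NumericalError,
    SingularInputError,
)

__all__ = [
    "ReversibleRates",
    "ThermoResult",
    "EntropyReport",
    "generator_matrix",
    "steady_state_reversible",
    "entropy_production_rate",
    "relaxation_time_reversible",
    "positional_error_reversible",
    "tradeoff_reversible",
    "optimal_hop_reversible",
    "estimate_entropy_rate_ssa",
    "detailed_balance_rates",
    "reversible_rates_from_config",
]


def reversible_rates_from_config(config) -> "ReversibleRates":
    """Build :class:`ReversibleRates` from a mapping or TOML/YAML path.

    Keys mirror the field names, under an optional ``reversible`` table.
    """
    from .params import load_config

    if not hasattr(config, "get"):
        config = load_config(config)
    table = config.get("reversible", config)
    known = ("synth_fwd", "synth_rev", "deg_fwd", "deg_rev", "hop_fwd",
             "hop_rev", "n_cells", "lcell")
    kwargs = {k: table[k] for k in known if k in table}
    kwargs["n_cells"] = int(kwargs.get("n_cells", 0))
    return ReversibleRates(**kwargs)


@dataclass(frozen=True)
class ReversibleRates:
    """Forward/reverse rates of every elementary step of the lattice.

    Units: ``synth_fwd`` and ``deg_rev`` are zeroth order (molecules/time,
    the former acting only in cell 0, the latter in every cell); all other
    rates are first order (1/time per molecule).
    """

    synth_fwd: float
    synth_rev: float
    deg_fwd: float
    deg_rev: float
    hop_fwd: float
    hop_rev: float
    n_cells: int
    lcell: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise InvalidParameterError("need at least 3 cells")
        for name in ("synth_fwd", "synth_rev", "deg_fwd", "deg_rev",
                     "hop_fwd", "hop_rev"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be nonnegative, got {v!r}")
        if self.lcell <= 0:
            raise InvalidParameterError("lcell must be positive")

    @property
    def is_irreversible(self) -> bool:
        """True if any active forward step lacks its reverse (divergent S_dot)."""
        pairs = [
            (self.synth_fwd, self.synth_rev),
            (self.deg_fwd, self.deg_rev),
            (self.hop_fwd, self.hop_rev),
        ]
        return any((f > 0) != (r > 0) for f, r in pairs)

    @property
    def cell_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.lcell


def detailed_balance_rates(
    n_cells: int, *, synth_fwd: float = 5.0, deg_fwd: float = 1.0,
    hop: float = 2.0, occupancy: float = 5.0,
) -> ReversibleRates:
    """A parameterization satisfying detailed balance (flat profile).

    Equilibrium requires symmetric hops and a uniform occupancy ``n_eq``
    balancing both the synthesis (``ks = ks_rev n_eq``) and degradation
    (``kd n_eq = kd_rev``) edges.
    """
    return ReversibleRates(
        synth_fwd=synth_fwd,
        synth_rev=synth_fwd / occupancy,
        deg_fwd=deg_fwd,
        deg_rev=deg_fwd * occupancy,
        hop_fwd=hop,
        hop_rev=hop,
        n_cells=n_cells,
    )


def generator_matrix(rates: ReversibleRates) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field dynamics ``dn/dt = A n + b`` of the reversible lattice.

    ``A`` is returned dense (tridiagonal content) together with the
    constant production vector ``b``; both are exact for the mean of the
    linear master equation.
    """
    n = rates.n_cells
    A = np.zeros((n, n))
    idx = np.arange(n)
    diag = -(rates.deg_fwd * np.ones(n))
    diag[:-1] -= rates.hop_fwd
    diag[1:] -= rates.hop_rev
    diag[0] -= rates.synth_rev
    A[idx, idx] = diag
    A[idx[1:], idx[:-1]] = rates.hop_fwd
    A[idx[:-1], idx[1:]] = rates.hop_rev
    b = np.full(n, rates.deg_rev)
    b[0] += rates.synth_fwd
    return A, b


def _banded(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    ab = np.zeros((3, n))
    ab[0, 1:] = np.diag(A, 1)
    ab[1] = np.diag(A)
    ab[2, :-1] = np.diag(A, -1)
    return ab


def steady_state_reversible(rates: ReversibleRates) -> np.ndarray:
    """Stationary mean occupancy per cell (solves ``A n = -b``).

    Reduces to the irreversible lattice steady state when both reverse
    rates vanish; raises :class:`NoSteadyStateError` when nothing removes
    molecules from the system.
    """
    if rates.deg_fwd == 0 and rates.synth_rev == 0:
        raise NoSteadyStateError("no removal channel: occupancy grows without bound")
    A, b = generator_matrix(rates)
    try:
        n_ss = solve_banded((1, 1), _banded(A), -b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NoSteadyStateError(f"singular stationary system: {exc}") from exc
    if not np.all(np.isfinite(n_ss)) or np.any(n_ss < 0):
        raise NoSteadyStateError("stationary solve produced invalid occupancies")
    return n_ss


@dataclass(frozen=True)
class EntropyReport:
    """Entropy production rate with divergence bookkeeping (k_B/time)."""

    rate: float
    divergent: bool
    divergent_edges: tuple[str, ...] = ()


def entropy_production_rate(
    rates: ReversibleRates, steady_state: np.ndarray | None = None
) -> EntropyReport:
    """Total entropy production rate of the stationary state.

    Schnakenberg form ``sum (J+ - J-) ln(J+/J-)`` over the synthesis edge,
    the per-cell degradation edges and the hop edges, with one-way fluxes
    evaluated at the stationary means (exact for this linear network of
    independent particles).  Zero iff detailed balance holds; strictly
    irreversible edges are flagged as divergent instead of returning a
    silent infinity.
    """
    if steady_state is None:
        steady_state = steady_state_reversible(rates)
    n = steady_state
    edges: list[tuple[str, float, float]] = [
        ("synthesis", rates.synth_fwd, rates.synth_rev * n[0]),
    ]
    for i in range(rates.n_cells):
        edges.append((f"degradation[{i}]", rates.deg_fwd * n[i], rates.deg_rev))
    for i in range(rates.n_cells - 1):
        edges.append((f"hop[{i},{i + 1}]", rates.hop_fwd * n[i], rates.hop_rev * n[i + 1]))
    total = 0.0
    divergent: list[str] = []
    for name, jp, jm in edges:
        if jp == 0.0 and jm == 0.0:
            continue
        if jp == 0.0 or jm == 0.0:
            divergent.append(name)
            continue
        total += (jp - jm) * math.log(jp / jm)
    if divergent:
        return EntropyReport(rate=math.inf, divergent=True,
                             divergent_edges=tuple(divergent))
    return EntropyReport(rate=total, divergent=False)


def _cell_index(rates: ReversibleRates, x: float) -> int:
    i = int(x / rates.lcell)
    if not (0 <= i < rates.n_cells):
        raise DomainError(f"x={x} outside the lattice of extent {rates.n_cells * rates.lcell}")
    return i


def relaxation_time_reversible(
    rates: ReversibleRates, x: float, steady_state: np.ndarray | None = None
) -> float:
    """Accumulation-time analogue for the reversible lattice.

    For a zero initial condition the deficit evolves as ``e^{At} n_ss``, so
    its time integral is the resolvent solve ``-A^{-1} n_ss``; the local
    relaxation time is that integral divided by the local stationary mean.
    Reduces to ``f(x; lam)/kd`` in the irreversible continuum limit.
    """
    if steady_state is None:
        steady_state = steady_state_reversible(rates)
    A, _ = generator_matrix(rates)
    integral = solve_banded((1, 1), _banded(A), -steady_state)
    if not np.all(np.isfinite(integral)):
        raise NoSteadyStateError("non-decaying relaxation mode detected")
    i = _cell_index(rates, x)
    return float(integral[i] / steady_state[i])


def positional_error_reversible(
    rates: ReversibleRates, x: float, steady_state: np.ndarray | None = None
) -> float:
    """Squared relative positional error from the reversible steady state.

    Poisson stationary statistics (variance = mean, guaranteed by the
    zeroth/first-order network) with a central-difference profile slope:
    ``eps^2 = n(x) / (x dn/dx)^2``.
    """
    if steady_state is None:
        steady_state = steady_state_reversible(rates)
    i = _cell_index(rates, x)
    i = min(max(i, 1), rates.n_cells - 2)
    slope = (steady_state[i + 1] - steady_state[i - 1]) / (2.0 * rates.lcell)
    if slope == 0:
        raise SingularInputError("flat profile: positional error diverges")
    xc = rates.cell_centers[i]
    return float(steady_state[i] / (xc * slope) ** 2)


@dataclass(frozen=True)
class ThermoResult:
    """Three-way trade-off at a boundary: dissipation x speed x error."""

    xb: float
    entropy_rate: float  # k_B / time
    tau_rev: float
    epsilon_rev_sq: float
    product: float  # k_B units
    degenerate: bool = False  # equilibrium: no gradient, zero dissipation
    irreversible: bool = False  # divergent entropy production


def tradeoff_reversible(rates: ReversibleRates, xb: float) -> ThermoResult:
    """Assemble ``pi_o_rev(xb) = S_dot_tot * tau_rev * eps_rev^2``.

    At detailed balance the dissipation is zero and the profile is flat:
    the product is reported as 0 and flagged degenerate (the bound is
    attained trivially, but no positional information is transferred).  In
    the strictly irreversible limit the product is flagged divergent.
    """
    n_ss = steady_state_reversible(rates)
    report = entropy_production_rate(rates, n_ss)
    tau = relaxation_time_reversible(rates, xb, n_ss)
    if report.divergent:
        return ThermoResult(xb=xb, entropy_rate=math.inf, tau_rev=tau,
                            epsilon_rev_sq=math.nan, product=math.inf,
                            irreversible=True)
    if report.rate <= 1e-12 * max(rates.synth_fwd, rates.deg_rev, 1.0):
        return ThermoResult(xb=xb, entropy_rate=report.rate, tau_rev=tau,
                            epsilon_rev_sq=math.inf, product=0.0,
                            degenerate=True)
    eps2 = positional_error_reversible(rates, xb, n_ss)
    return ThermoResult(xb=xb, entropy_rate=report.rate, tau_rev=tau,
                        epsilon_rev_sq=eps2, product=report.rate * tau * eps2)


def optimal_hop_reversible(
    rates: ReversibleRates, xb: float, *, hop_bounds: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Symmetric hop rate minimizing the three-way product at ``xb``.

    The hop rate plays the role of the decay-length dial
    (``lam ~ sqrt(hop/kd)``); returns ``(hop_min, product_min)``.  The
    minimized product increases monotonically with the boundary position.
    """
    if hop_bounds is None:
        s = xb / rates.lcell
        hop_bounds = (max(rates.deg_fwd * (s / 20.0) ** 2, 1e-6),
                      rates.deg_fwd * (5.0 * s) ** 2)

    def objective(log_h: float) -> float:
        h = math.exp(log_h)
        r = ReversibleRates(
            synth_fwd=rates.synth_fwd, synth_rev=rates.synth_rev,
            deg_fwd=rates.deg_fwd, deg_rev=rates.deg_rev,
            hop_fwd=h, hop_rev=h, n_cells=rates.n_cells, lcell=rates.lcell,
        )
        return math.log(tradeoff_reversible(r, xb).product)

    res = minimize_scalar(
        objective, bounds=(math.log(hop_bounds[0]), math.log(hop_bounds[1])),
        method="bounded", options={"xatol": 1e-8},
    )
    if not res.success:
        raise NumericalError(f"hop-rate optimization failed at xb={xb}")
    return math.exp(res.x), math.exp(res.fun)


def estimate_entropy_rate_ssa(
    rates: ReversibleRates, t_burnin: float, t_end: float, seed: int
) -> float:
    """Empirical entropy production rate from one SSA path (k_B/time).

    Sums the log-ratio of forward to reverse propensities over every fired
    event after burn-in and divides by the elapsed time; converges to the
    Schnakenberg stationary rate.  Requires a fully reversible network.
    """
    if rates.is_irreversible or rates.synth_rev == 0 or rates.deg_rev == 0:
        raise InvalidParameterError("path entropy requires all reverse rates > 0")
    if t_end <= t_burnin:
        raise InvalidParameterError("t_end must exceed t_burnin")
    from ._kernels import ssa_reversible

    entropy, elapsed = ssa_reversible(
        np.uint32(seed), rates.n_cells, rates.synth_fwd, rates.synth_rev,
        rates.deg_fwd, rates.deg_rev, rates.hop_fwd, rates.hop_rev,
        t_burnin, np.array([t_end]), np.empty((1, rates.n_cells), dtype=np.int64),
    )
    return float(entropy / elapsed)


def sample_reversible_counts(
    rates: ReversibleRates, sample_times: np.ndarray, seed: int
) -> np.ndarray:
    """Snapshots of the reversible SSA (for Poisson/Fano validation)."""
    from ._kernels import ssa_reversible

    st = np.asarray(sample_times, dtype=float)
    out = np.empty((st.size, rates.n_cells), dtype=np.int64)
    ssa_reversible(
        np.uint32(seed), rates.n_cells, rates.synth_fwd, rates.synth_rev,
        rates.deg_fwd, rates.deg_rev, rates.hop_fwd, rates.hop_rev,
        0.0, st, out,
    )
    return out
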