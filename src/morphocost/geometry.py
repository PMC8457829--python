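"""Trade-off analysis beyond the localized-source 1D geometry.

Two generalizations of the SDD trade-off: a 1D system whose morphogen
source is spatially distributed (e.g. a boxcar of width ``w`` instead of a
boundary flux), and diffusion-depletion on the surface of a sphere with an
azimuthally symmetric polar source cap (the geometry of early fish-embryo
patterning).

The scoring generalizes the 1D definitions:

* the steady profile comes from the Green's function of
  ``D rho'' - kd rho + s(x) = 0`` (1D, zero-flux ends) or a conservative
  finite-volume solve of the Laplace-Beltrami operator (sphere);
* the cost is ``alpha_o x (total production rate) x tau(boundary)`` with the
  local relaxation time obtained as the time-integrated relaxation deficit
  (resolvent solve ``-A^{-1} rho_ss``, the exact time integral of the
  method-of-lines dynamics);
* the precision uses Poisson concentration noise in the local sensing
  volume (a cell of length ``lcell`` and volume ``vcell`` in 1D; a ring of
  arc width ``lcell`` on the sphere) divided by the squared profile slope
  and squared distance from the source edge.

With a point-like source these definitions reduce exactly to the 1D
point-measurement trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

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
from .params import CostParams, SddParams
from .pointmodel import ConcentrationProfile, TradeoffResult

__all__ = [
    "DistributedSourceSpec",
    "SphereSpec",
    "steady_state_distributed",
    "steady_state_sphere",
    "sphere_conservation_residual",
    "tradeoff_geometry",
]


@dataclass(frozen=True)
class DistributedSourceSpec:
    """1D SDD system with a distributed source.

    The default source is a boxcar of width ``width`` and amplitude
    ``amplitude`` (concentration/time) on ``[0, width]``; alternatively a
    tabulated profile ``(x_src, s_src)`` may be given and is interpolated
    linearly.  ``params.jin`` is ignored -- production is set here.
    """

    params: SddParams
    width: float | None = None
    amplitude: float | None = None
    x_src: np.ndarray | None = None
    s_src: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.x_src is not None:
            x = np.asarray(self.x_src, dtype=float)
            s = np.asarray(self.s_src, dtype=float)
            if x.ndim != 1 or s.shape != x.shape or x.size < 2:
                raise InvalidParameterError("tabulated source needs matching 1D arrays")
            if np.any(np.diff(x) <= 0) or x[0] < 0 or x[-1] > self.params.L:
                raise InvalidParameterError("source grid must increase within [0, L]")
            if np.any(s < 0) or np.trapezoid(s, x) <= 0:
                raise InvalidParameterError("source must be nonnegative with positive total")
            object.__setattr__(self, "x_src", x)
            object.__setattr__(self, "s_src", s)
        else:
            if self.width is None or self.amplitude is None:
                raise InvalidParameterError("provide width+amplitude or a tabulated source")
            if not (0 < self.width <= self.params.L):
                raise InvalidParameterError("boxcar width must lie in (0, L]")
            if self.amplitude <= 0:
                raise InvalidParameterError("amplitude must be positive")

    @property
    def source_edge(self) -> float:
        """Rightmost position with nonzero production."""
        if self.x_src is not None:
            nz = np.nonzero(self.s_src > 0)[0]
            return float(self.x_src[nz[-1]])
        return float(self.width)

    @property
    def total_production(self) -> float:
        """Integrated source strength, in jin units (conc x length / time)."""
        if self.x_src is not None:
            return float(np.trapezoid(self.s_src, self.x_src))
        return self.amplitude * self.width

    def source_on(self, x: np.ndarray) -> np.ndarray:
        if self.x_src is not None:
            return np.interp(x, self.x_src, self.s_src, left=0.0, right=0.0)
        return np.where(x <= self.width, self.amplitude, 0.0)

    def source_cell_average(self, edges: np.ndarray) -> np.ndarray:
        """Mean source density per grid cell (exact for the boxcar).

        Point sampling would miss a boxcar narrower than a grid cell; the
        overlap integral keeps the total production exact at any width.
        """
        if self.x_src is None:
            overlap = np.clip(
                np.minimum(edges[1:], self.width) - edges[:-1], 0.0, None
            )
            return self.amplitude * overlap / np.diff(edges)
        fine = np.linspace(edges[0], edges[-1], 20 * (edges.size - 1) + 1)
        vals = self.source_on(fine)
        cells = np.searchsorted(edges, fine[:-1], side="right") - 1
        dx = np.diff(fine)
        mids = 0.5 * (vals[:-1] + vals[1:])
        totals = np.bincount(cells, weights=mids * dx, minlength=edges.size - 1)
        return totals / np.diff(edges)


def steady_state_distributed(
    spec: DistributedSourceSpec, x: np.ndarray | None = None
) -> ConcentrationProfile:
    """Steady state of ``D rho'' - kd rho + s(x) = 0`` with zero-flux ends.

    Superposition of the zero-flux Green's function
    ``G(x, x') = lam cosh(x_</lam) cosh((L - x_>)/lam) / (D sinh(L/lam))``;
    the boxcar case is integrated in closed form, tabulated sources by
    high-resolution trapezoid quadrature.  A boxcar shrunk onto the
    boundary at fixed total production recovers the localized-source cosh
    profile.
    """
    p = spec.params
    lam, L, D = p.lam, p.L, p.D
    if x is None:
        x = np.linspace(0.0, L, 401)
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > L):
        raise DomainError("evaluation grid outside [0, L]")
    A = L / lam
    if spec.x_src is None:
        w, s0 = spec.width, spec.amplitude
        pref = s0 * lam**2 / (D * math.sinh(A))
        below = xa < w
        rho = np.empty_like(xa)
        # x >= w: all source lies to the left
        xa_hi = xa[~below]
        rho[~below] = pref * math.sinh(w / lam) * np.cosh((L - xa_hi) / lam)
        # x < w: split the source integral at x
        xa_lo = xa[below]
        rho[below] = pref * (
            np.cosh((L - xa_lo) / lam) * np.sinh(xa_lo / lam)
            + np.cosh(xa_lo / lam)
            * (np.sinh((L - xa_lo) / lam) - math.sinh((L - w) / lam))
        )
    else:
        xq = np.linspace(spec.x_src[0], spec.x_src[-1], 4001)
        sq = spec.source_on(xq)
        lo = np.minimum.outer(xa, xq)
        hi = np.maximum.outer(xa, xq)
        G = lam / (D * math.sinh(A)) * np.cosh(lo / lam) * np.cosh((L - hi) / lam)
        rho = np.trapezoid(G * sq[None, :], xq, axis=1)
        if not np.all(np.isfinite(rho)):
            raise NumericalError("source quadrature did not converge")
    return ConcentrationProfile(x=xa, rho=rho, is_steady=True)


@dataclass(frozen=True)
class SphereSpec:
    """Diffusion-depletion on a spherical surface with a polar source cap.

    Morphogen is produced at ``source_rate`` (concentration/time) inside
    the polar cap ``theta < theta0``, diffuses on the sphere of radius
    ``R`` and is depleted at ``kd``.  ``lcell``/``thickness`` define the
    local sensing volume (a ring of arc width lcell) used for the Poisson
    precision; ``n_theta`` is the polar finite-volume resolution.
    """

    R: float
    theta0: float
    D: float
    kd: float
    source_rate: float
    n_theta: int = 400
    lcell: float = 1.0
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.theta0 < math.pi):
            raise InvalidParameterError("theta0 must lie in (0, pi)")
        if self.n_theta < 50:
            raise InvalidParameterError("n_theta too coarse (need >= 50)")
        for name in ("R", "D", "source_rate", "lcell", "thickness"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.kd < 0:
            raise InvalidParameterError("kd must be nonnegative")

    @property
    def theta_grid(self) -> np.ndarray:
        d = math.pi / self.n_theta
        return (np.arange(self.n_theta) + 0.5) * d

    @property
    def lam(self) -> float:
        return math.sqrt(self.D / self.kd) if self.kd > 0 else math.inf


def _sphere_operator(spec: SphereSpec) -> tuple[np.ndarray, np.ndarray]:
    """Banded Laplace-Beltrami + depletion operator and source vector."""
    n = spec.n_theta
    d = math.pi / n
    theta = spec.theta_grid
    sin_c = np.sin(theta)
    sin_f = np.sin(theta - 0.5 * d)  # lower faces; sin(0)=sin(pi)=0 at poles
    sin_fu = np.sin(theta + 0.5 * d)
    w = spec.D / (spec.R**2 * d**2)
    lower = w * sin_f[1:] / sin_c[1:]
    upper = w * sin_fu[:-1] / sin_c[:-1]
    diag = -(spec.kd + w * (sin_f + sin_fu) / sin_c)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1] = diag
    ab[2, :-1] = lower
    src = np.where(theta < spec.theta0, spec.source_rate, 0.0)
    return ab, src


def steady_state_sphere(spec: SphereSpec) -> ConcentrationProfile:
    """Steady concentration over the polar angle.

    Conservative second-order finite volumes with natural pole regularity
    (the metric factor ``sin(theta)`` annihilates the polar fluxes); the
    profile coordinate returned is ``theta``.  Without depletion there is
    no steady state for net production.
    """
    ab, src = _sphere_operator(spec)
    if spec.kd == 0:
        raise NoSteadyStateError("kd = 0 with net production: no steady state")
    rho = solve_banded((1, 1), ab, -src)
    if not np.all(np.isfinite(rho)) or np.any(rho < -1e-12 * np.abs(rho).max()):
        raise NumericalError("sphere solve produced non-finite or negative values")
    return ConcentrationProfile(x=spec.theta_grid, rho=np.maximum(rho, 0.0),
                                is_steady=True)


def sphere_conservation_residual(spec: SphereSpec) -> float:
    """Relative imbalance between total degradation and total production."""
    profile = steady_state_sphere(spec)
    theta = spec.theta_grid
    sin_w = np.sin(theta)
    ab, src = _sphere_operator(spec)
    produced = float((src * sin_w).sum())
    degraded = float((spec.kd * profile.rho * sin_w).sum())
    return abs(degraded - produced) / produced


# ---------------------------------------------------------------------------
# generalized trade-off


def _tradeoff_from_operator(
    ab: np.ndarray,
    src: np.ndarray,
    rho: np.ndarray,
    coord: np.ndarray,
    boundary: float,
    x_of_coord: Callable[[float], float],
    production_rate: float,
    sensing_volume: Callable[[int], float],
    slope_scale: float,
    cost: CostParams,
) -> tuple[float, float, float]:
    """(cost, eps^2, tau) at the boundary for a discrete operator.

    ``ab`` is the banded generator acting on concentrations, ``src`` the
    source vector, ``slope_scale`` converts a per-coordinate derivative to
    a per-arc-length derivative.
    """
    i = int(np.searchsorted(coord, boundary))
    i = min(max(i, 1), coord.size - 2)
    integral = solve_banded((1, 1), ab, -rho)
    tau = float(integral[i] / rho[i])
    slope = (rho[i + 1] - rho[i - 1]) / (coord[i + 1] - coord[i - 1]) * slope_scale
    if slope >= 0:
        raise SingularInputError("profile slope must be strictly negative at boundary")
    x_eff = x_of_coord(float(coord[i]))
    var = rho[i] / sensing_volume(i)
    eps2 = var / (slope * x_eff) ** 2
    c = cost.alpha_o * production_rate * tau
    return c, eps2, tau


def _tradeoff_distributed(
    spec: DistributedSourceSpec, cost: CostParams, xb: float, n_grid: int = 2000
) -> tuple[float, float]:
    p = spec.params
    h = p.L / n_grid
    xg = (np.arange(n_grid) + 0.5) * h
    w = p.D / h**2
    diag = -(p.kd + 2.0 * w) * np.ones(n_grid)
    diag[0] += w
    diag[-1] += w
    ab = np.zeros((3, n_grid))
    ab[0, 1:] = w
    ab[1] = diag
    ab[2, :-1] = w
    src = spec.source_cell_average(np.arange(n_grid + 1) * h)
    rho = solve_banded((1, 1), ab, -src)
    production = spec.total_production * p.vcell / p.lcell  # molecules/time
    c, eps2, _ = _tradeoff_from_operator(
        ab, src, rho, xg, xb,
        x_of_coord=lambda x: x,
        production_rate=production,
        sensing_volume=lambda i: p.vcell,
        slope_scale=1.0,
        cost=cost,
    )
    return c, eps2


def _tradeoff_sphere(
    spec: SphereSpec, cost: CostParams, theta_b: float
) -> tuple[float, float]:
    ab, src = _sphere_operator(spec)
    rho = solve_banded((1, 1), ab, -src)
    theta = spec.theta_grid
    d = math.pi / spec.n_theta
    sin_w = np.sin(theta)
    # production in molecules/time over the whole cap
    production = float(
        (src * sin_w).sum() * d * 2.0 * math.pi * spec.R**2 * spec.thickness
    )

    def ring_volume(i: int) -> float:
        return 2.0 * math.pi * spec.R * math.sin(theta[i]) * spec.lcell * spec.thickness

    c, eps2, _ = _tradeoff_from_operator(
        ab, src, rho, theta, theta_b,
        x_of_coord=lambda t: spec.R * (t - spec.theta0),
        production_rate=production,
        sensing_volume=ring_volume,
        slope_scale=1.0 / spec.R,
        cost=cost,
    )
    return c, eps2


def tradeoff_geometry(
    spec: DistributedSourceSpec | SphereSpec,
    cost: CostParams,
    boundary: float,
    *,
    optimize: bool = True,
    n_grid: int = 2000,
) -> TradeoffResult:
    """Cost-precision trade-off at a boundary coordinate, any geometry.

    ``boundary`` is a position ``xb`` for the distributed-source system or
    a polar angle ``theta_b`` for the sphere (distance is measured as arc
    length from the cap edge).  When ``optimize`` is set, the decay length
    ``lam = sqrt(D/kd)`` is additionally minimized over ``D`` at fixed
    geometry, filling ``lambda_min``/``product_min``.
    """
    if isinstance(spec, DistributedSourceSpec):
        p = spec.params
        if not (0 < boundary < p.L):
            raise DomainError("boundary must lie inside (0, L)")
        lam0, extent, lcell = p.lam, p.L, p.lcell

        def evaluate(D: float) -> tuple[float, float]:
            sp = DistributedSourceSpec(
                params=p.with_(D=D), width=spec.width, amplitude=spec.amplitude,
                x_src=spec.x_src, s_src=spec.s_src,
            )
            return _tradeoff_distributed(sp, cost, boundary, n_grid=n_grid)

        kd = p.kd
    elif isinstance(spec, SphereSpec):
        if not (spec.theta0 < boundary < math.pi):
            raise DomainError("theta_b must lie between the cap edge and the far pole")
        lam0 = spec.lam
        extent, lcell = spec.R * (math.pi - spec.theta0), spec.lcell

        def evaluate(D: float) -> tuple[float, float]:
            sp = SphereSpec(
                R=spec.R, theta0=spec.theta0, D=D, kd=spec.kd,
                source_rate=spec.source_rate, n_theta=spec.n_theta,
                lcell=spec.lcell, thickness=spec.thickness,
            )
            return _tradeoff_sphere(sp, cost, boundary)

        kd = spec.kd
    else:
        raise InvalidParameterError("spec must be DistributedSourceSpec or SphereSpec")

    c, eps2 = evaluate(lam0**2 * kd)
    product = c * eps2
    lam_min, product_min = lam0, product
    if optimize:
        # the decay-length scale is set by the distance from the source edge
        if isinstance(spec, DistributedSourceSpec):
            x_eff = boundary - spec.source_edge
            if x_eff <= 0:
                x_eff = boundary
        else:
            x_eff = spec.R * (boundary - spec.theta0)
        lo, hi = math.log(x_eff / 20.0), math.log(4.0 * x_eff)

        def objective(t: float) -> float:
            lam = math.exp(t)
            cc, ee = evaluate(lam * lam * kd)
            return math.log(cc * ee)

        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        if not res.success:
            raise NumericalError("decay-length optimization failed")
        lam_min, product_min = math.exp(res.x), math.exp(res.fun)
    return TradeoffResult(
        xb=float(boundary), lam=lam0, cost=c, precision_sq=eps2,
        product=product, product_normalized=product / (cost.alpha_o * extent / lcell),
        lambda_min=lam_min, product_min=product_min,
    )
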