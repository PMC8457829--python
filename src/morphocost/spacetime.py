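"""Space-time-averaged measurement of a semi-infinite exponential gradient.

Instead of reading the concentration at a point, a cell at ``x`` integrates
the molecular count over a window ``(x - a, x + a)`` for a duration ``T``:

    m(x) = (1/T) int_0^T dt int_{x-a}^{x+a} rho(y, t) dy.

For the steady-state SDD gradient on a half line this has mean
``<m> = 2 (jin/kd) e^{-x/lam} sinh(a/lam)`` and, for ``T >> 1/kd``, a
variance proportional to ``1/T``.  The squared relative positional error is

    eps_T^2(x) = (lam/x)^2 e^{x/lam} / (jin T) * g(a/lam),

with the sensor factor ``g(u) = (e^{-u} + 3 e^{3u} - 4(1+u) e^{u}) /
(2 (e^{2u} - 1)^2)``, which tends to 1 as the sensor shrinks.  The cost of
maintaining the profile for the measurement is simply ``alpha_o jin T``
(all molecules produced during T), so the trade-off product
``pi_T = C_T * eps_T^2`` is again production-independent and is minimized
at ``lam_min(x_b)`` in ``[(x_b - a)/2, x_b/2]`` -- for a small sensor,
``lam_min -> x_b / 2`` exactly.

``jin`` here is in molecules/time and the domain is semi-infinite; finite-L
corrections are deliberately not invented (use the point model for small
systems).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DomainError, InvalidParameterError, NumericalError, SingularInputError, ValidityError
from .params import CostParams, SensorSpec, SpacetimeParams
from .pointmodel import TradeoffResult

__all__ = [
    "sensor_factor",
    "mean_window_count",
    "window_count_variance",
    "precision_spacetime",
    "cost_spacetime",
    "tradeoff_spacetime",
    "optimal_lambda_spacetime",
    "min_production_for_error",
    "ProductionRequirement",
]

#: below this measurement duration (in units of 1/kd) the long-time variance
#: formula is refused outright; below _T_WARN it is used with a warning.
_T_FLOOR = 10.0
_T_WARN = 50.0


def sensor_factor(u: float | np.ndarray) -> float | np.ndarray:
    """Sensor factor g(u), u = a/lam, of the space-time-averaged error.

    Monotone decreasing from ``g(0) = 1``; for ``u < 1e-3`` a series
    expansion ``1 - 2u/3 + u^2/6`` avoids the 8u^2/8u^2 cancellation.
    """
    ua = np.asarray(u, dtype=float)
    if np.any(ua < 0):
        raise InvalidParameterError("a/lam must be nonnegative")
    small = ua < 1e-3
    out = np.empty_like(ua)
    us = ua[small]
    out[small] = 1.0 - (2.0 / 3.0) * us + us * us / 6.0
    ub = ua[~small]
    num = np.exp(-ub) + 3.0 * np.exp(3.0 * ub) - 4.0 * (1.0 + ub) * np.exp(ub)
    den = 2.0 * np.expm1(2.0 * ub) ** 2
    out[~small] = num / den
    return float(out) if np.isscalar(u) or ua.ndim == 0 else out


def _check_window(p: SpacetimeParams, s: SensorSpec, x: float) -> None:
    if x < s.a:
        raise DomainError(f"window (x-a, x+a) must lie in x >= 0: x={x}, a={s.a}")


def _check_duration(p: SpacetimeParams, s: SensorSpec) -> None:
    tk = s.T * p.kd
    if tk < _T_FLOOR:
        raise ValidityError(
            f"T = {tk:.3g}/kd is below the long-time validity floor "
            f"({_T_FLOOR}/kd) of the variance formula"
        )
    if tk < _T_WARN:
        warnings.warn(
            f"T = {tk:.3g}/kd: long-time variance formula may be inaccurate "
            f"below {_T_WARN}/kd",
            stacklevel=3,
        )


def mean_window_count(p: SpacetimeParams, s: SensorSpec, x: float) -> float:
    """Mean space-time-averaged molecular count in the sensor window.

    ``<m(x)> = 2 (jin/kd) e^{-x/lam} sinh(a/lam)``; dividing by the window
    size 2a recovers the point concentration as ``a -> 0``.
    """
    _check_window(p, s, x)
    return 2.0 * (p.jin / p.kd) * math.exp(-x / p.lam) * math.sinh(s.a / p.lam)


def window_count_variance(p: SpacetimeParams, s: SensorSpec, x: float) -> float:
    """Variance of the window-averaged count for a long measurement.

    Equals ``<m>^2 (x/lam)^2 eps_T^2``, i.e.
    ``4 jin e^{-x/lam} sinh^2(a/lam) g(a/lam) / (T kd^2)``; strictly
    positive and proportional to ``1/T``.
    """
    _check_window(p, s, x)
    _check_duration(p, s)
    u = s.a / p.lam
    return (
        4.0 * p.jin * math.exp(-x / p.lam) * math.sinh(u) ** 2
        * float(sensor_factor(u)) / (s.T * p.kd**2)
    )


def precision_spacetime(p: SpacetimeParams, s: SensorSpec, x: float) -> float:
    """Squared relative positional error eps_T^2(x) of the averaged readout."""
    if x <= 0:
        raise SingularInputError("eps_T^2 diverges as x -> 0")
    _check_window(p, s, x)
    _check_duration(p, s)
    u = s.a / p.lam
    return (p.lam / x) ** 2 * math.exp(x / p.lam) / (p.jin * s.T) * float(sensor_factor(u))


def cost_spacetime(p: SpacetimeParams, s: SensorSpec, cost: CostParams) -> float:
    """Cost of maintaining the profile for the measurement: alpha_o jin T."""
    return cost.alpha_o * p.jin * s.T


def _log_product_spacetime(xb: float, lam: float, a: float) -> float:
    """log of pi_T / alpha_o = log[(lam/xb)^2 e^{xb/lam} g(a/lam)]."""
    return (
        2.0 * (math.log(lam) - math.log(xb))
        + xb / lam
        + math.log(float(sensor_factor(a / lam)))
    )


def tradeoff_spacetime(
    p: SpacetimeParams, s: SensorSpec, cost: CostParams, xb: float
) -> TradeoffResult:
    """Assemble the space-time trade-off at boundary ``xb``.

    ``product`` is in alpha_o units; ``product_normalized`` divides by
    alpha_o (the natural scale here -- no system size exists).
    """
    c = cost_spacetime(p, s, cost)
    e2 = precision_spacetime(p, s, xb)
    product = c * e2
    lam_min, prod_min = optimal_lambda_spacetime(xb, s.a)
    return TradeoffResult(
        xb=float(xb),
        lam=p.lam,
        cost=c,
        precision_sq=e2,
        product=product,
        product_normalized=product / cost.alpha_o,
        lambda_min=lam_min,
        product_min=prod_min * cost.alpha_o,
    )


def optimal_lambda_spacetime(xb: float, a: float) -> tuple[float, float]:
    """Decay length minimizing pi_T at ``xb`` for sensor half-width ``a``.

    Returns ``(lambda_min, product_min/alpha_o)``; the optimum lies in
    ``[(xb - a)/2, xb/2]`` and approaches ``xb/2`` as ``a -> 0``.
    """
    if not (0 < a < xb):
        raise DomainError(f"need 0 < a < xb, got a={a}, xb={xb}")
    # optimize the dimensionless ratio s = lam/xb: the product depends only
    # on (s, a/xb), which makes the result exactly unit-system invariant
    rel = a / xb
    res = minimize_scalar(
        lambda t: _log_product_spacetime(1.0, math.exp(t), rel),
        bounds=(math.log(0.02), math.log(10.0)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise NumericalError(f"lambda optimization failed at xb={xb}: {res.message}")
    return xb * math.exp(res.x), math.exp(res.fun)


@dataclass(frozen=True)
class ProductionRequirement:
    """Molecules needed to reach a target error (real value and ceiling)."""

    jin_T: float
    jin_T_ceil: int
    lam: float
    xb: float
    a: float
    epsilon_target: float


def min_production_for_error(
    xb: float, a: float, epsilon_target: float, lam: float | None = None
) -> ProductionRequirement:
    """Minimum total production jin*T achieving a target positional error.

    Solves ``eps_T(xb) = epsilon_target`` for ``jin T`` at the given decay
    length (default: the optimal ``lam_min(xb)``); since
    ``eps_T^2 ~ 1/(jin T)``, the requirement is ``pi_T/(alpha_o eps^2)``.
    The count is reported both as the real solution and its integer ceiling
    (molecules come in whole numbers).
    """
    if epsilon_target <= 0:
        raise InvalidParameterError("epsilon_target must be positive")
    if lam is None:
        lam, _ = optimal_lambda_spacetime(xb, a)
    jin_T = math.exp(_log_product_spacetime(xb, lam, a)) / epsilon_target**2
    return ProductionRequirement(
        jin_T=jin_T,
        jin_T_ceil=math.ceil(jin_T),
        lam=lam,
        xb=xb,
        a=a,
        epsilon_target=epsilon_target,
    )
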