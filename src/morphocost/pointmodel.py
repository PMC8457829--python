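"""Point-measurement cost-precision trade-off for the SDD model.

A morphogen is injected at ``x = 0`` with flux ``jin``, diffuses with
diffusivity ``D`` and is depleted at rate ``kd`` on ``0 <= x <= L`` with a
reflecting far boundary.  The steady state is

    rho_ss(x) = (jin / sqrt(D kd)) * cosh((L - x)/lam) / sinh(L/lam),

with decay length ``lam = sqrt(D/kd)``; for ``L >> lam`` this is a plain
exponential.  The *point measurement* scenario scores this profile by

* cost       ``C(x)   = alpha_o * nm * f(x; lam)``  -- molecules produced
  while the profile builds up to steady state at ``x`` (f is the local
  accumulation time in units of ``1/kd``), and
* precision  ``eps^2(x)`` -- the squared relative positional error of a
  single instantaneous concentration readout, assuming Poisson copy-number
  statistics.

Their product ``pi_o = C * eps^2`` is independent of the production
amplitude ``nm`` and, at a fixed target boundary ``x_b``, is minimized by an
optimal decay length ``lam_min(x_b) ~= 0.43 x_b`` (exactly
``2 x_b / (1 + sqrt(13))`` for ``L >> lam``).

All hyperbolic combinations are evaluated in factored-exponential form so
the expressions stay finite for arbitrarily large ``L/lam``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    DomainError,
    InvalidParameterError,
    NumericalError,
    SingularInputError,
)
from .params import CostParams, SddParams

__all__ = [
    "ConcentrationProfile",
    "TradeoffResult",
    "steady_state_profile",
    "accumulation_time",
    "accumulation_f",
    "cost_point",
    "positional_error_point",
    "positional_variance",
    "normalized_product_point",
    "log_normalized_product_point",
    "tradeoff_point",
    "optimal_lambda_point",
    "threshold_fraction",
    "results_to_json",
    "results_to_csv",
]

# Closed-form optimum of the large-L product: stationarity of
# (1 + s) s^-3 e^s in s = x/lam gives s^2 - s - 3 = 0.
LARGE_L_OPTIMAL_RATIO = 2.0 / (1.0 + math.sqrt(13.0))


@dataclass(frozen=True)
class ConcentrationProfile:
    """A concentration profile sampled on an ordered grid."""

    x: np.ndarray
    rho: np.ndarray
    is_steady: bool = True

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "rho", rho)
        if x.ndim != 1 or rho.shape != x.shape:
            raise InvalidParameterError("x and rho must be matching 1D arrays")
        if x.size > 1 and not np.all(np.diff(x) > 0):
            raise InvalidParameterError("grid must be strictly increasing")
        if np.any(rho < 0):
            raise InvalidParameterError("concentrations must be nonnegative")


@dataclass(frozen=True)
class TradeoffResult:
    """Cost, precision and their product at a target boundary.

    ``product`` is in units of ``alpha_o`` and ``product_normalized``
    divides by ``alpha_o * L / lcell`` (the natural scale of the point
    model); ``lambda_min``/``product_min`` describe the optimum over the
    decay length at the same boundary.
    """

    xb: float
    lam: float
    cost: float
    precision_sq: float
    product: float
    product_normalized: float
    lambda_min: float
    product_min: float

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_params(params: SddParams) -> None:
    if not isinstance(params, SddParams):
        raise InvalidParameterError("params must be an SddParams instance")


def _check_domain(x: np.ndarray, L: float) -> None:
    if np.any(~np.isfinite(x)):
        raise InvalidParameterError("positions must be finite")
    if np.any(x < 0) or np.any(x > L):
        raise DomainError(f"position outside [0, {L}]")


def steady_state_profile(params: SddParams, x: Sequence[float] | np.ndarray) -> ConcentrationProfile:
    """Steady-state concentration of the SDD model on a grid.

    Evaluates ``(jin/sqrt(D kd)) cosh((L-x)/lam)/sinh(L/lam)`` in a form
    that does not overflow for large ``L/lam``, where it reduces to
    ``(jin/sqrt(D kd)) exp(-x/lam)``.
    """
    _validate_params(params)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(xa, params.L)
    lam, L = params.lam, params.L
    amp = params.jin / math.sqrt(params.D * params.kd)
    # cosh((L-x)/lam)/sinh(L/lam) = e^{-x/lam} (1+e^{-2(L-x)/lam})/(1-e^{-2L/lam})
    rho = amp * np.exp(-xa / lam) * (1.0 + np.exp(-2.0 * (L - xa) / lam)) \
        / (-np.expm1(-2.0 * L / lam))
    return ConcentrationProfile(x=xa, rho=rho, is_steady=True)


def accumulation_f(x, lam: float, L: float):
    """Dimensionless accumulation-time factor f(x; lam).

    ``f = 1/2 [1 + (L/lam) coth(L/lam) - ((L-x)/lam) tanh((L-x)/lam)]``;
    the local accumulation time is ``f / kd``.
    """
    xa = np.asarray(x, dtype=float)
    A = L / lam
    B = (L - xa) / lam
    return 0.5 * (1.0 + A / np.tanh(A) - B * np.tanh(B))


def accumulation_time(params: SddParams, x) -> float | np.ndarray:
    """Mean local accumulation time tau(x) = f(x; lam) / kd.

    This is the time integral of the relaxation deficit
    ``R(x,t) = (rho_ss - rho(x,t)) / rho_ss`` for a zero initial condition.
    """
    _validate_params(params)
    xa = np.asarray(x, dtype=float)
    _check_domain(np.atleast_1d(xa), params.L)
    out = accumulation_f(xa, params.lam, params.L) / params.kd
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def cost_point(params: SddParams, cost: CostParams, x) -> float | np.ndarray:
    """Thermodynamic cost C(x) = alpha_o * nm * f(x; lam).

    The number of molecules produced over one accumulation time, scaled by
    the per-molecule cost; grows like ``alpha_o nm (1 + x/lam)/2`` when
    ``L >> lam``.
    """
    _validate_params(params)
    tau = accumulation_time(params, x)
    return cost.alpha_o * params.nm * params.kd * tau


def _log_sinh_cosh_ratio(x, lam: float, L: float):
    """log of S = sinh(L/lam) cosh((L-x)/lam) / sinh((L-x)/lam)^2, stably."""
    xa = np.asarray(x, dtype=float)
    A = L / lam
    B = (L - xa) / lam
    # S = e^{x/lam} (1 - e^{-2A})(1 + e^{-2B}) / (1 - e^{-2B})^2
    return (
        xa / lam
        + np.log1p(-np.exp(-2.0 * A))
        + np.log1p(np.exp(-2.0 * B))
        - 2.0 * np.log(-np.expm1(-2.0 * B))
    )


def positional_error_point(params: SddParams, x) -> float | np.ndarray:
    """Squared relative positional error eps^2(x) of a point measurement.

    ``eps^2 = (lam^3 / (x^2 lcell)) nm^-1 sinh(L/lam) cosh((L-x)/lam)
    / sinh((L-x)/lam)^2``, diverging at both ``x = 0`` (relative error of a
    vanishing coordinate) and ``x = L`` (flat profile, zero slope).
    """
    _validate_params(params)
    xa = np.asarray(x, dtype=float)
    _check_domain(np.atleast_1d(xa), params.L)
    if np.any(xa == 0.0) or np.any(xa == params.L):
        raise SingularInputError("eps^2 diverges at x=0 and x=L")
    logS = _log_sinh_cosh_ratio(xa, params.lam, params.L)
    out = (params.lam**3 / (xa**2 * params.lcell)) / params.nm * np.exp(logS)
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def positional_variance(profile_slope: float, conc_variance: float) -> float:
    """Squared positional error from concentration noise and profile slope.

    ``sigma_x^2 = sigma_rho^2 / (d rho/dx)^2`` -- steep profiles and quiet
    concentrations localize a threshold crossing precisely.
    """
    if conc_variance < 0:
        raise InvalidParameterError("variance must be nonnegative")
    if profile_slope == 0:
        raise SingularInputError("zero profile slope: positional error diverges")
    return conc_variance / profile_slope**2


def log_normalized_product_point(xb: float, lam: float, L: float) -> float:
    """log of pi_o / (alpha_o L / lcell); depends only on xb/L and lam/L."""
    f = accumulation_f(xb, lam, L)
    return float(
        math.log(f) + 3.0 * math.log(lam) - 2.0 * math.log(xb) - math.log(L)
        + _log_sinh_cosh_ratio(xb, lam, L)
    )


def normalized_product_point(xb: float, lam: float, L: float) -> float:
    """Trade-off product pi_o(xb; lam) normalized by alpha_o * L / lcell.

    Amplitude-free: neither ``jin``, ``vcell`` nor ``lcell`` appears.
    """
    if not (0 < xb < L):
        raise DomainError("boundary position must satisfy 0 < xb < L")
    if not (lam > 0 and math.isfinite(lam)):
        raise InvalidParameterError(f"lam must be positive, got {lam!r}")
    return math.exp(log_normalized_product_point(xb, lam, L))


def optimal_lambda_point(xb: float, L: float) -> tuple[float, float]:
    """Decay length minimizing the point-model trade-off product at ``xb``.

    Returns ``(lambda_min, product_min)`` where ``product_min`` is the
    normalized product at the optimum.  Minimization is Brent's method on
    ``log lam`` over ``[xb/50, 10 xb]`` (the product is unimodal in lam).
    """
    if not (0 < xb < L):
        raise DomainError("boundary position must satisfy 0 < xb < L")
    # optimize the dimensionless ratio s = lam/xb at fixed xb/L: the
    # normalized product depends only on (s, xb/L), so the result is
    # exactly unit-system invariant
    xrel = xb / L
    lo, hi = math.log(1.0 / 50.0), math.log(10.0)
    res = minimize_scalar(
        lambda t: log_normalized_product_point(xrel, math.exp(t) * xrel, 1.0),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise NumericalError(f"lambda optimization failed at xb={xb}: {res.message}")
    s_min = math.exp(res.x)
    if s_min < math.exp(lo) * 1.001 or s_min > math.exp(hi) * 0.999:
        raise NumericalError(
            f"optimum pinned to bracket edge at xb={xb}: lam/xb={s_min}"
        )
    return xb * s_min, math.exp(res.fun)


def threshold_fraction(xb: float, lam: float) -> float:
    """Boundary concentration as a fraction of the source amplitude.

    In the large-L limit ``rho(xb)/rho(0) = exp(-xb/lam)``; at the optimal
    point-model decay length this evaluates to ~0.1, i.e. boundaries sit
    where the profile has fallen to a tenth of its source value.
    """
    if not (lam > 0 and math.isfinite(lam)):
        raise InvalidParameterError(f"lam must be positive, got {lam!r}")
    if not (xb >= 0 and math.isfinite(xb)):
        raise InvalidParameterError(f"xb must be nonnegative, got {xb!r}")
    return math.exp(-xb / lam)


def tradeoff_point(params: SddParams, cost: CostParams, xb: float) -> TradeoffResult:
    """Assemble the full point-measurement trade-off at boundary ``xb``."""
    _validate_params(params)
    if not (0 < xb < params.L):
        raise DomainError("boundary position must satisfy 0 < xb < L")
    c = float(cost_point(params, cost, xb))
    e2 = float(positional_error_point(params, xb))
    product = c * e2
    norm = cost.alpha_o * params.L / params.lcell
    lam_min, prod_min_norm = optimal_lambda_point(xb, params.L)
    return TradeoffResult(
        xb=float(xb),
        lam=params.lam,
        cost=c,
        precision_sq=e2,
        product=product,
        product_normalized=product / norm,
        lambda_min=lam_min,
        product_min=prod_min_norm * norm,
    )


def results_to_json(results: Iterable[TradeoffResult], path: str | Path) -> None:
    """Serialize trade-off results to a JSON list."""
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)


def results_to_csv(results: Iterable[TradeoffResult], path: str | Path) -> None:
    """Serialize trade-off results to CSV, one row per (xb, lam) pair."""
    import pandas as pd

    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, index=False)
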