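"""Parameter containers for the synthesis-diffusion-depletion (SDD) model.

The SDD model describes a morphogen produced at one end of a 1D array of
cells (constant influx ``jin``), spreading with diffusivity ``D`` and removed
everywhere at first-order rate ``kd``.  Two derived quantities recur in every
result of the package:

* the decay length  ``lambda = sqrt(D / kd)``  of the exponential steady
  state, and
* the amplitude  ``nm = vcell * jin / (lcell * kd)``  -- the number of
  molecules produced during one degradation time, which sets the overall
  copy number scale (and hence the Poisson noise level).

All printed results of the theory are ratios, so any self-consistent unit
system works; ``lcell = kd = 1`` is a convenient canonical choice and the
``from_lambda`` constructor builds parameter sets directly in those units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .errors import InvalidParameterError

__all__ = [
    "SddParams",
    "CostParams",
    "SensorSpec",
    "SpacetimeParams",
    "load_config",
    "sdd_params_from_config",
]

_REL_TOL = 1e-12


def _require_positive_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise InvalidParameterError(
                f"{name} must be positive and finite, got {value!r}"
            )


@dataclass(frozen=True)
class SddParams:
    """Full parameterization of the 1D SDD system.

    Parameters
    ----------
    L : float
        System length.
    lcell : float
        Cell length (spatial grid unit defining local error and cost).
    vcell : float
        Cell volume; converts concentration to molecule counts.
    D : float
        Morphogen diffusivity, length^2 / time.
    kd : float
        First-order depletion rate, 1 / time.
    jin : float
        Influx at the source boundary, concentration x length / time.
    """

    L: float
    lcell: float
    vcell: float
    D: float
    kd: float
    jin: float
    lam: float = field(init=False)
    nm: float = field(init=False)

    def __post_init__(self) -> None:
        _require_positive_finite(
            L=self.L, lcell=self.lcell, vcell=self.vcell,
            D=self.D, kd=self.kd, jin=self.jin,
        )
        lam = math.sqrt(self.D / self.kd)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "nm", self.vcell * self.jin / (self.lcell * self.kd))
        # consistency of the derived decay length (guards unit mix-ups)
        if abs(lam * lam * self.kd - self.D) > _REL_TOL * self.D:
            raise InvalidParameterError("lambda^2 * kd inconsistent with D")

    @classmethod
    def from_lambda(
        cls,
        L: float,
        lam: float,
        *,
        lcell: float = 1.0,
        vcell: float = 1.0,
        kd: float = 1.0,
        jin: float = 1.0,
    ) -> "SddParams":
        """Build a parameter set from the decay length instead of ``D``."""
        _require_positive_finite(lam=lam, kd=kd)
        return cls(L=L, lcell=lcell, vcell=vcell, D=lam * lam * kd, kd=kd, jin=jin)

    def with_(self, **overrides: float) -> "SddParams":
        """Return a copy with the given primary fields replaced."""
        fields = dict(L=self.L, lcell=self.lcell, vcell=self.vcell,
                      D=self.D, kd=self.kd, jin=self.jin)
        fields.update(overrides)
        return SddParams(**fields)


@dataclass(frozen=True)
class CostParams:
    """Per-molecule thermodynamic cost.

    ``alpha_o`` is the cost (in ATP equivalents) of synthesizing and
    degrading one morphogen molecule; for a 494-residue protein at ~4 ATP
    per peptide bond this is about 2x10^3 ATP.
    """

    alpha_o: float = 1.0

    def __post_init__(self) -> None:
        _require_positive_finite(alpha_o=self.alpha_o)


@dataclass(frozen=True)
class SensorSpec:
    """Sensor geometry/duration for the space-time-averaged measurement.

    The sensor integrates the molecular count over the interval
    ``(x - a, x + a)`` for a duration ``T``.
    """

    a: float
    T: float

    def __post_init__(self) -> None:
        _require_positive_finite(a=self.a, T=self.T)


@dataclass(frozen=True)
class SpacetimeParams:
    """Parameters of the semi-infinite space-time-averaged model.

    Here ``jin`` is in molecules/time (not concentration flux) and ``lam``
    is the decay length; the model lives on a half-line, so there is no
    system size.
    """

    jin: float
    kd: float
    lam: float

    def __post_init__(self) -> None:
        _require_positive_finite(jin=self.jin, kd=self.kd, lam=self.lam)


# ---------------------------------------------------------------------------
# config loading


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a TOML or YAML config file into a plain dict.

    The format is chosen by extension (``.toml`` / ``.yaml`` / ``.yml``).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise InvalidParameterError(f"config {path} does not contain a mapping")
        return loaded
    raise InvalidParameterError(f"unsupported config format: {path.suffix!r}")


def sdd_params_from_config(config: Mapping[str, Any] | str | Path) -> SddParams:
    """Build :class:`SddParams` from a config mapping or file path.

    Keys mirror the field names (``L``, ``lcell``, ``vcell``, ``D``, ``kd``,
    ``jin``); a top-level ``sdd`` table is used when present.  ``lam`` may be
    given instead of ``D``.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    table = config.get("sdd", config)
    kwargs = {k: float(table[k]) for k in ("L", "lcell", "vcell", "kd", "jin") if k in table}
    kwargs.setdefault("lcell", 1.0)
    kwargs.setdefault("vcell", 1.0)
    kwargs.setdefault("kd", 1.0)
    kwargs.setdefault("jin", 1.0)
    if "D" in table:
        return SddParams(D=float(table["D"]), **kwargs)
    if "lam" in table:
        lam = float(table["lam"])
        return SddParams(D=lam * lam * kwargs["kd"], **kwargs)
    raise InvalidParameterError("config must provide either 'D' or 'lam'")
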