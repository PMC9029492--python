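"""Validated parameter records for the SLP model.

Every record stores strict SI values (A/m, J/m^3, kg/m^3, Pa.s, K, m, Hz).
Validation is eager: an invalid field raises :class:`InvalidParameterError` at
construction time, so the physics layer never sees an out-of-range value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class InvalidStateError(ValueError):
    """A derived quantity is undefined for the given parameter combination."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


def _finite(x: float, name: str) -> None:
    _require(isinstance(x, (int, float)) and math.isfinite(x), f"{name} must be a finite number, got {x!r}")


@dataclass(frozen=True)
class MaterialParams:
    """Intrinsic magnetic material constants.

    Parameters
    ----------
    Ms : float
        Spontaneous magnetization, A/m.
    K : float
        Uniaxial magnetic anisotropy constant, J/m^3.
    rho : float
        Density of the magnetic material, kg/m^3.
    tau0 : float, default 1e-9
        Attempt time of the Néel process, s.
    Msat : float, optional
        Saturation magnetization, A/m.  Defaults to ``Ms``.
    """

    Ms: float
    K: float
    rho: float
    tau0: float = 1e-9
    Msat: float | None = None

    def __post_init__(self) -> None:
        for name in ("Ms", "K", "rho", "tau0"):
            v = getattr(self, name)
            _finite(v, name)
            _require(v > 0, f"{name} must be strictly positive, got {v!r}")
        if self.Msat is None:
            object.__setattr__(self, "Msat", self.Ms)
        else:
            _finite(self.Msat, "Msat")
            _require(self.Msat > 0, f"Msat must be strictly positive, got {self.Msat!r}")


@dataclass(frozen=True)
class CoatingParams:
    """Organic shell on the particle surface.

    ``d`` is the layer thickness in metres; ``d = 0`` recovers an uncoated
    particle (hydrodynamic diameter equals the core diameter).
    """

    d: float = 0.0

    def __post_init__(self) -> None:
        _finite(self.d, "d")
        _require(self.d >= 0, f"coating thickness d must be >= 0, got {self.d!r}")


@dataclass(frozen=True)
class MediumParams:
    """Carrier liquid and thermal environment.

    Parameters
    ----------
    eta : float
        Dynamic viscosity of the carrier, Pa.s.
    T : float, default 300.0
        Absolute temperature, K.
    mobile : bool, default True
        Whether particles may rotate bodily (dispersed) or are immobilized.
    """

    eta: float
    T: float = 300.0
    mobile: bool = True

    def __post_init__(self) -> None:
        _finite(self.T, "T")
        _require(self.T > 0, f"temperature T must be positive, got {self.T!r}")
        _finite(self.eta, "eta")
        if self.mobile:
            _require(self.eta > 0, f"viscosity eta must be positive for a mobile particle, got {self.eta!r}")
        else:
            _require(self.eta >= 0, f"viscosity eta must be non-negative, got {self.eta!r}")


@dataclass(frozen=True)
class FieldParams:
    """AC magnetic field: amplitude ``H`` (A/m) and frequency ``f`` (Hz)."""

    H: float
    f: float

    def __post_init__(self) -> None:
        _finite(self.H, "H")
        _finite(self.f, "f")
        _require(self.H >= 0, f"field amplitude H must be >= 0, got {self.H!r}")
        _require(self.f > 0, f"frequency f must be positive, got {self.f!r}")


@dataclass(frozen=True)
class ParticleParams:
    """Monodisperse spherical ensemble: core diameter ``D`` (m) and packing fraction ``epsilon``."""

    D: float
    epsilon: float

    def __post_init__(self) -> None:
        _finite(self.D, "D")
        _finite(self.epsilon, "epsilon")
        _require(self.D > 0, f"core diameter D must be positive, got {self.D!r}")
        _require(0 <= self.epsilon <= 1, f"packing fraction epsilon must lie in [0, 1], got {self.epsilon!r}")


@dataclass(frozen=True)
class SLPBreakdown:
    """Every intermediate quantity on the way to the specific loss power.

    ``tau_N`` may be ``math.inf`` (the Néel barrier exceeded the overflow
    guard: the moment is frozen on any laboratory timescale).  ``tau_B`` is
    ``None`` for an immobilized particle, which cannot rotate bodily.
    ``Ps`` is in W per gram of magnetic material.
    """

    chi_i: float
    xi: float
    langevin_factor: float
    L: float
    tau_N: float
    tau_eff: float
    Dh: float
    Ps: float
    tau_B: float | None = None
    M: float | None = None

    @property
    def neel_frozen(self) -> bool:
        """True when the Néel time is effectively infinite."""
        return math.isinf(self.tau_N)
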