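"""Closed-form specific loss power (SLP) of superparamagnetic nanoparticles.

The model is linear-response (Debye) heating with a Langevin saturation
correction.  An AC field of amplitude H and frequency f drives an ensemble of
monodisperse, single-domain spherical particles; the out-of-phase response
dissipates

    Ps = pi * mu0 * f * H^2 * chi_i * [3 L(xi)/xi] * [w tau / (1 + (w tau)^2)] / rho

per unit mass (w = 2 pi f).  chi_i is the initial susceptibility of the
ensemble, 3 L(xi)/xi corrects it for partial saturation at finite field, and
tau is the magnetic relaxation time: the Néel time alone for an immobilized
particle, or the harmonic combination of the Néel and Brown times for a
particle free to rotate in a liquid.  The Brown time is governed by the
hydrodynamic diameter (core plus twice the shell thickness); all other
quantities use the magnetic core diameter.

Every function accepts scalars or numpy arrays in the diameter-like argument
and computes in strict SI; ``Ps`` is returned in W/g.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import KB, MU0, NEEL_EXPONENT_MAX
from .params import (
    CoatingParams,
    FieldParams,
    InvalidParameterError,
    InvalidStateError,
    MaterialParams,
    MediumParams,
    ParticleParams,
    SLPBreakdown,
)

__all__ = [
    "hydrodynamic_diameter",
    "langevin",
    "langevin_argument",
    "langevin_factor",
    "initial_susceptibility",
    "magnetization",
    "neel_time",
    "brown_time",
    "effective_time",
    "slp_immobilized",
    "slp_dispersed",
]

# Below this argument, coth(xi) - 1/xi loses ~xi^-2 digits to cancellation;
# the Taylor series through xi^7 is accurate to a few 1e-15 there, so the
# worst case sits at the switch point with relative error well under 1e-12.
_LANGEVIN_SERIES_CUTOFF = 0.05


def hydrodynamic_diameter(D, d):
    """Hydrodynamic diameter ``D + 2 d`` of a core-shell particle (m).

    The shell (thickness ``d``) enlarges the body that rotates against viscous
    drag, so this diameter enters the Brown time only; susceptibility, the
    Langevin argument and the Néel barrier all use the magnetic core ``D``.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise InvalidParameterError("core diameter D must be positive")
    if d < 0:
        raise InvalidParameterError("coating thickness d must be >= 0")
    out = D + 2.0 * d
    return float(out) if out.ndim == 0 else out


def langevin_argument(Ms, D, H, T):
    """Langevin argument xi = pi mu0 Ms D^3 H / (6 kB T) (dimensionless)."""
    if T <= 0:
        raise InvalidParameterError("temperature T must be positive")
    D = np.asarray(D, dtype=float)
    out = math.pi * MU0 * Ms * H / (6.0 * KB * T) * D**3
    return float(out) if out.ndim == 0 else out


def langevin(xi):
    """Langevin function L(xi) = coth(xi) - 1/xi, with L(0) = 0.

    Strictly increasing, bounded by 1.  Small arguments use the Taylor
    series ``xi/3 - xi^3/45 + 2 xi^5/945 - xi^7/4725`` to avoid catastrophic
    cancellation in ``coth(xi) - 1/xi``.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise InvalidParameterError("Langevin argument xi must be >= 0")
    small = xi < _LANGEVIN_SERIES_CUTOFF
    safe = np.where(small, 1.0, xi)
    out = np.where(
        small,
        xi / 3.0 - xi**3 / 45.0 + 2.0 * xi**5 / 945.0 - xi**7 / 4725.0,
        1.0 / np.tanh(safe) - 1.0 / safe,
    )
    return float(out) if out.ndim == 0 else out


def langevin_factor(xi):
    """Saturation correction 3 L(xi) / xi, with limit 1 at xi = 0.

    Multiplies the initial susceptibility; strictly decreasing, in (0, 1].
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise InvalidParameterError("Langevin argument xi must be >= 0")
    small = xi < _LANGEVIN_SERIES_CUTOFF
    safe = np.where(small, 1.0, xi)
    out = np.where(
        small,
        1.0 - xi**2 / 15.0 + 2.0 * xi**4 / 315.0 - xi**6 / 1575.0,
        3.0 * (1.0 / np.tanh(safe) - 1.0 / safe) / safe,
    )
    return float(out) if out.ndim == 0 else out


def initial_susceptibility(epsilon, Ms, D, T):
    """Initial susceptibility chi_i = epsilon pi mu0 Ms^2 D^3 / (18 kB T)."""
    if not 0 <= epsilon <= 1:
        raise InvalidParameterError("packing fraction epsilon must lie in [0, 1]")
    if T <= 0:
        raise InvalidParameterError("temperature T must be positive")
    D = np.asarray(D, dtype=float)
    out = epsilon * math.pi * MU0 * Ms**2 / (18.0 * KB * T) * D**3
    return float(out) if out.ndim == 0 else out


def magnetization(Msat, xi):
    """Ensemble magnetization M = Msat L(xi) (A/m)."""
    if Msat <= 0:
        raise InvalidParameterError("Msat must be positive")
    out = Msat * np.asarray(langevin(xi))
    return float(out) if out.ndim == 0 else out


def neel_time(tau0, K, D, T):
    """Néel relaxation time tau0 exp(pi K D^3 / (6 kB T)) (s).

    The barrier grows with the particle volume; once the exponent exceeds the
    overflow guard the time is returned as ``inf`` ("effectively infinite":
    its reciprocal is zero in the harmonic combination).
    """
    if tau0 <= 0 or K <= 0 or T <= 0:
        raise InvalidParameterError("tau0, K and T must be positive")
    D = np.asarray(D, dtype=float)
    exponent = math.pi * K / (6.0 * KB * T) * D**3
    out = np.where(
        exponent > NEEL_EXPONENT_MAX,
        np.inf,
        tau0 * np.exp(np.minimum(exponent, NEEL_EXPONENT_MAX)),
    )
    return float(out) if out.ndim == 0 else out


def brown_time(eta, Dh, T):
    """Brown rotational relaxation time 3 eta Vh / (kB T) = pi eta Dh^3 / (2 kB T) (s)."""
    if eta <= 0 or T <= 0:
        raise InvalidParameterError("eta and T must be positive")
    Dh = np.asarray(Dh, dtype=float)
    out = math.pi * eta / (2.0 * KB * T) * Dh**3
    return float(out) if out.ndim == 0 else out


def effective_time(tau_N, tau_B):
    """Harmonic combination tau_N tau_B / (tau_N + tau_B) (s).

    Evaluated through reciprocals so that an effectively infinite input
    degrades gracefully to the other time; the result never exceeds the
    smaller input.  Both inputs infinite is an invalid state (no relaxation
    channel at all).
    """
    tau_N = np.asarray(tau_N, dtype=float)
    tau_B = np.asarray(tau_B, dtype=float)
    if np.any(np.isinf(tau_N) & np.isinf(tau_B)):
        raise InvalidStateError("both relaxation times are infinite: no relaxation channel")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(tau_N), 0.0, 1.0 / tau_N) + np.where(np.isinf(tau_B), 0.0, 1.0 / tau_B)
    out = 1.0 / inv
    return float(out) if out.ndim == 0 else out


def _lorentzian(f, tau):
    """Out-of-phase Debye factor w tau / (1 + (w tau)^2), zero for tau = inf."""
    tau = np.asarray(tau, dtype=float)
    wt = 2.0 * math.pi * f * tau
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(np.isinf(tau), 0.0, wt / (1.0 + wt * wt))
    return out


def _slp_core(epsilon, material, f, H, T, D, tau):
    """Common Ps assembly given a relaxation time, W/g (per gram of core material)."""
    chi = initial_susceptibility(epsilon, material.Ms, D, T)
    xi = langevin_argument(material.Ms, D, H, T)
    fac = langevin_factor(xi)
    lor = _lorentzian(f, tau)
    ps_si = math.pi * MU0 * f * H**2 * chi * fac * lor / material.rho  # W/kg
    return chi, xi, fac, ps_si / 1000.0


def slp_immobilized(
    material: MaterialParams,
    particle: ParticleParams,
    field: FieldParams,
    T: float = 300.0,
) -> SLPBreakdown:
    """SLP of immobilized particles: the Néel channel alone dissipates.

    Returns the full :class:`SLPBreakdown`; ``tau_B`` is absent because a
    fixed particle cannot rotate bodily.  The hydrodynamic diameter equals the
    core diameter here (no rotation, so the shell is irrelevant).
    """
    D = particle.D
    tau_N = neel_time(material.tau0, material.K, D, T)
    chi, xi, fac, ps = _slp_core(particle.epsilon, material, field.f, field.H, T, D, tau_N)
    return SLPBreakdown(
        chi_i=float(chi),
        xi=float(xi),
        langevin_factor=float(fac),
        L=float(langevin(xi)),
        M=float(magnetization(material.Msat, xi)),
        tau_N=float(tau_N),
        tau_B=None,
        tau_eff=float(tau_N),
        Dh=D,
        Ps=float(ps),
    )


def slp_dispersed(
    material: MaterialParams,
    coating: CoatingParams,
    medium: MediumParams,
    particle: ParticleParams,
    field: FieldParams,
) -> SLPBreakdown:
    """SLP of particles dispersed in a liquid: Néel and Brown channels combine.

    The Brown time uses the hydrodynamic diameter ``D + 2 d``; susceptibility,
    Langevin argument and the Néel barrier use the core diameter.
    """
    D = particle.D
    T = medium.T
    Dh = hydrodynamic_diameter(D, coating.d)
    tau_N = neel_time(material.tau0, material.K, D, T)
    tau_B = brown_time(medium.eta, Dh, T)
    tau = effective_time(tau_N, tau_B)
    chi, xi, fac, ps = _slp_core(particle.epsilon, material, field.f, field.H, T, D, tau)
    return SLPBreakdown(
        chi_i=float(chi),
        xi=float(xi),
        langevin_factor=float(fac),
        L=float(langevin(xi)),
        M=float(magnetization(material.Msat, xi)),
        tau_N=float(tau_N),
        tau_B=float(tau_B),
        tau_eff=float(tau),
        Dh=float(Dh),
        Ps=float(ps),
    )


def slp_values(
    D,
    *,
    material: MaterialParams,
    epsilon: float,
    f: float,
    H: float,
    T: float = 300.0,
    coating: CoatingParams | None = None,
    medium: MediumParams | None = None,
    mode: str = "dispersed",
):
    """Vectorized Ps(D) in W/g over an array of core diameters.

    ``mode`` selects the dispersed (Néel + Brown) or immobilized (Néel-only)
    relaxation path; dispersed mode requires ``coating`` and ``medium``.
    This is the evaluation kernel behind the sweep machinery.
    """
    D = np.asarray(D, dtype=float)
    if mode == "dispersed":
        if coating is None or medium is None:
            raise InvalidParameterError("dispersed mode requires coating and medium parameters")
        T = medium.T
        tau_N = neel_time(material.tau0, material.K, D, T)
        tau_B = brown_time(medium.eta, hydrodynamic_diameter(D, coating.d), T)
        tau = effective_time(tau_N, tau_B)
    elif mode == "immobilized":
        tau = neel_time(material.tau0, material.K, D, T)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}: expected 'dispersed' or 'immobilized'")
    _, _, _, ps = _slp_core(epsilon, material, f, H, T, D, tau)
    return float(ps) if np.ndim(ps) == 0 else ps
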