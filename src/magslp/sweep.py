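"""Diameter sweeps of the SLP model, peak localization and regime analysis.

A sweep evaluates Ps(D) on a dense diameter grid for one (field amplitude,
frequency) condition, keeping every intermediate quantity.  Peaks of the
curve are the clinically interesting objects: the diameter D_M at which the
dissipated power is maximal and the power P_sM there.  Each peak is refined
below the grid resolution by golden-section search on the continuous model
and labelled by the relaxation regime that produces it — Brown (bodily
rotation in the liquid), Néel (internal moment reversal) or mixed.

The crossover diameter, where the Néel and Brown times are equal, separates
the two regimes: below it the Néel channel is faster, above it the Brown
channel dominates because the Néel time grows exponentially with volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import KB
from .params import (
    CoatingParams,
    InvalidParameterError,
    MaterialParams,
    MediumParams,
)
from . import physics

__all__ = [
    "SweepSpec",
    "SweepCurve",
    "PeakResult",
    "CrossoverResult",
    "sweep_curve",
    "find_peaks",
    "dominant_peak",
    "classify_regime",
    "crossover_diameter",
    "field_response",
    "frequency_response",
    "scenario_table",
]

#: Sweep CSV column order (display units; times and dimensionless columns raw).
CSV_COLUMNS = [
    "D_nm",
    "f_kHz",
    "H_kA_per_m",
    "epsilon",
    "chi_i",
    "xi",
    "langevin_factor",
    "tau_N_s",
    "tau_B_s",
    "tau_eff_s",
    "Ps_W_per_g",
]

#: Peaks closer than this (m) are float-noise twins and merge into one.
DEFAULT_MIN_SEPARATION = 0.2e-9

#: Factor-of-ten separation of the two relaxation times defines a pure regime.
REGIME_THRESHOLD = 10.0


@dataclass(frozen=True)
class SweepSpec:
    """Grid over which SLP is swept.

    ``D_range`` is (min, max, step) in metres; ``f_values``/``H_values`` are
    in Hz and A/m; ``mode`` selects the dispersed or immobilized model.
    """

    D_range: tuple[float, float, float]
    f_values: tuple[float, ...] = ()
    H_values: tuple[float, ...] = ()
    epsilon: float = 0.0
    mode: str = "dispersed"

    def __post_init__(self) -> None:
        lo, hi, step = self.D_range
        if not (step > 0 and lo > 0 and lo < hi):
            raise InvalidParameterError(f"D_range must satisfy 0 < min < max with step > 0, got {self.D_range}")
        if self.mode not in ("dispersed", "immobilized"):
            raise InvalidParameterError(f"mode must be 'dispersed' or 'immobilized', got {self.mode!r}")
        if not 0 <= self.epsilon <= 1:
            raise InvalidParameterError(f"epsilon must lie in [0, 1], got {self.epsilon!r}")

    def diameters(self) -> np.ndarray:
        """Deterministic grid: linspace with the step-implied point count."""
        lo, hi, step = self.D_range
        n = int(round((hi - lo) / step)) + 1
        if n < 2:
            raise InvalidParameterError("diameter grid has fewer than 2 points")
        return np.linspace(lo, lo + (n - 1) * step, n)


@dataclass(frozen=True)
class PeakResult:
    """A local maximum of Ps(D): location (m), height (W/g), regime label."""

    D_M: float
    P_sM: float
    regime: str
    refined: bool = True


@dataclass(frozen=True)
class CrossoverResult:
    """Diameter (m) at which the Néel and Brown times are equal, and that common time (s)."""

    D_cross: float
    tau_at_cross: float


@dataclass(frozen=True)
class SweepCurve:
    """One evaluated Ps(D) curve plus the continuous model behind it.

    ``table`` has one row per grid diameter in the CSV schema (D in nm, Ps in
    W/g, relaxation times in s).  ``ps_of_D`` re-evaluates the continuous
    model at any diameter in metres, which is what peak refinement uses.
    """

    table: pd.DataFrame
    f: float
    H: float
    epsilon: float
    mode: str
    material: MaterialParams
    coating: CoatingParams | None = None
    medium: MediumParams | None = None
    T: float = 300.0

    def ps_of_D(self, D) -> float:
        return physics.slp_values(
            D,
            material=self.material,
            epsilon=self.epsilon,
            f=self.f,
            H=self.H,
            T=self.T,
            coating=self.coating,
            medium=self.medium,
            mode=self.mode,
        )

    @property
    def D(self) -> np.ndarray:
        return self.table["D_nm"].to_numpy() * 1e-9

    @property
    def Ps(self) -> np.ndarray:
        return self.table["Ps_W_per_g"].to_numpy()


def sweep_curve(
    spec: SweepSpec,
    f: float,
    H: float,
    *,
    material: MaterialParams,
    coating: CoatingParams | None = None,
    medium: MediumParams | None = None,
    T: float = 300.0,
) -> SweepCurve:
    """Evaluate the SLP model on the spec's diameter grid at one (f, H).

    Returns a :class:`SweepCurve` whose table holds every breakdown quantity
    per grid diameter, ordered by D.  Deterministic: the grid and every value
    depend only on the inputs.
    """
    D = spec.diameters()
    if spec.mode == "dispersed":
        if coating is None or medium is None:
            raise InvalidParameterError("dispersed sweep requires coating and medium parameters")
        T = medium.T
        tau_N = physics.neel_time(material.tau0, material.K, D, T)
        tau_B = physics.brown_time(medium.eta, physics.hydrodynamic_diameter(D, coating.d), T)
        tau = physics.effective_time(tau_N, tau_B)
    else:
        tau_N = physics.neel_time(material.tau0, material.K, D, T)
        tau_B = np.full_like(D, np.nan)
        tau = tau_N
    chi = physics.initial_susceptibility(spec.epsilon, material.Ms, D, T)
    xi = physics.langevin_argument(material.Ms, D, H, T)
    fac = physics.langevin_factor(xi)
    ps = physics.slp_values(
        D, material=material, epsilon=spec.epsilon, f=f, H=H, T=T,
        coating=coating, medium=medium, mode=spec.mode,
    )
    table = pd.DataFrame(
        {
            "D_nm": D * 1e9,
            "f_kHz": f / 1e3,
            "H_kA_per_m": H / 1e3,
            "epsilon": spec.epsilon,
            "chi_i": chi,
            "xi": xi,
            "langevin_factor": fac,
            "tau_N_s": tau_N,
            "tau_B_s": tau_B,
            "tau_eff_s": tau,
            "Ps_W_per_g": ps,
        },
        columns=CSV_COLUMNS,
    )
    return SweepCurve(
        table=table, f=f, H=H, epsilon=spec.epsilon, mode=spec.mode,
        material=material, coating=coating, medium=medium, T=T,
    )


def _refine_peak(curve: SweepCurve, i: int) -> tuple[float, float]:
    """Golden-section refinement of a grid maximum within its bracketing cells."""
    D = curve.D
    brack = (D[i - 1], D[i], D[i + 1])
    try:
        d_opt = optimize.golden(lambda x: -curve.ps_of_D(x), brack=brack, tol=1e-10)
    except ValueError:
        # degenerate bracket (flat neighbours): keep the grid point
        return D[i], curve.Ps[i]
    d_opt = float(np.clip(d_opt, brack[0], brack[2]))
    return d_opt, float(curve.ps_of_D(d_opt))


def classify_regime(
    D: float,
    material: MaterialParams,
    coating: CoatingParams,
    medium: MediumParams,
    threshold: float = REGIME_THRESHOLD,
) -> str:
    """Label the relaxation regime at core diameter ``D`` (m).

    'neel' when the Néel time is more than ``threshold`` times shorter than
    the Brown time, 'brown' for the reverse, 'mixed' in between (both
    channels contribute comparably near the crossover).
    """
    T = medium.T
    tau_N = physics.neel_time(material.tau0, material.K, D, T)
    tau_B = physics.brown_time(medium.eta, physics.hydrodynamic_diameter(D, coating.d), T)
    if tau_N < tau_B / threshold:
        return "neel"
    if tau_B < tau_N / threshold:
        return "brown"
    return "mixed"


def find_peaks(
    curve: SweepCurve,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> list[PeakResult]:
    """All strict interior local maxima of the sweep, refined and classified.

    A grid point is a peak candidate when it strictly exceeds both
    neighbours; each candidate is refined by golden-section search within its
    bracketing cells.  Candidates closer than ``min_separation`` merge,
    keeping the higher.  Boundary maxima are warned about, never reported:
    they indicate the sweep window clipped a peak.
    """
    ps = curve.Ps
    if len(ps) < 3:
        raise InvalidParameterError("peak finding needs at least 3 grid points")
    interior = np.flatnonzero((ps[1:-1] > ps[:-2]) & (ps[1:-1] > ps[2:])) + 1
    if ps[0] > ps[1] or ps[-1] > ps[-2]:
        warnings.warn(
            "SLP is maximal at a sweep boundary; the diameter window may clip a peak",
            stacklevel=2,
        )
    peaks: list[PeakResult] = []
    for i in interior:
        d_opt, p_opt = _refine_peak(curve, int(i))
        if curve.mode == "dispersed":
            regime = classify_regime(d_opt, curve.material, curve.coating, curve.medium)
        else:
            regime = "neel"
        peaks.append(PeakResult(D_M=d_opt, P_sM=p_opt, regime=regime))
    peaks.sort(key=lambda p: p.D_M)
    merged: list[PeakResult] = []
    for p in peaks:
        if merged and p.D_M - merged[-1].D_M < min_separation:
            if p.P_sM > merged[-1].P_sM:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def dominant_peak(curve: SweepCurve, **kwargs) -> PeakResult:
    """The global maximum of the sweep (highest interior peak)."""
    peaks = find_peaks(curve, **kwargs)
    if not peaks:
        raise InvalidParameterError("curve has no interior maximum")
    return max(peaks, key=lambda p: p.P_sM)


def crossover_diameter(
    material: MaterialParams,
    coating: CoatingParams,
    medium: MediumParams,
    bracket: tuple[float, float] = (3e-9, 10e-9),
) -> CrossoverResult:
    """Diameter at which the Néel and Brown relaxation times are equal.

    Solves log(tau_N / tau_B) = 0 by bisection over ``bracket`` (m).  The log
    ratio is assembled from the Néel exponent directly, so the search is
    immune to overflow of the Néel time itself.
    """
    T = medium.T

    def log_ratio(D: float) -> float:
        exponent = math.pi * material.K * D**3 / (6.0 * KB * T)
        tau_B = physics.brown_time(medium.eta, physics.hydrodynamic_diameter(D, coating.d), T)
        return math.log(material.tau0) + exponent - math.log(tau_B)

    lo, hi = bracket
    if log_ratio(lo) * log_ratio(hi) > 0:
        raise InvalidParameterError(
            "tau_N - tau_B does not change sign over the bracket; widen it to straddle the crossover"
        )
    d_cross = float(optimize.bisect(log_ratio, lo, hi, rtol=1e-12, xtol=1e-15))
    tau = physics.brown_time(medium.eta, physics.hydrodynamic_diameter(d_cross, coating.d), T)
    return CrossoverResult(D_cross=d_cross, tau_at_cross=float(tau))


def _scan(spec, f, H, material, coating, medium, T):
    curve = sweep_curve(spec, f, H, material=material, coating=coating, medium=medium, T=T)
    return curve


def field_response(
    H_values,
    f: float,
    spec: SweepSpec,
    *,
    material: MaterialParams,
    coating: CoatingParams | None = None,
    medium: MediumParams | None = None,
    T: float = 300.0,
) -> pd.DataFrame:
    """Dominant peak per field amplitude at fixed frequency.

    One row per H with the global-maximum diameter and power; the power grows
    with H while the optimal diameter shrinks (stronger fields saturate large
    particles first).
    """
    rows = []
    for H in H_values:
        peak = dominant_peak(_scan(spec, f, H, material, coating, medium, T))
        rows.append(
            {
                "H_kA_per_m": H / 1e3,
                "f_kHz": f / 1e3,
                "D_M_nm": peak.D_M * 1e9,
                "PsM_W_per_g": peak.P_sM,
                "regime": peak.regime,
            }
        )
    return pd.DataFrame(rows)


def frequency_response(
    f_values,
    H: float,
    spec: SweepSpec,
    *,
    material: MaterialParams,
    coating: CoatingParams | None = None,
    medium: MediumParams | None = None,
    T: float = 300.0,
) -> pd.DataFrame:
    """All peaks per frequency at fixed field amplitude, one row per peak.

    At high frequency (around 2 MHz for cobalt-ferrite cores) the Néel
    channel produces a second, small-diameter maximum alongside the Brown
    one, so a single frequency may contribute two rows.
    """
    rows = []
    for f in f_values:
        curve = _scan(spec, f, H, material, coating, medium, T)
        for peak in find_peaks(curve):
            rows.append(
                {
                    "f_kHz": f / 1e3,
                    "H_kA_per_m": H / 1e3,
                    "D_M_nm": peak.D_M * 1e9,
                    "PsM_W_per_g": peak.P_sM,
                    "regime": peak.regime,
                }
            )
    return pd.DataFrame(rows)


def scenario_table(
    H_values,
    f_values,
    spec: SweepSpec,
    *,
    material: MaterialParams,
    coating: CoatingParams | None = None,
    medium: MediumParams | None = None,
    T: float = 300.0,
) -> pd.DataFrame:
    """Dominant maximum over a (H, f) grid: one row per combination."""
    rows = []
    for H in H_values:
        for f in f_values:
            peak = dominant_peak(_scan(spec, f, H, material, coating, medium, T))
            rows.append(
                {
                    "H_kA_per_m": H / 1e3,
                    "f_kHz": f / 1e3,
                    "D_M_nm": peak.D_M * 1e9,
                    "PsM_W_per_g": peak.P_sM,
                    "regime": peak.regime,
                }
            )
    return pd.DataFrame(rows)
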