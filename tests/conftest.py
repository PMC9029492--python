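"""Shared fixtures and the independent hand oracle.

The oracle evaluates the whole SLP chain in one pass of plain ``math`` calls,
written separately from the package so that agreement between the two is a
real cross-check and not a tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pytest

import magslp


@dataclass(frozen=True)
class OracleBreakdown:
    chi_i: float
    xi: float
    langevin_factor: float
    tau_N: float
    tau_B: float | None
    tau_eff: float
    Ps: float


def oracle_slp(
    D: float,
    H: float,
    f: float,
    eps: float,
    *,
    Ms: float = 425e3,
    K: float = 200e3,
    rho: float = 5.29e3,
    tau0: float = 1e-9,
    eta: float = 7e-4,
    d: float = 1.6e-9,
    T: float = 300.0,
    mobile: bool = True,
) -> OracleBreakdown:
    """Single-pass evaluation of the full SLP chain (SI in, W/g out)."""
    mu0 = 4e-7 * math.pi
    kB = 1.380649e-23
    chi = eps * math.pi * mu0 * Ms**2 * D**3 / (18 * kB * T)
    xi = math.pi * mu0 * Ms * D**3 * H / (6 * kB * T)
    if xi == 0.0:
        fac = 1.0
    elif xi < 0.05:
        fac = 1.0 - xi**2 / 15 + 2 * xi**4 / 315 - xi**6 / 1575
    else:
        fac = 3 * (1 / math.tanh(xi) - 1 / xi) / xi
    expo = math.pi * K * D**3 / (6 * kB * T)
    tau_N = math.inf if expo > 700 else tau0 * math.exp(expo)
    if mobile:
        tau_B = math.pi * eta * (D + 2 * d) ** 3 / (2 * kB * T)
        inv = (0.0 if math.isinf(tau_N) else 1 / tau_N) + 1 / tau_B
        tau = 1 / inv
    else:
        tau_B = None
        tau = tau_N
    wt = 0.0 if math.isinf(tau) else 2 * math.pi * f * tau
    lor = wt / (1 + wt * wt)
    ps = math.pi * mu0 * f * H**2 * chi * fac * lor / rho / 1000.0
    return OracleBreakdown(chi, xi, fac, tau_N, tau_B, tau, ps)


@pytest.fixture(scope="session")
def table1():
    """Baseline dilute cobalt-ferrite suspension preset."""
    return magslp.load_config("table1")


@pytest.fixture(scope="session")
def table5():
    """High-packing (epsilon=0.15) scenario preset."""
    return magslp.load_config("table5")
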