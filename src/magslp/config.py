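"""Configuration loading and packaged parameter presets.

Config files are flat key-value JSON or TOML in the conventional hyperthermia
units (kA/m, kJ/m^3, g/cm^3, Pa.s, nm, kHz, K); conversion to SI happens here,
exactly once, when the file resolves into validated physics types.  Unknown
keys are rejected outright rather than ignored, so a typo cannot silently
fall back to a default.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

from .params import (
    CoatingParams,
    InvalidParameterError,
    MaterialParams,
    MediumParams,
)
from .sweep import SweepSpec

logger = logging.getLogger("magslp")

__all__ = ["RunConfig", "load_config", "PRESETS"]

_ALLOWED_KEYS = {
    "Ms_kA_per_m",
    "K_kJ_per_m3",
    "rho_g_per_cm3",
    "epsilon",
    "eta_Pa_s",
    "d_nm",
    "T_K",
    "tau0_s",
    "Msat_kA_per_m",
    "mode",
    "D_min_nm",
    "D_max_nm",
    "D_step_nm",
    "H_kA_per_m",
    "f_kHz",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run setup: physics types plus the sweep grid."""

    material: MaterialParams
    coating: CoatingParams
    medium: MediumParams
    spec: SweepSpec
    name: str = "custom"

    def with_epsilon(self, epsilon: float) -> "RunConfig":
        return replace(self, spec=replace(self.spec, epsilon=epsilon))


def _build(values: dict, name: str) -> RunConfig:
    unknown = set(values) - _ALLOWED_KEYS
    if unknown:
        raise InvalidParameterError(
            f"unknown config key(s): {', '.join(sorted(unknown))}; allowed: {', '.join(sorted(_ALLOWED_KEYS))}"
        )
    try:
        material = MaterialParams(
            Ms=float(values["Ms_kA_per_m"]) * 1e3,
            K=float(values["K_kJ_per_m3"]) * 1e3,
            rho=float(values["rho_g_per_cm3"]) * 1e3,
            tau0=float(values.get("tau0_s", 1e-9)),
            Msat=float(values["Msat_kA_per_m"]) * 1e3 if "Msat_kA_per_m" in values else None,
        )
    except KeyError as exc:
        raise InvalidParameterError(f"missing required config key {exc.args[0]!r}") from None
    coating = CoatingParams(d=float(values.get("d_nm", 0.0)) * 1e-9)
    mode = values.get("mode", "dispersed")
    medium = MediumParams(
        eta=float(values.get("eta_Pa_s", 0.0)),
        T=float(values.get("T_K", 300.0)),
        mobile=(mode == "dispersed"),
    )
    spec = SweepSpec(
        D_range=(
            float(values.get("D_min_nm", 1.0)) * 1e-9,
            float(values.get("D_max_nm", 25.0)) * 1e-9,
            float(values.get("D_step_nm", 0.01)) * 1e-9,
        ),
        f_values=tuple(float(f) * 1e3 for f in values.get("f_kHz", ())),
        H_values=tuple(float(h) * 1e3 for h in values.get("H_kA_per_m", ())),
        epsilon=float(values.get("epsilon", 0.0)),
        mode=mode,
    )
    cfg = RunConfig(material=material, coating=coating, medium=medium, spec=spec, name=name)
    logger.info(
        "resolved config %s: Ms=%g A/m K=%g J/m3 rho=%g kg/m3 eta=%g Pa.s d=%g m "
        "T=%g K epsilon=%g mode=%s D=%s m",
        name, material.Ms, material.K, material.rho, medium.eta, coating.d,
        medium.T, spec.epsilon, spec.mode, spec.D_range,
    )
    return cfg


# Cobalt-ferrite cores with a ~1.6 nm cyclodextrin/PAA shell in saline.
# "table1": the baseline dilute suspension; "table5": the high-packing
# scenario over wider field and frequency ranges.
_PRESET_VALUES: dict[str, dict] = {
    "table1": {
        "Ms_kA_per_m": 425.0,
        "K_kJ_per_m3": 200.0,
        "rho_g_per_cm3": 5.29,
        "epsilon": 0.024,
        "eta_Pa_s": 7e-4,
        "d_nm": 1.6,
        "T_K": 300.0,
        "tau0_s": 1e-9,
        "D_min_nm": 1.0,
        "D_max_nm": 25.0,
        "D_step_nm": 0.01,
        "H_kA_per_m": [10.0, 30.0, 50.0],
        "f_kHz": [100.0, 500.0],
        "mode": "dispersed",
    },
    "table5": {
        "Ms_kA_per_m": 425.0,
        "K_kJ_per_m3": 200.0,
        "rho_g_per_cm3": 5.29,
        "epsilon": 0.15,
        "eta_Pa_s": 7e-4,
        "d_nm": 1.6,
        "T_K": 300.0,
        "tau0_s": 1e-9,
        "D_min_nm": 1.0,
        "D_max_nm": 30.0,
        "D_step_nm": 0.01,
        "H_kA_per_m": [5.0, 50.0, 100.0],
        "f_kHz": [50.0, 500.0, 1000.0],
        "mode": "dispersed",
    },
}

PRESETS = tuple(sorted(_PRESET_VALUES))


def load_config(source: str | Path, overrides: dict | None = None) -> RunConfig:
    """Resolve a preset name or a JSON/TOML config file into a :class:`RunConfig`.

    ``overrides`` (same keys as the file schema) take precedence over the
    file/preset values — this is how CLI flags override a config.
    """
    values: dict
    name = str(source)
    if name in _PRESET_VALUES:
        values = dict(_PRESET_VALUES[name])
    else:
        path = Path(source)
        if not path.exists():
            raise InvalidParameterError(
                f"{name!r} is neither a packaged preset ({', '.join(PRESETS)}) nor an existing config file"
            )
        if path.suffix.lower() == ".toml":
            with open(path, "rb") as fh:
                values = tomllib.load(fh)
        else:
            with open(path, encoding="utf-8") as fh:
                values = json.load(fh)
        name = path.stem
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    return _build(values, name)
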