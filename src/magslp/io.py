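"""CSV and JSON writers for sweep curves and peak summaries.

Files carry full ``repr`` precision so that a written sweep re-reads
bit-identically; rounding to the conventional display precision (0.01 W/g
for power, 0.1 nm for diameter) happens only in human-readable tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .sweep import CrossoverResult, PeakResult, SweepCurve

__all__ = [
    "write_sweep_csv",
    "read_sweep_csv",
    "peaks_to_dict",
    "crossover_to_dict",
    "write_json",
    "format_peak_table",
]


def write_sweep_csv(curve: SweepCurve | pd.DataFrame, path) -> None:
    """Write a sweep to RFC-4180 CSV with a header row, full precision."""
    table = curve.table if isinstance(curve, SweepCurve) else curve
    table.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_sweep_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def peaks_to_dict(H: float, f: float, peaks: list[PeakResult]) -> dict:
    """Serializable peak summary for one (H, f) condition (display units)."""
    return {
        "H_kA_per_m": H / 1e3,
        "f_kHz": f / 1e3,
        "peaks": [
            {"D_M_nm": p.D_M * 1e9, "PsM_W_per_g": p.P_sM, "regime": p.regime}
            for p in peaks
        ],
    }


def crossover_to_dict(result: CrossoverResult) -> dict:
    return {"crossover_nm": result.D_cross * 1e9, "tau_at_cross_s": result.tau_at_cross}


def write_json(obj, path_or_stream) -> None:
    """Deterministic JSON: sorted keys, no timestamps, UTF-8."""
    text = json.dumps(obj, indent=2, sort_keys=True)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text + "\n")
    else:
        Path(path_or_stream).write_text(text + "\n", encoding="utf-8")


def format_peak_table(df: pd.DataFrame) -> str:
    """Human-readable peak table: Ps to 0.01 W/g, D to 0.1 nm."""
    shown = df.copy()
    if "D_M_nm" in shown:
        shown["D_M_nm"] = shown["D_M_nm"].round(1)
    if "PsM_W_per_g" in shown:
        shown["PsM_W_per_g"] = shown["PsM_W_per_g"].round(2)
    return shown.to_string(index=False)
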