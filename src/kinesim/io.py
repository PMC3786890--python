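"""Delimited-text I/O with validation and sidecar metadata.

All datasets are small curves and profiles, so they live in plain CSV/TSV
(auto-detected delimiter, header row naming the columns) with an optional
JSON sidecar ``<path>.meta.json`` carrying ground truth and provenance.
Numeric round trips preserve 17 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .frap import RecoveryCurve
from .profiles import LineProfile

__all__ = [
    "read_table",
    "write_table",
    "read_meta",
    "read_recovery_curve",
    "write_recovery_curve",
    "read_line_profile",
    "write_line_profile",
    "write_field",
]


def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a delimited text table; validate required numeric columns.

    Extra columns are preserved. Raises ``ValueError`` naming the offending
    column (and row, for non-numeric cells).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} (found {list(df.columns)})")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        df[col] = coerced
    return df


def write_table(path, df: pd.DataFrame, meta: Optional[dict] = None, sep: str = ",") -> Path:
    """Write a table at full float precision; optional JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    if meta is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=float) + "\n")
    return path


def read_meta(path) -> dict:
    return json.loads(Path(str(path) + ".meta.json").read_text())


def read_recovery_curve(path) -> RecoveryCurve:
    df = read_table(path, required=("t_s", "F"))
    return RecoveryCurve(df["t_s"].to_numpy(), df["F"].to_numpy())


def write_recovery_curve(path, curve: RecoveryCurve, meta: Optional[dict] = None) -> Path:
    return write_table(path, pd.DataFrame({"t_s": curve.t, "F": curve.F}), meta)


def read_line_profile(path) -> LineProfile:
    df = read_table(path, required=("s_um", "khc", "egfp"))
    return LineProfile(df["s_um"].to_numpy(), df["khc"].to_numpy(), df["egfp"].to_numpy())


def write_line_profile(path, profile: LineProfile, meta: Optional[dict] = None) -> Path:
    df = pd.DataFrame({"s_um": profile.s, "khc": profile.khc, "egfp": profile.egfp})
    return write_table(path, df, meta)


def write_field(path, field, meta: Optional[dict] = None) -> Path:
    """Export a ConcentrationField as (x_um, c_bound, c_free, c_inert, c_tot)."""
    df = pd.DataFrame(
        {
            "x_um": field.x,
            "c_bound": field.c_bound,
            "c_free": field.c_free,
            "c_inert": field.c_inert,
            "c_tot": field.c_tot,
        }
    )
    return write_table(path, df, meta)
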