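"""CSV schemas and validated readers/writers for the behavioural tables.

All tables are flat CSV.  Angles are degrees of visual angle (origin at the
stimulus centre, y up); durations are milliseconds; scales are unitless.

trials.csv     one row per stimulus interval (two per trial):
               participant, trial, interval, scale, is_standard,
               target_present, target_x_deg, target_y_deg, response_present,
               chosen, blink, practice
fixations.csv  participant, trial, interval, order_index, x_deg, y_deg,
               duration_ms
staircase.csv  participant, trial, contrast, correct
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_trials", "read_fixations", "read_staircase",
           "write_table", "SchemaError"]

TRIALS_SCHEMA = {
    "participant": None, "trial": int, "interval": int, "scale": float,
    "is_standard": bool, "target_present": bool, "target_x_deg": float,
    "target_y_deg": float, "response_present": bool, "chosen": bool,
    "blink": bool, "practice": bool,
}
FIXATIONS_SCHEMA = {
    "participant": None, "trial": int, "interval": int, "order_index": int,
    "x_deg": float, "y_deg": float, "duration_ms": float,
}
STAIRCASE_SCHEMA = {
    "participant": None, "trial": int, "contrast": float, "correct": bool,
}

FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def _read(path, schema: dict, name: str, bool_allow_na=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")
    for col, typ in schema.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                rows = list(df.index[bad][:5] + 2)  # +2: header + 1-based
                raise SchemaError(
                    f"{name}: non-numeric values in {col!r} at file row(s) "
                    f"{rows}")
            if typ is int and coerced.notna().all() and \
                    not np.allclose(coerced, coerced.round()):
                raise SchemaError(f"{name}: non-integer values in {col!r}")
            df[col] = coerced
        elif typ is bool and col not in bool_allow_na:
            df[col] = df[col].map(_to_bool)
            if df[col].isna().any():
                raise SchemaError(f"{name}: non-boolean values in {col!r}")
            df[col] = df[col].astype(bool)
    return df


def _to_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, float, np.integer, np.floating)):
        if v in (0, 1):
            return bool(v)
        return np.nan
    s = str(v).strip().lower()
    return {"true": True, "false": False, "1": True, "0": False}.get(s, np.nan)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trials table.

    Enforces: documented columns, numeric positions, two intervals per trial,
    no duplicate (participant, trial, interval).
    """
    df = _read(path, TRIALS_SCHEMA, "trials")
    key = ["participant", "trial", "interval"]
    dup = df.duplicated(key)
    if dup.any():
        offenders = df.loc[dup, key].head(5).to_dict("records")
        raise SchemaError(f"trials: duplicate {key} rows, e.g. {offenders}")
    sizes = df.groupby(["participant", "trial"]).size()
    if (sizes != 2).any():
        bad = sizes[sizes != 2].head(5).index.tolist()
        raise SchemaError(f"trials: trials without exactly 2 intervals: {bad}")
    return df


def read_fixations(path) -> pd.DataFrame:
    """Read and validate a fixations table."""
    df = _read(path, FIXATIONS_SCHEMA, "fixations")
    key = ["participant", "trial", "interval", "order_index"]
    dup = df.duplicated(key)
    if dup.any():
        offenders = df.loc[dup, key].head(5).to_dict("records")
        raise SchemaError(f"fixations: duplicate {key} rows, e.g. {offenders}")
    if (df["duration_ms"] <= 0).any():
        raise SchemaError("fixations: non-positive duration_ms")
    return df


def read_staircase(path) -> pd.DataFrame:
    """Read and validate a staircase table."""
    df = _read(path, STAIRCASE_SCHEMA, "staircase")
    if ((df["contrast"] <= 0) | (df["contrast"] > 1)).any():
        raise SchemaError("staircase: contrast must be in (0, 1]")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV deterministically (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
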