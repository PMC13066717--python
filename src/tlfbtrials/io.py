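"""Readers and writers for the package's CSV/JSON dialects.

All tables travel as RFC-4180 CSV with booleans serialized as 0/1; run
manifests and exclusion logs are JSON.  Readers validate every row and report
problems with 1-based CSV line numbers (header = line 1); silent coercion is
never performed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tlfb import StudyConfig, TlfbCalendar

__all__ = [
    "read_tlfb",
    "write_tlfb",
    "read_baseline",
    "write_baseline",
    "build_calendars",
    "write_table",
    "file_sha256",
    "write_json",
]

TLFB_COLUMNS = ["participant_id", "day", "drinks", "missing"]


class UserInputError(ValueError):
    """Malformed user-supplied input (maps to CLI exit code 1)."""


def _lines(mask: pd.Series) -> list[int]:
    # +2: 1-based numbering plus the header line.
    return [int(i) + 2 for i in mask[mask].index[:8]]


def read_tlfb(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format daily drinking CSV.

    Schema: ``participant_id,day,drinks,missing`` with ``missing`` in {0,1}
    and ``drinks`` empty exactly when ``missing`` is 1.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = [c for c in TLFB_COLUMNS if c not in df.columns]
    if missing_cols:
        raise UserInputError(f"{path}: TLFB file missing columns {missing_cols}")
    day = pd.to_numeric(df["day"], errors="coerce")
    bad = day.isna() | (day != day.round())
    if bad.any():
        raise UserInputError(f"{path}: non-integer day values at lines {_lines(bad)}")
    miss = pd.to_numeric(df["missing"], errors="coerce")
    bad = ~miss.isin([0, 1])
    if bad.any():
        raise UserInputError(f"{path}: missing flag must be 0 or 1 at lines {_lines(bad)}")
    drinks = pd.to_numeric(df["drinks"], errors="coerce")
    bad = (miss == 0) & drinks.isna()
    if bad.any():
        raise UserInputError(f"{path}: observed day without drinks value at lines {_lines(bad)}")
    bad = (miss == 0) & (drinks < 0)
    if bad.any():
        raise UserInputError(f"{path}: negative drinks at lines {_lines(bad)}")
    bad = (miss == 1) & drinks.notna()
    if bad.any():
        raise UserInputError(f"{path}: missing day carries a drinks value at lines {_lines(bad)}")
    dup = df.duplicated(subset=["participant_id", "day"])
    if dup.any():
        raise UserInputError(f"{path}: duplicate (participant, day) rows at lines {_lines(dup)}")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "day": day.astype(int),
            "drinks": drinks,
            "missing": miss.astype(int),
        }
    )
    return out


def write_tlfb(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format TLFB table (drinks blank on missing days)."""
    out = df[TLFB_COLUMNS].copy()
    out["drinks"] = [
        "" if m else f"{d:.4f}" for d, m in zip(out["drinks"], out["missing"].astype(bool))
    ]
    out.to_csv(path, index=False)


def read_baseline(path: str | Path) -> pd.DataFrame:
    """Read a raw per-study baseline table, validating ids and ages."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise UserInputError(f"{path}: baseline file has no participant_id column")
    if df["participant_id"].isna().any() or df["participant_id"].duplicated().any():
        raise UserInputError(f"{path}: missing or duplicate participant ids")
    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce")
        bad = age.isna() | (age <= 0)
        if bad.any():
            raise UserInputError(f"{path}: invalid age at lines {_lines(bad)}")
    return df


def write_baseline(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False, float_format="%.4f")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write an output table with 0/1 booleans and stable float formatting."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=index, float_format="%.6g")


def build_calendars(
    tlfb: pd.DataFrame,
    *,
    screening_day: int,
    treatment_end_by_id: Mapping[str, int] | int,
) -> list[TlfbCalendar]:
    """Assemble per-participant calendars from a long-format TLFB table."""
    calendars = []
    for pid, g in tlfb.sort_values(["participant_id", "day"]).groupby("participant_id", sort=True):
        t_end = (
            treatment_end_by_id
            if isinstance(treatment_end_by_id, int)
            else treatment_end_by_id[pid]
        )
        days = g["day"].to_numpy()
        lo, hi = int(days.min()), int(days.max())
        drinks = np.full(hi - lo + 1, np.nan)
        missing = np.ones(hi - lo + 1, dtype=bool)
        drinks[days - lo] = g["drinks"].to_numpy()
        missing[days - lo] = g["missing"].to_numpy().astype(bool)
        drinks[missing] = np.nan
        calendars.append(
            TlfbCalendar(
                str(pid),
                start_day=lo,
                drinks=drinks,
                missing=missing,
                screening_day=screening_day,
                treatment_end_day=int(t_end),
            )
        )
    return calendars


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
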