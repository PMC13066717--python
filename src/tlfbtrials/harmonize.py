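"""Merging per-study tables into one analysis dataset.

The five bundled trial designs used different instruments for marital status,
employment, income and smoking; harmonization recodes each raw category into
the shared binary flags through explicit category dictionaries (shipped as
package data, overridable per study) and then merges the per-study tables.
Participants whose baseline WHO risk level is below MEDIUM are excluded — a
two-level risk reduction is not attainable from LOW — and every exclusion is
logged so that retained + excluded always reconciles with the input.

Race/ethnicity is carried as three non-exclusive indicator columns (White,
Black, Hispanic); participants in none of the three form the implicit
reference category and their count is logged rather than modelled.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .tlfb import RiskLevel

__all__ = [
    "HARMONIZED_COLUMNS",
    "default_category_maps",
    "recode_demographics",
    "apply_exclusions",
    "merge_studies",
]

#: Column order of a harmonized baseline table.
HARMONIZED_COLUMNS = [
    "participant_id",
    "study",
    "arm",
    "sex",
    "age",
    "married_cohab",
    "education_12plus",
    "employed",
    "income_60k",
    "race_white",
    "race_black",
    "race_hispanic",
    "smoker_10plus",
    "thc_positive",
    "baseline_rdl",
]

#: Raw per-study dialect expected by :func:`recode_demographics`.
RAW_COLUMNS = [
    "participant_id",
    "study",
    "arm",
    "sex",
    "age",
    "marital",
    "employment",
    "income_category",
    "education_years",
    "cigarettes_per_day",
    "thc_screen",
    "race",
    "hispanic",
]


def default_category_maps() -> dict:
    """The bundled category dictionaries (marital/employment/income/...)."""
    text = resources.files("tlfbtrials.data").joinpath("category_maps.yaml").read_text()
    return yaml.safe_load(text)


def _map_column(series: pd.Series, mapping: Mapping, name: str) -> pd.Series:
    values = series.astype(str)
    unknown = sorted(set(values.dropna().unique()) - set(map(str, mapping)))
    if unknown:
        raise ValueError(f"unmappable {name} categories: {unknown}")
    return values.map({str(k): v for k, v in mapping.items()})


def recode_demographics(raw: pd.DataFrame, maps: Mapping | None = None) -> pd.DataFrame:
    """Recode one study's raw baseline table into the harmonized binary schema.

    Recodings: married/cohabitating vs all other marital states; employed full
    or part time vs the rest; income dichotomized at $60,000/yr (collected as
    ordinal bands); education at 12+ years; smoking at 10+ cigarettes/day; THC
    from the urine-screen result.  Any raw category absent from the dictionary
    raises, listing the offending values.
    """
    maps = dict(default_category_maps(), **(maps or {}))
    required = [c for c in RAW_COLUMNS if c not in ("study", "arm")]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw baseline table missing columns: {missing_cols}")

    out = pd.DataFrame(index=raw.index)
    for col in ("participant_id", "study", "arm", "sex"):
        if col in raw.columns:
            out[col] = raw[col]
    age = pd.to_numeric(raw["age"])
    if (age <= 0).any():
        raise ValueError("age must be positive")
    out["age"] = age
    out["married_cohab"] = _map_column(raw["marital"], maps["marital"], "marital")
    out["education_12plus"] = (
        pd.to_numeric(raw["education_years"]) >= maps["education_years_threshold"]
    )
    out["employed"] = _map_column(raw["employment"], maps["employment"], "employment")
    out["income_60k"] = _map_column(raw["income_category"], maps["income"], "income_category")
    race = _map_column(raw["race"], maps["race"], "race")
    out["race_white"] = race == "white"
    out["race_black"] = race == "black"
    out["race_hispanic"] = raw["hispanic"].astype(int).astype(bool)
    out["smoker_10plus"] = (
        pd.to_numeric(raw["cigarettes_per_day"]) >= maps["cigarettes_per_day_threshold"]
    )
    out["thc_positive"] = _map_column(raw["thc_screen"], maps["thc_screen"], "thc_screen")
    if "baseline_rdl" in raw.columns:
        out["baseline_rdl"] = raw["baseline_rdl"]
    for col in out.columns:
        if out[col].dtype == object and set(out[col].dropna().unique()) <= {True, False}:
            out[col] = out[col].astype(bool)
    return out


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop baseline low-risk (and abstinent) rows; return the table plus a log.

    The log reconciles exactly: ``input_n == retained_n + sum(excluded)``, and
    additionally counts rows retained without a White/Black race indicator
    (small categories that are kept in the data but not separately modelled).
    """
    if "baseline_rdl" not in table.columns:
        raise ValueError("table has no baseline_rdl column")
    levels = table["baseline_rdl"].map(lambda v: RiskLevel.from_label(v).label)
    excluded_low = int((levels == "low").sum())
    excluded_abstinent = int((levels == "abstinent").sum())
    keep = ~levels.isin(["low", "abstinent"])
    out = table.loc[keep].copy()
    log = {
        "input_n": int(len(table)),
        "excluded_baseline_low": excluded_low,
        "excluded_baseline_abstinent": excluded_abstinent,
        "retained_n": int(len(out)),
    }
    if {"race_white", "race_black"} <= set(out.columns):
        log["retained_without_race_indicator"] = int(
            (~out["race_white"].astype(bool) & ~out["race_black"].astype(bool)).sum()
        )
    if len(out) == 0:
        warnings.warn("all rows excluded: every participant was baseline low-risk/abstinent")
    out.attrs["exclusion_log"] = log
    return out, log


def merge_studies(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-study tables, keeping the study label as a covariate.

    Schemas must agree exactly (an error names the missing columns).
    Participant ids are prefixed with the study label so ids reused across
    trials can never collide.
    """
    tables = [t for t in tables if len(t)]
    if not tables:
        raise ValueError("no non-empty tables to merge")
    ref_cols = list(tables[0].columns)
    for t in tables[1:]:
        missing = sorted(set(ref_cols) - set(t.columns))
        extra = sorted(set(t.columns) - set(ref_cols))
        if missing or extra:
            raise ValueError(
                f"schema mismatch between study tables: missing {missing}, unexpected {extra}"
            )
    parts = []
    for t in tables:
        t = t.copy()
        prefix = t["study"].astype(str) + ":"
        pid = t["participant_id"].astype(str)
        needs = ~pid.str.startswith(prefix.iloc[0]) if len(t) else pid
        t["participant_id"] = pid.where(~needs, prefix + pid)
        parts.append(t[ref_cols])
    merged = pd.concat(parts, ignore_index=True)
    if merged["participant_id"].duplicated().any():
        dupes = merged.loc[merged["participant_id"].duplicated(), "participant_id"].unique()
        raise ValueError(f"duplicate participant ids after study prefixing: {list(dupes)[:5]}")
    merged.attrs["per_study_counts"] = merged["study"].value_counts().to_dict()
    return merged
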