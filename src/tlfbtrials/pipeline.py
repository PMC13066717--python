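"""End-to-end pipeline: simulate-or-load -> derive -> harmonize -> analyze.

The pipeline is a thin composition of the library stages plus a machine-
readable run manifest (input hashes, the fully-resolved configuration and
library versions), so that identical inputs, configuration and seed always
produce identical outputs and an identical manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__ as _pkg_version
from .analysis import (
    OUTCOME_COLUMNS,
    bonferroni_threshold,
    cutoff_table,
    fit_outcome_model,
    group_compare,
    roc_youden,
    tabulate_outcomes,
)
from .endpoints import derive_endpoint_table
from .harmonize import apply_exclusions, merge_studies, recode_demographics
from .io import (
    build_calendars,
    file_sha256,
    read_baseline,
    read_tlfb,
    write_baseline,
    write_json,
    write_table,
    write_tlfb,
)
from .simulate import SimulationConfig, simulate_trial
from .tlfb import StudyConfig, study_presets

__all__ = ["PipelineConfig", "run_pipeline", "harmonize_tables", "derive_from_frames"]


class PipelineConfig(BaseModel):
    """Everything a full run needs, validated before any computation."""

    seed: int = 0
    #: Synthetic-trial generator settings (used when no input paths are given).
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    #: Optional real inputs; when set, simulation is skipped.
    tlfb_path: str | None = None
    baseline_path: str | None = None
    screening_gap_days: int = Field(default=14, ge=1)
    grams_per_drink: float = Field(default=14.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_tests: int = Field(default=4, ge=1)
    who_window_policy: str = "strict"
    roc_outcomes: list[str] = Field(default_factory=lambda: ["abstinent", "no_heavy", "who2plus"])


def _study_configs_for(baseline: pd.DataFrame, grams_per_drink: float) -> dict[str, StudyConfig]:
    presets = study_presets()
    out = {}
    for pid, study in zip(baseline["participant_id"], baseline["study"]):
        if study not in presets:
            raise ValueError(f"no study preset for {study!r}")
        p = presets[study]
        out[str(pid)] = StudyConfig(
            study_name=study,
            treatment_weeks=p.treatment_weeks,
            titration_weeks=p.titration_weeks,
            taper_weeks=p.taper_weeks,
            grams_per_drink=grams_per_drink,
        )
    return out


def derive_from_frames(
    tlfb: pd.DataFrame,
    baseline: pd.DataFrame,
    *,
    screening_gap_days: int = 14,
    grams_per_drink: float = 14.0,
    who_policy: str = "strict",
    cfg_by_id: Mapping[str, StudyConfig] | None = None,
) -> pd.DataFrame:
    """Derive the endpoint table from long-format TLFB plus a baseline table."""
    cfgs = cfg_by_id or _study_configs_for(baseline, grams_per_drink)
    calendars = build_calendars(
        tlfb,
        screening_day=-screening_gap_days,
        treatment_end_by_id={pid: cfg.treatment_end_day for pid, cfg in cfgs.items()},
    )
    sex_by_id = dict(zip(baseline["participant_id"].astype(str), baseline["sex"]))
    return derive_endpoint_table(calendars, sex_by_id, cfgs, who_policy=who_policy)


def harmonize_tables(
    baseline_raw: pd.DataFrame, endpoint_df: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Recode each study's raw baseline, join endpoints, merge and exclude."""
    per_study = []
    for _, sub in baseline_raw.groupby("study", sort=True):
        recoded = recode_demographics(sub.reset_index(drop=True))
        joined = recoded.merge(endpoint_df, on="participant_id", how="inner", validate="1:1")
        per_study.append(joined)
    merged = merge_studies(per_study)
    return apply_exclusions(merged)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write all outputs plus a manifest.

    Returns a dict with the in-memory results (analysis table, fits, ROC
    curves, cutoff report) for programmatic use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.model_dump(),
        "versions": {"tlfbtrials": _pkg_version, "pandas": pd.__version__},
        "inputs": {},
        "outputs": [],
    }

    if cfg.tlfb_path and cfg.baseline_path:
        tlfb = read_tlfb(cfg.tlfb_path)
        baseline_raw = read_baseline(cfg.baseline_path)
        manifest["inputs"] = {
            "tlfb": file_sha256(cfg.tlfb_path),
            "baseline": file_sha256(cfg.baseline_path),
        }
        screening_gap = cfg.screening_gap_days
        cfg_by_id = None
        calendars_src = None
    else:
        sim = simulate_trial(cfg.simulation, seed=cfg.seed)
        tlfb, baseline_raw = sim.tlfb, sim.baseline
        write_tlfb(tlfb, out / "tlfb.csv")
        write_baseline(baseline_raw, out / "baseline.csv")
        write_baseline(sim.truth, out / "truth.csv")
        write_json(sim.params, out / "truth_params.json")
        manifest["inputs"] = {
            "tlfb": file_sha256(out / "tlfb.csv"),
            "baseline": file_sha256(out / "baseline.csv"),
        }
        screening_gap = cfg.simulation.screening_gap_days
        cfg_by_id = sim.study_configs()
        calendars_src = sim

    if calendars_src is not None:
        sex_by_id = calendars_src.sex_by_id()
        endpoint_df = derive_endpoint_table(
            calendars_src.calendars(), sex_by_id, cfg_by_id, who_policy=cfg.who_window_policy
        )
    else:
        endpoint_df = derive_from_frames(
            tlfb,
            baseline_raw,
            screening_gap_days=screening_gap,
            grams_per_drink=cfg.grams_per_drink,
            who_policy=cfg.who_window_policy,
        )
    write_table(endpoint_df, out / "endpoints.csv")

    table, exclusion_log = harmonize_tables(baseline_raw, endpoint_df)
    write_table(table, out / "analysis_table.csv")
    write_json(exclusion_log, out / "exclusion_log.json")

    threshold = bonferroni_threshold(cfg.alpha, cfg.n_tests)
    fits = {}
    for outcome in OUTCOME_COLUMNS:
        for subset in ("all", "placebo_only"):
            try:
                fit = fit_outcome_model(
                    table, outcome, subset, alpha=cfg.alpha, n_tests=cfg.n_tests
                )
            except ValueError as exc:
                fits[(outcome, subset)] = None
                manifest.setdefault("model_failures", []).append(f"{outcome}/{subset}: {exc}")
                continue
            fits[(outcome, subset)] = fit
            write_table(
                fit.summary_frame().reset_index(names="predictor"),
                out / f"coefficients_{outcome}_{subset}.csv",
            )

    rocs = {}
    for outcome in cfg.roc_outcomes:
        try:
            roc = roc_youden(table["dsld"].to_numpy(), table[outcome].astype(bool).to_numpy())
        except ValueError as exc:
            manifest.setdefault("model_failures", []).append(f"roc {outcome}: {exc}")
            continue
        rocs[outcome] = roc
        write_table(roc.frame(), out / f"roc_{outcome}.csv")

    finite = [r.optimal_cutoff for r in rocs.values() if np.isfinite(r.optimal_cutoff)]
    primary_cutoff = finite[-1] if finite else 3.5
    cut = cutoff_table(table, primary_cutoff, alpha_threshold=threshold)
    write_table(cut.table.reset_index(), out / "cutoff_table.csv")

    by_rdl = tabulate_outcomes(table)
    write_table(by_rdl.reset_index(), out / "outcomes_by_baseline_rdl.csv")

    dsld_tests = []
    for outcome in OUTCOME_COLUMNS:
        try:
            res = group_compare(table, outcome, "dsld")
        except ValueError as exc:
            manifest.setdefault("model_failures", []).append(f"dsld by {outcome}: {exc}")
            continue
        g = res.group_stats
        dsld_tests.append(
            {
                "outcome": outcome,
                "t": res.statistic,
                "p": res.pvalue,
                "mean_success": float(g.loc[g.index.max(), "mean"]),
                "mean_failure": float(g.loc[g.index.min(), "mean"]),
            }
        )
    write_table(pd.DataFrame(dsld_tests), out / "dsld_group_tests.csv")

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest["summary"] = {
        "n_analysis": int(len(table)),
        "bonferroni_threshold": threshold,
        "roc_optimal_cutoffs": {k: r.optimal_cutoff for k, r in rocs.items()},
        "roc_auc": {k: r.auc for k, r in rocs.items()},
    }
    write_json(manifest, out / "manifest.json")
    return {
        "table": table,
        "endpoints": endpoint_df,
        "fits": fits,
        "rocs": rocs,
        "cutoff": cut,
        "exclusion_log": exclusion_log,
        "manifest": manifest,
    }
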