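"""Synthetic multi-study trial generator with known ground truth.

The real calendars behind this kind of analysis are controlled-access
clinical-trial datasets, so every pipeline stage here is exercised against a
generator whose defaults emulate the published marginals of the five bundled
trial designs: per-study sample sizes and treatment lengths, a baseline WHO
risk mixture skewed to very-high risk, per-study distributions of days since
last drink (DSLD), and a dropout process producing roughly 14% non-completers.

Generative model, per participant:

* demographics and baseline covariates are drawn from configured marginals,
  as *raw* instrument categories so the harmonization recodes are exercised;
* a baseline WHO risk stratum is assigned from the configured mixture and a
  target mean daily grams value is drawn uniformly inside that stratum's
  sex-specific gram band — pre-randomization drinking is a two-state
  (drink/abstain) first-order Markov chain with lognormal grams on drinking
  days, rescaled so the 28-day baseline window mean hits the target exactly
  (the derived baseline level therefore equals the assigned stratum);
* DSLD is induced by forcing the terminal pre-randomization run: the last
  ``dsld`` days before day 0 are abstinent and the day before the run drinks;
* treatment-period outcomes follow a logistic "sustained response" law: with
  probability ``expit(intercept + b*covariates)`` the participant responds —
  fully abstinent and completing treatment — otherwise drinking continues
  with a drawn reduction multiplier and a geometric (constant daily hazard)
  dropout day after which all days are missing.

Because a response implies total abstinence and a non-response precludes it
(up to a negligible chance of spontaneous 100+-day abstinence), the derived
total-abstinence endpoint follows the configured logistic model exactly; the
other endpoints are correlated consequences of the same latent response.

Randomness uses one global seed with per-participant substreams derived by a
(study, participant) counter, so removing a participant never shifts others.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .tlfb import RiskLevel, Sex, StudyConfig, TlfbCalendar, study_presets

__all__ = [
    "StudySim",
    "OutcomeModel",
    "Demographics",
    "DrinkingProcess",
    "SimulationConfig",
    "SimulatedTrial",
    "simulate_participant",
    "simulate_trial",
    "simulate_outcome_table",
    "scale_sample_sizes",
]


class StudySim(BaseModel):
    """Per-study sample size, length, allocation and DSLD distribution."""

    n: int = Field(gt=0)
    treatment_weeks: int = Field(ge=1)
    placebo_frac: float = Field(ge=0.0, le=1.0)
    dsld_mean: float = Field(ge=0.0)
    dsld_sd: float = Field(ge=0.0)


class OutcomeModel(BaseModel):
    """Logistic coefficients for the latent sustained-response propensity.

    ``dsld_step_threshold``/``dsld_step_size`` optionally add a step effect at
    a known DSLD threshold, used to test that the ROC machinery recovers the
    threshold midpoint.
    """

    intercept: float = -3.9
    dsld: float = 0.15
    age: float = 0.02
    rdl_high: float = 0.0
    rdl_very_high: float = 0.0
    placebo: float = -0.1
    study_offsets: dict[str, float] = Field(default_factory=dict)
    dsld_step_threshold: float | None = None
    dsld_step_size: float = 0.0

    def linear_predictor(
        self,
        study: np.ndarray,
        placebo: np.ndarray,
        rdl: np.ndarray,
        dsld: np.ndarray,
        age: np.ndarray,
    ) -> np.ndarray:
        eta = (
            self.intercept
            + self.dsld * np.asarray(dsld, float)
            + self.age * np.asarray(age, float)
            + self.placebo * np.asarray(placebo, float)
            + self.rdl_high * (np.asarray(rdl) == "high")
            + self.rdl_very_high * (np.asarray(rdl) == "very_high")
            + np.array([self.study_offsets.get(s, 0.0) for s in np.atleast_1d(study)])
        )
        if self.dsld_step_threshold is not None:
            eta = eta + self.dsld_step_size * (np.asarray(dsld, float) > self.dsld_step_threshold)
        return eta


class Demographics(BaseModel):
    """Marginal frequencies for the harmonized baseline covariates."""

    male_frac: float = 0.704
    age_mean: float = 45.9
    age_sd: float = 10.9
    married_frac: float = 0.471
    education_12plus_frac: float = 0.946
    employed_frac: float = 0.723
    income_60k_frac: float = 0.463
    white_frac: float = 0.749
    black_frac: float = 0.162
    hispanic_frac: float = 0.078
    smoker_10plus_frac: float = 0.262
    thc_positive_frac: float = 0.117


class DrinkingProcess(BaseModel):
    """Two-state Markov drinking process parameters, per baseline stratum."""

    #: Stationary drinking-day probability by baseline risk stratum.
    drink_prob: dict[str, float] = Field(
        default_factory=lambda: {"medium": 0.55, "high": 0.70, "very_high": 0.85}
    )
    #: Day-to-day persistence: P(drink|drank) = pi + rho*(1-pi).
    persistence: float = Field(default=0.5, ge=0.0, lt=1.0)
    #: Lognormal sigma for grams on drinking days.
    grams_sigma: float = Field(default=0.5, ge=0.0)
    #: Sex-specific (low, high) gram/day bands per stratum for the baseline
    #: window target mean.
    gram_bands: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: {
            "medium": {"male": (40.0, 60.0), "female": (20.0, 40.0)},
            "high": {"male": (60.0, 100.0), "female": (40.0, 60.0)},
            "very_high": {"male": (100.0, 160.0), "female": (60.0, 120.0)},
        }
    )
    #: Optional override of the non-responder post-randomization stationary
    #: drinking probability (None: baseline probability times the reduction).
    post_randomization_drink_prob: float | None = None

    @model_validator(mode="after")
    def _check_probs(self) -> "DrinkingProcess":
        for level, p in self.drink_prob.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"drink_prob[{level!r}] must lie in (0, 1], got {p}")
        return self


def _default_studies() -> dict[str, StudySim]:
    presets = study_presets()
    marginals = {
        "combine": dict(n=594, placebo_frac=0.254, dsld_mean=7.8, dsld_sd=5.2),
        "horizant": dict(n=346, placebo_frac=0.500, dsld_mean=3.5, dsld_sd=1.5),
        "levetiracetam": dict(n=130, placebo_frac=0.508, dsld_mean=0.6, dsld_sd=1.8),
        "quetiapine": dict(n=221, placebo_frac=0.525, dsld_mean=1.8, dsld_sd=4.2),
        "varenicline": dict(n=200, placebo_frac=0.505, dsld_mean=0.2, dsld_sd=0.6),
    }
    return {
        name: StudySim(treatment_weeks=presets[name].treatment_weeks, **vals)
        for name, vals in marginals.items()
    }


class SimulationConfig(BaseModel):
    """All generative parameters, serializable with known truth."""

    seed: int = 0
    screening_gap_days: int = Field(default=14, ge=1)
    grams_per_drink: float = Field(default=14.0, gt=0)
    studies: dict[str, StudySim] = Field(default_factory=_default_studies)
    rdl_mixture: dict[str, float] = Field(
        default_factory=lambda: {"medium": 0.044, "high": 0.180, "very_high": 0.776}
    )
    drinking: DrinkingProcess = Field(default_factory=DrinkingProcess)
    outcome_model: OutcomeModel = Field(default_factory=OutcomeModel)
    demographics: Demographics = Field(default_factory=Demographics)
    #: Non-responder multiplicative reduction of drinking intensity, drawn
    #: uniformly from this range.
    reduction_range: tuple[float, float] = (0.15, 1.0)
    #: Constant daily dropout hazard for non-responders.
    dropout_hazard: float = Field(default=0.0015, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_mixture(self) -> "SimulationConfig":
        total = sum(self.rdl_mixture.values())
        if not np.isclose(total, 1.0, atol=1e-3):
            raise ValueError(f"rdl_mixture must sum to 1, got {total}")
        if set(self.rdl_mixture) != {"medium", "high", "very_high"}:
            raise ValueError("rdl_mixture must cover medium/high/very_high exactly")
        self.rdl_mixture = {k: v / total for k, v in self.rdl_mixture.items()}
        return self


def scale_sample_sizes(cfg: SimulationConfig, total_n: int) -> SimulationConfig:
    """Copy of the config with study sizes scaled proportionally to ``total_n``."""
    out = cfg.model_copy(deep=True)
    current = sum(s.n for s in cfg.studies.values())
    names = list(cfg.studies)
    sizes = {name: max(1, round(cfg.studies[name].n * total_n / current)) for name in names}
    sizes[names[0]] += total_n - sum(sizes.values())  # absorb rounding in the largest study
    for name in names:
        out.studies[name].n = sizes[name]
    return out


# ---------------------------------------------------------------------------
# study-level simulation kernel
# ---------------------------------------------------------------------------

_MARITAL_TRUE = ["married", "married", "married", "married", "cohabitating"]
_MARITAL_FALSE = ["separated", "divorced", "widowed", "never_married"]
_EMPLOY_TRUE = ["full_time", "full_time", "part_time"]
_EMPLOY_FALSE = ["unemployed", "disabled", "retired", "student", "military"]
_INCOME_TRUE = ["60_80k", "80_100k", "gt_100k"]
_INCOME_FALSE = ["lt_20k", "20_40k", "40_60k"]
_RACE_OTHER = ["mixed", "native_american", "asian_pacific", "other"]


def _draw_cat(rng, p_true, true_opts, false_opts):
    opts = true_opts if rng.random() < p_true else false_opts
    return opts[rng.integers(len(opts))]


@dataclass
class _StudyArrays:
    """Simulated day-level matrices for one study (rows = participants)."""

    study: str
    ids: list[str]
    start_day: int
    screening_day: int
    treatment_end_day: int
    drinks: np.ndarray  # (n, n_days), NaN where missing
    missing: np.ndarray  # (n, n_days) bool
    baseline_rows: list[dict]
    truth_rows: list[dict]


def _simulate_study(
    cfg: SimulationConfig, study: str, rngs: list[np.random.Generator], id_prefix: str | None = None
) -> _StudyArrays:
    st = cfg.studies[study]
    demo = cfg.demographics
    dp = cfg.drinking
    gap = cfg.screening_gap_days
    screening_day = -gap
    t_end = 7 * st.treatment_weeks
    start = screening_day - 28
    days = np.arange(start, t_end + 1)
    nd = days.size
    idx0 = -start
    n = len(rngs)
    prefix = id_prefix if id_prefix is not None else study

    mix_levels = ["medium", "high", "very_high"]
    mix_cum = np.cumsum([cfg.rdl_mixture[l] for l in mix_levels])

    male = np.empty(n, dtype=bool)
    age = np.empty(n)
    placebo = np.empty(n, dtype=bool)
    stratum = np.empty(n, dtype=object)
    target = np.empty(n)
    dsld = np.empty(n, dtype=int)
    resp_u = np.empty(n)
    reduction = np.empty(n)
    dropout = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    U = np.empty((n, nd))
    Z = np.empty((n, nd))
    baseline_rows: list[dict] = []

    max_dsld = gap + 27  # leaves at least one baseline-window day free to drink

    for i, rng in enumerate(rngs):
        male[i] = rng.random() < demo.male_frac
        age[i] = float(np.clip(rng.normal(demo.age_mean, demo.age_sd), 18.0, 85.0))
        marital = _draw_cat(rng, demo.married_frac, _MARITAL_TRUE, _MARITAL_FALSE)
        employment = _draw_cat(rng, demo.employed_frac, _EMPLOY_TRUE, _EMPLOY_FALSE)
        income = _draw_cat(rng, demo.income_60k_frac, _INCOME_TRUE, _INCOME_FALSE)
        educ_years = int(
            rng.integers(12, 21) if rng.random() < demo.education_12plus_frac else rng.integers(8, 12)
        )
        cigs = int(
            rng.integers(10, 41) if rng.random() < demo.smoker_10plus_frac else rng.integers(0, 10)
        )
        thc = "positive" if rng.random() < demo.thc_positive_frac else "negative"
        u_race = rng.random()
        if u_race < demo.white_frac:
            race = "white"
        elif u_race < demo.white_frac + demo.black_frac:
            race = "black"
        else:
            race = _RACE_OTHER[rng.integers(len(_RACE_OTHER))]
        hispanic = int(rng.random() < demo.hispanic_frac)
        placebo[i] = rng.random() < st.placebo_frac
        stratum[i] = mix_levels[int(np.searchsorted(mix_cum, rng.random(), side="right"))]
        lo, hi = dp.gram_bands[stratum[i]]["male" if male[i] else "female"]
        target[i] = rng.uniform(lo + 1.0, hi - 1.0)
        dsld[i] = int(np.clip(round(rng.normal(st.dsld_mean, st.dsld_sd)), 0, max_dsld))
        resp_u[i] = rng.random()
        reduction[i] = rng.uniform(*cfg.reduction_range)
        if cfg.dropout_hazard > 0:
            dropout[i] = int(rng.geometric(cfg.dropout_hazard))
        U[i] = rng.random(nd)
        Z[i] = rng.standard_normal(nd)
        baseline_rows.append(
            {
                "participant_id": f"{prefix}_{i + 1:05d}",
                "study": study,
                "arm": "placebo" if placebo[i] else "active",
                "sex": "male" if male[i] else "female",
                "age": round(age[i], 1),
                "marital": marital,
                "employment": employment,
                "income_category": income,
                "education_years": educ_years,
                "cigarettes_per_day": cigs,
                "thc_screen": thc,
                "race": race,
                "hispanic": hispanic,
            }
        )

    eta = cfg.outcome_model.linear_predictor(
        np.full(n, study, dtype=object), placebo, stratum, dsld, age
    )
    p_response = expit(eta)
    responder = resp_u < p_response

    # Markov drinking indicators.
    pi = np.array([dp.drink_prob[s] for s in stratum])
    rho = dp.persistence
    pre_p11 = pi + rho * (1.0 - pi)
    pre_p01 = pi * (1.0 - rho)
    post_pi = np.where(responder, 0.0, np.clip(pi * reduction, 0.0, 1.0))
    if dp.post_randomization_drink_prob is not None:
        post_pi = np.where(responder, 0.0, dp.post_randomization_drink_prob)
    post_p11 = post_pi + rho * (1.0 - post_pi)
    post_p01 = post_pi * (1.0 - rho)

    state = np.empty((n, nd), dtype=bool)
    state[:, 0] = U[:, 0] < pi
    for t in range(1, nd):
        if days[t] < 0:
            p = np.where(state[:, t - 1], pre_p11, pre_p01)
        else:
            p = np.where(state[:, t - 1], post_p11, post_p01)
        state[:, t] = U[:, t] < p
    # a zero stationary drinking probability is absorbing: no carry-over of a
    # pre-randomization run into treatment (responders always have post_pi 0)
    state[post_pi == 0.0, idx0:] = False

    # Force the DSLD terminal run: dsld abstinent days before day 0, preceded
    # by a drinking day.
    dd = dsld[:, None]
    day_row = days[None, :]
    state &= ~((day_row >= -dd) & (day_row <= -1))
    state |= day_row == -(dd + 1)  # always a pre-randomization day

    # Guarantee a drinking day in the baseline window, then rescale the window
    # so its 28-day mean equals the stratum target exactly.
    none_in_win = ~state[:, :28].any(axis=1)
    state[none_in_win, 0] = True

    base_median = target / pi
    post_median = base_median * reduction
    med = np.where(day_row >= 0, post_median[:, None], base_median[:, None])
    grams = med * np.exp(dp.grams_sigma * Z - dp.grams_sigma**2 / 2.0)
    grams[~state] = 0.0
    win_sum = grams[:, :28].sum(axis=1)
    grams[:, :28] *= (target * 28.0 / win_sum)[:, None]

    drinks = np.round(grams / cfg.grams_per_drink, 4)

    miss = (~responder)[:, None] & (day_row >= dropout[:, None])
    drinks = np.where(miss, np.nan, drinks)

    ids = [row["participant_id"] for row in baseline_rows]
    truth_rows = [
        {
            "participant_id": ids[i],
            "study": study,
            "assigned_rdl": stratum[i],
            "target_grams": target[i],
            "dsld": int(dsld[i]),
            "responder": bool(responder[i]),
            "p_response": float(p_response[i]),
            "reduction": float(reduction[i]),
            "dropout_day": (
                int(dropout[i]) if (not responder[i] and dropout[i] <= t_end) else np.nan
            ),
        }
        for i in range(n)
    ]
    return _StudyArrays(
        study=study,
        ids=ids,
        start_day=start,
        screening_day=screening_day,
        treatment_end_day=t_end,
        drinks=drinks,
        missing=miss,
        baseline_rows=baseline_rows,
        truth_rows=truth_rows,
    )


@dataclass
class SimulatedTrial:
    """A simulated multi-study trial: raw tables plus per-day matrices."""

    baseline: pd.DataFrame
    tlfb: pd.DataFrame
    truth: pd.DataFrame
    params: dict
    arrays: dict[str, _StudyArrays] = dc_field(default_factory=dict, repr=False)

    def calendars(self) -> Iterator[TlfbCalendar]:
        """Yield per-participant calendars without a CSV round trip."""
        for sa in self.arrays.values():
            for i, pid in enumerate(sa.ids):
                yield TlfbCalendar(
                    pid,
                    start_day=sa.start_day,
                    drinks=sa.drinks[i],
                    missing=sa.missing[i],
                    screening_day=sa.screening_day,
                    treatment_end_day=sa.treatment_end_day,
                )

    def sex_by_id(self) -> dict[str, str]:
        return dict(zip(self.baseline["participant_id"], self.baseline["sex"]))

    def study_configs(self) -> dict[str, StudyConfig]:
        """Per-participant StudyConfig mapping (grams-per-drink aware)."""
        per_study = {
            name: StudyConfig(
                study_name=name,
                treatment_weeks=self.params["studies"][name]["treatment_weeks"],
                grams_per_drink=self.params["grams_per_drink"],
            )
            for name in self.params["studies"]
        }
        return {
            pid: per_study[study]
            for pid, study in zip(self.baseline["participant_id"], self.baseline["study"])
        }


def _participant_rng(seed: int, study_index: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(study_index, i)))


def simulate_participant(
    cfg: SimulationConfig, study: str, rng: np.random.Generator
) -> tuple[dict, TlfbCalendar]:
    """Simulate a single participant: (raw baseline row, TLFB calendar)."""
    sa = _simulate_study(cfg, study, [rng])
    cal = TlfbCalendar(
        sa.ids[0],
        start_day=sa.start_day,
        drinks=sa.drinks[0],
        missing=sa.missing[0],
        screening_day=sa.screening_day,
        treatment_end_day=sa.treatment_end_day,
    )
    return sa.baseline_rows[0], cal


def simulate_trial(
    cfg: SimulationConfig, seed: int | None = None, *, build_tlfb: bool = True
) -> SimulatedTrial:
    """Simulate the full multi-study trial described by ``cfg``.

    Fully reproducible from ``(cfg, seed)``; ``seed`` defaults to ``cfg.seed``.
    ``build_tlfb=False`` skips assembling the long-format daily table (the
    day-level matrices and :meth:`SimulatedTrial.calendars` remain available),
    which speeds up large replication studies.
    """
    seed = cfg.seed if seed is None else int(seed)
    arrays: dict[str, _StudyArrays] = {}
    baseline_rows: list[dict] = []
    truth_rows: list[dict] = []
    tlfb_parts: list[pd.DataFrame] = []
    for si, study in enumerate(cfg.studies):
        rngs = [_participant_rng(seed, si, i) for i in range(cfg.studies[study].n)]
        sa = _simulate_study(cfg, study, rngs)
        arrays[study] = sa
        baseline_rows.extend(sa.baseline_rows)
        truth_rows.extend(sa.truth_rows)
        if build_tlfb:
            n, nd = sa.drinks.shape
            day_vec = np.arange(sa.start_day, sa.treatment_end_day + 1)
            tlfb_parts.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(sa.ids, nd),
                        "day": np.tile(day_vec, n),
                        "drinks": sa.drinks.ravel(),
                        "missing": sa.missing.ravel().astype(int),
                    }
                )
            )
    params = cfg.model_dump()
    params["effective_seed"] = seed
    return SimulatedTrial(
        baseline=pd.DataFrame(baseline_rows),
        tlfb=pd.concat(tlfb_parts, ignore_index=True) if build_tlfb else pd.DataFrame(),
        truth=pd.DataFrame(truth_rows),
        params=params,
        arrays=arrays,
    )


def simulate_outcome_table(
    cfg: SimulationConfig,
    n: int,
    rng: np.random.Generator,
    outcome: str = "abstinent",
) -> pd.DataFrame:
    """Draw a harmonized analysis table directly from the logistic truth.

    Covariates are sampled from the configured marginals and the outcome is a
    Bernoulli draw from the configured response model — no calendars involved.
    This is the fast generator for coefficient-coverage and cutoff-recovery
    simulations where only the (covariates, outcome) law matters.
    """
    demo = cfg.demographics
    names = list(cfg.studies)
    sizes = np.array([cfg.studies[s].n for s in names], dtype=float)
    study = rng.choice(names, size=n, p=sizes / sizes.sum())
    dsld_mean = np.array([cfg.studies[s].dsld_mean for s in study])
    dsld_sd = np.array([cfg.studies[s].dsld_sd for s in study])
    dsld = np.clip(np.round(rng.normal(dsld_mean, dsld_sd)), 0, cfg.screening_gap_days + 27)
    placebo_frac = np.array([cfg.studies[s].placebo_frac for s in study])
    placebo = rng.random(n) < placebo_frac
    mix_levels = ["medium", "high", "very_high"]
    rdl = rng.choice(mix_levels, size=n, p=[cfg.rdl_mixture[l] for l in mix_levels])
    age = np.clip(rng.normal(demo.age_mean, demo.age_sd, size=n), 18.0, 85.0)
    male = rng.random(n) < demo.male_frac

    eta = cfg.outcome_model.linear_predictor(study, placebo, rdl, dsld, age)
    y = rng.random(n) < expit(eta)

    race_u = rng.random(n)
    table = pd.DataFrame(
        {
            "participant_id": [f"p{i:06d}" for i in range(n)],
            "study": study,
            "arm": np.where(placebo, "placebo", "active"),
            "sex": np.where(male, "male", "female"),
            "age": age,
            "married_cohab": rng.random(n) < demo.married_frac,
            "education_12plus": rng.random(n) < demo.education_12plus_frac,
            "employed": rng.random(n) < demo.employed_frac,
            "income_60k": rng.random(n) < demo.income_60k_frac,
            "race_white": race_u < demo.white_frac,
            "race_black": (race_u >= demo.white_frac) & (race_u < demo.white_frac + demo.black_frac),
            "race_hispanic": rng.random(n) < demo.hispanic_frac,
            "smoker_10plus": rng.random(n) < demo.smoker_10plus_frac,
            "thc_positive": rng.random(n) < demo.thc_positive_frac,
            "baseline_rdl": rdl,
            "dsld": dsld.astype(int),
            outcome: y.astype(int),
        }
    )
    return table
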