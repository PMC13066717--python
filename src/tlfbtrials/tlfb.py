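"""Daily drinking calendars and WHO risk drinking level classification.

Timeline follow-back (TLFB) interviews record the number of standard drinks a
participant reports for each calendar day.  This module holds the calendar data
model and the two measurement primitives every endpoint is built from:
extracting a fixed-length assessment window and classifying mean daily alcohol
consumption into a WHO risk drinking level (RDL).

Study-day coordinates are 0-based with the day of randomization/first dosing at
day 0.  Screening and the pre-screening month occupy negative days, so "prior
to randomization" is simply a scan over negative day indices; the treatment
period spans ``[0, treatment_end_day]``.

Missing days are first-class: a day a participant did not report is carried as
``missing=True`` with an undefined drinks value, and window extraction returns
such records for calendar gaps instead of shortening the window.  What to do
with a missing day (fail, impute, recode) is an endpoint-level policy and is
deliberately not decided here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "Sex",
    "RiskLevel",
    "RDL_CUTPOINTS_G",
    "DrinkingDay",
    "TlfbCalendar",
    "StudyConfig",
    "extract_window",
    "mean_daily_grams",
    "classify_rdl",
    "study_presets",
]

#: Grams of pure alcohol in one US standard drink.
STANDARD_DRINK_GRAMS = 14.0

#: Baseline/endpoint RDL assessment windows cover 28 consecutive days.
RDL_WINDOW_DAYS = 28


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class RiskLevel(enum.IntEnum):
    """WHO risk drinking level, totally ordered by consumption.

    The integer codes make risk-level shifts plain integer arithmetic:
    a "two or more level reduction" is ``baseline - endpoint >= 2``.
    """

    ABSTINENT = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3
    VERY_HIGH = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "RiskLevel":
        try:
            return cls[str(label).upper()]
        except KeyError:
            raise ValueError(f"unknown risk level label: {label!r}") from None


#: Sex-specific upper gram/day cutpoints for (LOW, MEDIUM, HIGH); anything above
#: the last cutpoint is VERY_HIGH.  Intervals are half-open on the left and
#: closed on the right, e.g. male MEDIUM = (40, 60] g/day.
RDL_CUTPOINTS_G: dict[Sex, tuple[float, float, float]] = {
    Sex.MALE: (40.0, 60.0, 100.0),
    Sex.FEMALE: (20.0, 40.0, 60.0),
}


@dataclass(frozen=True)
class DrinkingDay:
    """One day of a TLFB calendar.

    ``drinks`` is the self-reported standard-drink count and is undefined
    (``None``) whenever ``missing`` is true.
    """

    day: int
    drinks: float | None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            object.__setattr__(self, "drinks", None)
        else:
            if self.drinks is None or (
                isinstance(self.drinks, float) and math.isnan(self.drinks)
            ):
                raise ValueError(f"day {self.day}: observed day requires a drinks value")
            if self.drinks < 0:
                raise ValueError(f"day {self.day}: drinks must be non-negative, got {self.drinks}")


class TlfbCalendar:
    """One participant's ordered daily drinking record with study anchors.

    Internally the calendar is a dense pair of arrays over a contiguous span of
    study days; days never reported are stored as missing.  The span always
    covers at least the 28 days ending at ``screening_day`` and the treatment
    period ``[0, treatment_end_day]`` (the constructor pads with missing days
    if needed), so window extraction against either anchor is always defined.
    """

    __slots__ = ("participant_id", "start_day", "drinks", "missing", "screening_day", "treatment_end_day")

    def __init__(
        self,
        participant_id: str,
        *,
        start_day: int,
        drinks: np.ndarray,
        missing: np.ndarray,
        screening_day: int,
        treatment_end_day: int,
    ) -> None:
        if not screening_day < 0 < treatment_end_day:
            raise ValueError(
                f"participant {participant_id}: need screening_day < 0 < treatment_end_day, "
                f"got {screening_day}, {treatment_end_day}"
            )
        drinks = np.asarray(drinks, dtype=float)
        missing = np.asarray(missing, dtype=bool)
        if drinks.shape != missing.shape or drinks.ndim != 1:
            raise ValueError(f"participant {participant_id}: drinks/missing arrays must be 1-D and aligned")
        if np.any(drinks[~missing] < 0):
            raise ValueError(f"participant {participant_id}: negative drinks value in calendar")

        # Pad so the required assessment spans are always inside the calendar.
        lo = min(int(start_day), screening_day - RDL_WINDOW_DAYS)
        hi = max(int(start_day) + drinks.size - 1, treatment_end_day)
        if lo < start_day or hi >= start_day + drinks.size:
            full_drinks = np.full(hi - lo + 1, np.nan)
            full_missing = np.ones(hi - lo + 1, dtype=bool)
            off = start_day - lo
            full_drinks[off : off + drinks.size] = drinks
            full_missing[off : off + missing.size] = missing
            drinks, missing, start_day = full_drinks, full_missing, lo

        drinks = drinks.copy()
        drinks[missing] = np.nan
        self.participant_id = participant_id
        self.start_day = int(start_day)
        self.drinks = drinks
        self.missing = missing
        self.screening_day = int(screening_day)
        self.treatment_end_day = int(treatment_end_day)

    @classmethod
    def from_days(
        cls,
        participant_id: str,
        days: Iterable[DrinkingDay | tuple],
        *,
        screening_day: int,
        treatment_end_day: int,
    ) -> "TlfbCalendar":
        """Build a calendar from per-day records; internal gaps become missing days."""
        recs = [d if isinstance(d, DrinkingDay) else DrinkingDay(*d) for d in days]
        if not recs:
            raise ValueError(f"participant {participant_id}: empty calendar")
        idx = [r.day for r in recs]
        if len(set(idx)) != len(idx):
            raise ValueError(f"participant {participant_id}: duplicate day indices in calendar")
        recs.sort(key=lambda r: r.day)
        lo, hi = recs[0].day, recs[-1].day
        drinks = np.full(hi - lo + 1, np.nan)
        missing = np.ones(hi - lo + 1, dtype=bool)
        for r in recs:
            missing[r.day - lo] = r.missing
            if not r.missing:
                drinks[r.day - lo] = r.drinks
        return cls(
            participant_id,
            start_day=lo,
            drinks=drinks,
            missing=missing,
            screening_day=screening_day,
            treatment_end_day=treatment_end_day,
        )

    # -- introspection -----------------------------------------------------

    @property
    def end_day(self) -> int:
        return self.start_day + self.drinks.size - 1

    def __len__(self) -> int:
        return self.drinks.size

    @property
    def days(self) -> list[DrinkingDay]:
        """The calendar as an ordered sequence of per-day records."""
        return [
            DrinkingDay(self.start_day + i, None if m else float(d), bool(m))
            for i, (d, m) in enumerate(zip(self.drinks, self.missing))
        ]

    def day_slice(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """(drinks, missing) arrays for study days ``lo..hi`` inclusive.

        Days outside the stored span are returned as missing.  Fast path used
        by the endpoint derivations; drinks are NaN wherever missing is true.
        """
        n = hi - lo + 1
        if lo >= self.start_day and hi <= self.end_day:
            i = lo - self.start_day
            return self.drinks[i : i + n], self.missing[i : i + n]
        drinks = np.full(n, np.nan)
        missing = np.ones(n, dtype=bool)
        s, e = max(lo, self.start_day), min(hi, self.end_day)
        if s <= e:
            i = s - self.start_day
            drinks[s - lo : e - lo + 1] = self.drinks[i : i + e - s + 1]
            missing[s - lo : e - lo + 1] = self.missing[i : i + e - s + 1]
        return drinks, missing

    def to_frame(self):
        """Long-format view matching the on-disk TLFB CSV dialect."""
        import pandas as pd

        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "day": np.arange(self.start_day, self.end_day + 1),
                "drinks": self.drinks,
                "missing": self.missing.astype(int),
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TlfbCalendar({self.participant_id!r}, days {self.start_day}..{self.end_day}, "
            f"screening={self.screening_day}, treatment_end={self.treatment_end_day})"
        )


@dataclass(frozen=True)
class StudyConfig:
    """Per-trial design constants.

    ``treatment_weeks`` sets the treatment period ``[0, 7 * treatment_weeks]``;
    titration/taper weeks are carried as metadata only.  ``grams_per_drink``
    converts standard drinks to grams of pure alcohol (US convention 14 g).
    """

    study_name: str
    treatment_weeks: int
    titration_weeks: int = 0
    taper_weeks: int = 0
    grams_per_drink: float = STANDARD_DRINK_GRAMS

    def __post_init__(self) -> None:
        if self.grams_per_drink <= 0:
            raise ValueError("grams_per_drink must be positive")
        if self.treatment_weeks < 1:
            raise ValueError("treatment_weeks must be at least 1")

    @property
    def treatment_end_day(self) -> int:
        return 7 * self.treatment_weeks


def study_presets() -> dict[str, StudyConfig]:
    """The five bundled trial-design presets, keyed by study label."""
    text = resources.files("tlfbtrials.data").joinpath("study_presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: StudyConfig(study_name=name, **fields) for name, fields in raw.items()}


def extract_window(
    cal: TlfbCalendar,
    anchor: int,
    length: int,
    direction: Literal["before", "ending_at"],
) -> list[DrinkingDay]:
    """Extract a fixed-length daily window relative to an anchor day.

    ``direction="before"`` returns the ``length`` days strictly before the
    anchor (``[anchor-length, anchor-1]``), the convention for the baseline
    window anchored at screening.  ``direction="ending_at"`` includes the
    anchor as the last day (``[anchor-length+1, anchor]``), the convention for
    the endpoint window anchored at the final treatment day.  Days absent from
    the calendar are returned as missing records, so the result always has
    exactly ``length`` entries.
    """
    if length < 1:
        raise ValueError("window length must be at least 1")
    if direction not in ("before", "ending_at"):
        raise ValueError(f"unknown window direction: {direction!r}")
    if not (cal.start_day <= anchor <= cal.end_day):
        raise ValueError(
            f"participant {cal.participant_id}: anchor day {anchor} outside calendar span "
            f"[{cal.start_day}, {cal.end_day}]"
        )
    hi = anchor - 1 if direction == "before" else anchor
    lo = hi - length + 1
    drinks, missing = cal.day_slice(lo, hi)
    return [
        DrinkingDay(lo + i, None if m else float(d), bool(m))
        for i, (d, m) in enumerate(zip(drinks, missing))
    ]


def mean_daily_grams(
    window: Sequence[DrinkingDay], cfg: StudyConfig | float = STANDARD_DRINK_GRAMS
) -> float | None:
    """Mean grams of alcohol per day over a window, or None when undefined.

    Returns ``None`` (an undefined-flagged mean) if any window day is missing;
    whether that is an error, an imputation or a recode is the caller's policy.
    ``cfg`` may be a :class:`StudyConfig` or a bare grams-per-drink constant.
    """
    if len(window) == 0:
        raise ValueError("cannot average an empty window")
    gpd = cfg.grams_per_drink if isinstance(cfg, StudyConfig) else float(cfg)
    if any(d.missing for d in window):
        return None
    return float(np.mean([d.drinks for d in window])) * gpd


def classify_rdl(mean_grams: float, any_drinking_day: bool, sex: Sex | str) -> RiskLevel:
    """Classify mean daily grams of alcohol into a WHO risk drinking level.

    ABSTINENT requires that the window contained no drinking day at all; any
    drinking places the participant at LOW or above even if the mean rounds to
    zero.  Boundaries are closed on the right ("up to 40 g" is LOW), so e.g.
    exactly 40 g/day is LOW for males and MEDIUM for females.
    """
    mean_grams = float(mean_grams)
    if math.isnan(mean_grams) or mean_grams < 0:
        raise ValueError(f"mean_grams must be a non-negative number, got {mean_grams}")
    if not any_drinking_day:
        if mean_grams > 0:
            raise ValueError("window with no drinking day cannot have positive mean grams")
        return RiskLevel.ABSTINENT
    cuts = RDL_CUTPOINTS_G[Sex(sex)]
    return RiskLevel(1 + int(np.searchsorted(cuts, mean_grams, side="left")))
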