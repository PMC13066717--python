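"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use a different computational route from the
implementation (dict scans, interval lookup, dense threshold matrices) so
they stay independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tlfbtrials.tlfb import RiskLevel, Sex, StudyConfig, TlfbCalendar


def make_calendar(
    day_map: dict[int, float | None],
    *,
    screening_day: int = -7,
    treatment_end_day: int = 14,
    pid: str = "p1",
) -> TlfbCalendar:
    """Calendar from a {day: drinks} dict; None marks a missing day.

    Days not mentioned inside the span come out missing (the calendar pads).
    """
    days = [(d, None, True) if v is None else (d, float(v), False) for d, v in day_map.items()]
    return TlfbCalendar.from_days(
        pid, days, screening_day=screening_day, treatment_end_day=treatment_end_day
    )


def full_calendar(
    pre: float = 0.0,
    treat: float = 0.0,
    *,
    screening_day: int = -7,
    treatment_end_day: int = 14,
    pid: str = "p1",
) -> TlfbCalendar:
    """Fully observed calendar with constant pre- and treatment-period drinks."""
    start = screening_day - 28
    return make_calendar(
        {d: (pre if d < 0 else treat) for d in range(start, treatment_end_day + 1)},
        screening_day=screening_day,
        treatment_end_day=treatment_end_day,
        pid=pid,
    )


def random_calendar(rng: np.random.Generator, pid: str = "p") -> TlfbCalendar:
    """A random, gap-ridden calendar for property tests."""
    screening = -int(rng.integers(3, 21))
    t_end = int(rng.integers(14, 120))
    start = screening - 28
    n = t_end - start + 1
    drinks = (rng.poisson(2.0, n) * (rng.random(n) < 0.7)).astype(float)
    missing = rng.random(n) < 0.15
    drinks[missing] = np.nan
    return TlfbCalendar(
        pid,
        start_day=start,
        drinks=drinks,
        missing=missing,
        screening_day=screening,
        treatment_end_day=t_end,
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def rdl_oracle(mean_grams: float, any_drinking: bool, sex: Sex) -> RiskLevel:
    """Brute-force interval lookup over the WHO gram bands."""
    if not any_drinking:
        return RiskLevel.ABSTINENT
    bands = {
        Sex.MALE: [(0, 40, RiskLevel.LOW), (40, 60, RiskLevel.MEDIUM),
                   (60, 100, RiskLevel.HIGH), (100, np.inf, RiskLevel.VERY_HIGH)],
        Sex.FEMALE: [(0, 20, RiskLevel.LOW), (20, 40, RiskLevel.MEDIUM),
                     (40, 60, RiskLevel.HIGH), (60, np.inf, RiskLevel.VERY_HIGH)],
    }
    hits = [lvl for lo, hi, lvl in bands[sex] if lo < mean_grams <= hi or (mean_grams == 0 and lo == 0)]
    assert len(hits) == 1, f"bands must partition: {mean_grams} -> {hits}"
    return hits[0]


def dsld_oracle(cal: TlfbCalendar) -> int:
    """Backward scan over per-day records, stopping at drink or missing."""
    by_day = {rec.day: rec for rec in cal.days}
    count = 0
    day = -1
    while day in by_day:
        rec = by_day[day]
        if rec.missing or rec.drinks > 0:
            break
        count += 1
        day -= 1
    return count


def youden_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive Youden maximization via a dense threshold-by-sample matrix."""
    u = np.unique(x)
    thresholds = np.concatenate([[-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]])
    pred = x[None, :] > thresholds[:, None]
    sens = (pred & y[None, :]).sum(axis=1) / y.sum()
    spec = (~pred & ~y[None, :]).sum(axis=1) / (~y).sum()
    j = sens + spec - 1.0
    best = int(np.argmax(j >= j.max() - 1e-9))  # smallest threshold on ties
    return float(thresholds[best]), float(j[best])


def chi2_oracle(table_2x2: np.ndarray) -> float:
    """Closed-form Pearson chi-squared: sum (O - E)^2 / E."""
    obs = np.asarray(table_2x2, dtype=float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


@pytest.fixture
def cfg16() -> StudyConfig:
    return StudyConfig(study_name="toy", treatment_weeks=16)
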