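"""Per-participant drinking endpoints with worst-case missing-data handling.

Four binary outcomes are derived from each TLFB calendar:

* ``abstinent`` — no drinking day over the entire treatment period;
* ``no_heavy`` — no heavy drinking day (>= 5 standard drinks for males,
  >= 4 for females) over the entire treatment period;
* ``who2plus`` — endpoint WHO risk drinking level, measured over the final
  28 treatment days, at least two ordinal levels below the baseline level;
* ``completer`` — TLFB data reported for the final treatment day.

Abstinence and no-heavy use worst-case scenario imputation: any unreported
treatment day is treated as a return to (heavy) drinking, so both outcomes are
monotone under data deletion.  The WHO reduction endpoint recodes an
unobservable endpoint window (any missing day, under the default strict
policy) to "no change", i.e. failure.  Days since last drink (DSLD) is the run
of consecutive reported abstinent days immediately before randomization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .tlfb import (
    RDL_WINDOW_DAYS,
    RiskLevel,
    Sex,
    StudyConfig,
    TlfbCalendar,
    classify_rdl,
)

__all__ = [
    "HEAVY_DRINK_THRESHOLD",
    "EndpointRecord",
    "days_since_last_drink",
    "total_abstinence",
    "no_heavy_drinking",
    "baseline_rdl",
    "endpoint_rdl",
    "who2plus_reduction",
    "research_completer",
    "derive_endpoints",
    "derive_endpoint_table",
]

#: Standard-drink counts defining a heavy drinking day (NIAAA convention).
HEAVY_DRINK_THRESHOLD: dict[Sex, float] = {Sex.MALE: 5.0, Sex.FEMALE: 4.0}

WhoWindowPolicy = Literal["strict", "observed"]


@dataclass(frozen=True)
class EndpointRecord:
    """The four binary outcomes plus DSLD and RDLs for one participant."""

    participant_id: str
    abstinent: bool
    no_heavy: bool
    who2plus: bool
    completer: bool
    dsld: int
    baseline_rdl: RiskLevel
    endpoint_rdl: RiskLevel | None

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "abstinent": int(self.abstinent),
            "no_heavy": int(self.no_heavy),
            "who2plus": int(self.who2plus),
            "completer": int(self.completer),
            "dsld": self.dsld,
            "baseline_rdl": self.baseline_rdl.label,
            "endpoint_rdl": "" if self.endpoint_rdl is None else self.endpoint_rdl.label,
        }


def days_since_last_drink(cal: TlfbCalendar) -> int:
    """Consecutive reported abstinent days immediately prior to randomization.

    Scans backwards from day -1 and stops at the first drinking day or the
    first missing day; if the whole observed pre-randomization history is
    abstinent the count is simply its length (no extrapolation).  Day 0 itself
    is excluded.  Interim days between screening and randomization participate
    automatically because they are ordinary calendar days.
    """
    if cal.start_day > -1:
        return 0
    drinks, missing = cal.day_slice(cal.start_day, -1)
    stop = missing | (np.nan_to_num(drinks) > 0)
    stop_rev = stop[::-1]
    if not stop_rev.any():
        return int(stop_rev.size)
    return int(np.argmax(stop_rev))


def _treatment_slice(cal: TlfbCalendar) -> tuple[np.ndarray, np.ndarray]:
    return cal.day_slice(0, cal.treatment_end_day)


def total_abstinence(cal: TlfbCalendar) -> bool:
    """True iff every treatment day is reported and reports zero drinks.

    Worst-case scenario imputation: a missing day counts as drinking.
    """
    drinks, missing = _treatment_slice(cal)
    return bool(not missing.any() and not (drinks > 0).any())


def no_heavy_drinking(
    cal: TlfbCalendar,
    sex: Sex | str,
    threshold: Mapping[Sex, float] = HEAVY_DRINK_THRESHOLD,
) -> bool:
    """True iff no treatment day is missing or reaches the heavy-day threshold.

    Worst-case scenario imputation: a missing day counts as a heavy day.
    """
    drinks, missing = _treatment_slice(cal)
    if missing.any():
        return False
    return bool(not (drinks >= threshold[Sex(sex)]).any())


def _window_rdl(
    cal: TlfbCalendar,
    lo: int,
    hi: int,
    sex: Sex | str,
    cfg: StudyConfig,
    policy: WhoWindowPolicy,
) -> RiskLevel | None:
    drinks, missing = cal.day_slice(lo, hi)
    if policy == "strict":
        if missing.any():
            return None
        observed = drinks
    else:
        observed = drinks[~missing]
        if observed.size == 0:
            return None
    mean_grams = float(np.mean(observed)) * cfg.grams_per_drink
    return classify_rdl(mean_grams, bool((observed > 0).any()), sex)


def baseline_rdl(cal: TlfbCalendar, sex: Sex | str, cfg: StudyConfig) -> RiskLevel:
    """WHO risk level over the 28 days before screening.

    The pre-study TLFB is collected retrospectively at screening, so the
    window is averaged over its observed days; a fully unreported window is an
    error because every analysis requires a baseline level.
    """
    level = _window_rdl(
        cal, cal.screening_day - RDL_WINDOW_DAYS, cal.screening_day - 1, sex, cfg, "observed"
    )
    if level is None:
        raise ValueError(
            f"participant {cal.participant_id}: baseline window entirely unreported"
        )
    return level


def endpoint_rdl(
    cal: TlfbCalendar,
    sex: Sex | str,
    cfg: StudyConfig,
    policy: WhoWindowPolicy = "strict",
) -> RiskLevel | None:
    """WHO risk level over the last 28 treatment days, or None if unobservable.

    Under the default ``strict`` policy any missing day inside the window voids
    the measurement; ``observed`` instead averages over the reported days
    (returning None only when the whole window is missing).
    """
    end = cal.treatment_end_day
    return _window_rdl(cal, end - RDL_WINDOW_DAYS + 1, end, sex, cfg, policy)


def who2plus_reduction(baseline: RiskLevel, endpoint: RiskLevel | None) -> bool:
    """Two-or-more risk-level reduction; an undefined endpoint is "no change".

    A MEDIUM baseline participant can only succeed by reaching ABSTINENT —
    that falls out of the integer-shift rule, with no special case.
    """
    if baseline not in (RiskLevel.MEDIUM, RiskLevel.HIGH, RiskLevel.VERY_HIGH):
        raise ValueError(
            f"baseline risk level {baseline.label} should have been excluded upstream"
        )
    if endpoint is None:
        return False
    return int(baseline) - int(endpoint) >= 2


def research_completer(cal: TlfbCalendar) -> bool:
    """True iff TLFB data are present for the final treatment day."""
    drinks, missing = cal.day_slice(cal.treatment_end_day, cal.treatment_end_day)
    return bool(not missing[0])


def derive_endpoints(
    cal: TlfbCalendar,
    sex: Sex | str,
    baseline: RiskLevel,
    cfg: StudyConfig,
    *,
    heavy_threshold: Mapping[Sex, float] = HEAVY_DRINK_THRESHOLD,
    who_policy: WhoWindowPolicy = "strict",
) -> EndpointRecord:
    """Compose the five derivations into one participant-level record."""
    end_rdl = endpoint_rdl(cal, sex, cfg, who_policy)
    return EndpointRecord(
        participant_id=cal.participant_id,
        abstinent=total_abstinence(cal),
        no_heavy=no_heavy_drinking(cal, sex, heavy_threshold),
        who2plus=who2plus_reduction(baseline, end_rdl),
        completer=research_completer(cal),
        dsld=days_since_last_drink(cal),
        baseline_rdl=baseline,
        endpoint_rdl=end_rdl,
    )


def derive_endpoint_table(
    calendars: Iterable[TlfbCalendar],
    sex_by_id: Mapping[str, Sex | str],
    cfg_by_id: Mapping[str, StudyConfig] | StudyConfig,
    baseline_by_id: Mapping[str, RiskLevel] | None = None,
    *,
    who_policy: WhoWindowPolicy = "strict",
) -> pd.DataFrame:
    """Derive endpoint records for a whole trial as a DataFrame.

    ``cfg_by_id`` may be a single :class:`StudyConfig` (single-study input) or a
    per-participant mapping.  When ``baseline_by_id`` is omitted the baseline
    risk level is measured from each calendar's pre-screening window.
    """
    rows = []
    for cal in calendars:
        pid = cal.participant_id
        sex = sex_by_id[pid]
        cfg = cfg_by_id if isinstance(cfg_by_id, StudyConfig) else cfg_by_id[pid]
        base = baseline_by_id[pid] if baseline_by_id is not None else baseline_rdl(cal, sex, cfg)
        rows.append(derive_endpoints(cal, sex, base, cfg, who_policy=who_policy).to_dict())
    return pd.DataFrame(rows)
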