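"""Endpoint derivations: DSLD, abstinence, no-heavy, WHO reduction, completion."""

import numpy as np
import pytest

from conftest import dsld_oracle, full_calendar, make_calendar, random_calendar
from tlfbtrials.endpoints import (
    days_since_last_drink,
    derive_endpoints,
    endpoint_rdl,
    no_heavy_drinking,
    research_completer,
    total_abstinence,
    who2plus_reduction,
)
from tlfbtrials.tlfb import RiskLevel, Sex, StudyConfig


def _with(base, overrides):
    out = dict(base)
    out.update(overrides)
    return out


BASE = {d: 2.0 for d in range(-35, 15)}  # screening -7, treatment end 14


class TestDaysSinceLastDrink:
    def test_run_ends_at_drinking_day(self):
        cal = make_calendar(_with(BASE, {d: 0.0 for d in range(-5, 0)} | {-6: 4.0}))
        assert days_since_last_drink(cal) == 5

    def test_drink_on_eve_of_randomization(self):
        cal = make_calendar(_with(BASE, {-1: 2.0}))
        assert days_since_last_drink(cal) == 0

    def test_missing_day_terminates_run(self):
        cal = make_calendar(_with(BASE, {-1: 0.0, -2: 0.0, -3: 0.0, -4: None}))
        assert days_since_last_drink(cal) == 3

    def test_fully_abstinent_history_capped_at_observed_length(self):
        cal = full_calendar(pre=0.0, treat=1.0)
        assert days_since_last_drink(cal) == 35  # 28-day window + 7-day gap

    def test_matches_backward_scan_oracle_on_random_calendars(self):
        rng = np.random.default_rng(42)
        for i in range(1000):
            cal = random_calendar(rng, pid=f"r{i}")
            assert days_since_last_drink(cal) == dsld_oracle(cal), cal.participant_id


class TestTotalAbstinence:
    def test_all_observed_zero(self):
        assert total_abstinence(full_calendar(pre=3.0, treat=0.0)) is True

    def test_missing_day_is_a_return_to_drinking(self):
        cal = make_calendar(_with({d: 0.0 for d in range(-35, 15)}, {7: None}))
        assert total_abstinence(cal) is False

    def test_single_drink_breaks_abstinence(self):
        cal = make_calendar(_with({d: 0.0 for d in range(-35, 15)}, {7: 1.0}))
        assert total_abstinence(cal) is False


class TestNoHeavyDrinking:
    def test_sex_specific_thresholds(self):
        four = full_calendar(pre=2.0, treat=4.0)
        assert no_heavy_drinking(four, Sex.MALE) is True  # male heavy day starts at 5
        assert no_heavy_drinking(four, Sex.FEMALE) is False  # female at 4
        five = full_calendar(pre=2.0, treat=5.0)
        assert no_heavy_drinking(five, Sex.MALE) is False

    def test_missing_day_is_a_heavy_day(self):
        cal = make_calendar(_with({d: 0.0 for d in range(-35, 15)}, {7: None}))
        assert no_heavy_drinking(cal, Sex.MALE) is False


class TestEndpointRdl:
    def test_mean_grams_classified_on_final_window(self, cfg16):
        # 30 g/day with drinking days -> LOW for a male
        cal = full_calendar(pre=3.0, treat=30.0 / 14.0, treatment_end_day=112)
        assert endpoint_rdl(cal, Sex.MALE, cfg16) == RiskLevel.LOW

    def test_all_zero_window_is_abstinent(self, cfg16):
        cal = full_calendar(pre=3.0, treat=0.0, treatment_end_day=112)
        assert endpoint_rdl(cal, Sex.MALE, cfg16) == RiskLevel.ABSTINENT

    def test_dropout_voids_window(self, cfg16):
        days = {d: 2.0 for d in range(-35, 57)}  # dropout at week 8 of 16
        cal = make_calendar(days, treatment_end_day=112)
        assert endpoint_rdl(cal, Sex.MALE, cfg16) is None

    def test_observed_policy_uses_reported_days(self, cfg16):
        days = {d: 2.0 for d in range(-35, 113) if d != 100}
        cal = make_calendar(days, treatment_end_day=112)
        assert endpoint_rdl(cal, Sex.MALE, cfg16) is None
        assert endpoint_rdl(cal, Sex.MALE, cfg16, policy="observed") == RiskLevel.LOW


class TestWho2Plus:
    @pytest.mark.parametrize(
        "baseline,endpoint,expected",
        [
            (RiskLevel.VERY_HIGH, RiskLevel.MEDIUM, True),
            (RiskLevel.VERY_HIGH, RiskLevel.HIGH, False),
            (RiskLevel.MEDIUM, RiskLevel.LOW, False),
            (RiskLevel.MEDIUM, RiskLevel.ABSTINENT, True),
            (RiskLevel.HIGH, None, False),  # missing endpoint recoded to "no change"
        ],
    )
    def test_two_level_shift_rule(self, baseline, endpoint, expected):
        assert who2plus_reduction(baseline, endpoint) is expected

    def test_ineligible_baseline_errors(self):
        with pytest.raises(ValueError, match="excluded upstream"):
            who2plus_reduction(RiskLevel.LOW, RiskLevel.ABSTINENT)


class TestResearchCompleter:
    def test_completion_is_not_abstinence(self):
        assert research_completer(full_calendar(treat=6.0)) is True

    def test_final_day_missing(self):
        cal = make_calendar({d: 1.0 for d in range(-35, 14)}, treatment_end_day=14)
        assert research_completer(cal) is False


class TestDeriveEndpoints:
    def test_fully_abstinent_completer(self, cfg16):
        cal = full_calendar(pre=9.0, treat=0.0, treatment_end_day=112)
        rec = derive_endpoints(cal, Sex.MALE, RiskLevel.VERY_HIGH, cfg16)
        assert (rec.abstinent, rec.no_heavy, rec.who2plus, rec.completer) == (
            True,
            True,
            True,
            True,
        )
        assert rec.endpoint_rdl == RiskLevel.ABSTINENT

    def test_week8_dropout_fails_everything(self, cfg16):
        days = {d: 2.0 for d in range(-35, 57)}
        cal = make_calendar(days, treatment_end_day=112)
        rec = derive_endpoints(cal, Sex.MALE, RiskLevel.VERY_HIGH, cfg16)
        assert (rec.abstinent, rec.no_heavy, rec.who2plus, rec.completer) == (
            False,
            False,
            False,
            False,
        )

    def test_heavy_drinking_completer(self, cfg16):
        cal = full_calendar(pre=9.0, treat=9.0, treatment_end_day=112)
        rec = derive_endpoints(cal, Sex.MALE, RiskLevel.VERY_HIGH, cfg16)
        assert (rec.abstinent, rec.no_heavy, rec.who2plus, rec.completer) == (
            False,
            False,
            False,
            True,
        )


class TestEndpointInvariants:
    """Logical structure that must hold for every calendar."""

    def _records(self, n=300, seed=11):
        rng = np.random.default_rng(seed)
        cfg = StudyConfig(study_name="toy", treatment_weeks=16)
        for i in range(n):
            # windows come from the calendar's own anchors; cfg only supplies
            # the grams-per-drink constant
            cal = random_calendar(rng, pid=f"i{i}")
            yield cal, derive_endpoints(cal, Sex.MALE, RiskLevel.VERY_HIGH, cfg)

    def test_abstinent_implies_no_heavy_implies_observed_window(self):
        for cal, rec in self._records():
            if rec.abstinent:
                assert rec.no_heavy
            if rec.no_heavy:
                _, missing = cal.day_slice(0, cal.treatment_end_day)
                assert not missing.any()

    def test_abstinent_implies_who2plus_and_completion(self):
        for cal, rec in self._records():
            if rec.abstinent:
                assert rec.endpoint_rdl == RiskLevel.ABSTINENT
                assert rec.who2plus
                assert rec.completer

    def test_noncompleter_fails_all_drinking_outcomes(self):
        for cal, rec in self._records():
            if not rec.completer:
                assert not rec.abstinent and not rec.no_heavy and not rec.who2plus

    def test_deleting_an_observed_day_never_flips_outcomes_to_success(self):
        rng = np.random.default_rng(7)
        for i in range(200):
            cal = random_calendar(rng, pid=f"d{i}")
            before = (total_abstinence(cal), no_heavy_drinking(cal, Sex.MALE))
            observed = np.flatnonzero(~cal.missing)
            if observed.size == 0:
                continue
            j = int(rng.choice(observed))
            cal.missing[j] = True
            cal.drinks[j] = np.nan
            after = (total_abstinence(cal), no_heavy_drinking(cal, Sex.MALE))
            assert after[0] <= before[0] and after[1] <= before[1]
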