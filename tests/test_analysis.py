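"""Logistic models, Bonferroni gating, ROC/Youden and contingency tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import chi2_oracle, youden_oracle
from tlfbtrials.analysis import (
    bonferroni_threshold,
    cutoff_table,
    fit_outcome_model,
    group_compare,
    roc_youden,
    tabulate_outcomes,
)
from tlfbtrials.pipeline import harmonize_tables
from tlfbtrials.simulate import SimulationConfig, scale_sample_sizes, simulate_trial
from tlfbtrials.endpoints import derive_endpoint_table


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.01, 5, 0.002)]
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_exact_inverse(self):
        for alpha, m in [(0.05, 4), (0.05, 1), (0.01, 5), (0.5, 2)]:
            assert bonferroni_threshold(alpha, m) * m == alpha

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 4)


class TestLogisticModel:
    def test_intercept_only_balanced_outcome(self):
        df = pd.DataFrame({"y": [0, 1] * 200, "arm": "active"})
        fit = fit_outcome_model(df, "y", predictors=[])
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-6)

    def test_one_class_outcome_errors(self):
        df = pd.DataFrame({"y": [1] * 50, "arm": "active"})
        with pytest.raises(ValueError, match="both classes"):
            fit_outcome_model(df, "y", predictors=[])

    def test_dsld_coefficient_recovered_from_synthetic_trial(self):
        # full pipeline on one n=5000 trial with a configured DSLD log-odds of 0.15
        cfg = scale_sample_sizes(SimulationConfig(), 5000)
        assert cfg.outcome_model.dsld == 0.15
        sim = simulate_trial(cfg, seed=20, build_tlfb=False)
        ep = derive_endpoint_table(sim.calendars(), sim.sex_by_id(), sim.study_configs())
        table, _ = harmonize_tables(sim.baseline, ep)
        fit = fit_outcome_model(table, "abstinent")
        assert fit.converged
        assert fit.params["dsld"] == pytest.approx(0.15, abs=0.05)
        # reference coding as in the merged analysis
        assert fit.reference == {"study": "combine", "baseline_rdl": "medium"}
        assert {"study", "baseline_rdl"} <= set(fit.block_pvalues)

    def test_placebo_only_subset_drops_arm_predictor(self):
        cfg = scale_sample_sizes(SimulationConfig(), 1500)
        sim = simulate_trial(cfg, seed=21, build_tlfb=False)
        ep = derive_endpoint_table(sim.calendars(), sim.sex_by_id(), sim.study_configs())
        table, _ = harmonize_tables(sim.baseline, ep)
        fit = fit_outcome_model(table, "who2plus", subset="placebo_only")
        assert "placebo" not in fit.params.index
        assert fit.n_used == (table["arm"] == "placebo").sum()


class TestRocYouden:
    def test_perfect_separation(self):
        x = np.array([0, 1, 2, 3, 10, 11, 12, 13], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        roc = roc_youden(x, y)
        assert roc.optimal_youden == pytest.approx(1.0)
        assert roc.optimal_cutoff == pytest.approx(6.5)
        assert roc.auc == pytest.approx(1.0)

    def test_uninformative_predictor_auc_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        y = rng.random(4000) < 0.5
        assert roc_youden(x, y).auc == pytest.approx(0.5, abs=0.03)

    def test_integer_predictor_gives_half_integer_cutoff(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 15, size=500).astype(float)
        y = rng.random(500) < 1 / (1 + np.exp(-(x - 4) * 0.8))
        cut = roc_youden(x, y).optimal_cutoff
        assert cut % 1 == pytest.approx(0.5)

    def test_tie_broken_toward_smallest_threshold(self):
        # symmetric case: J identical at 1.5 and 2.5; smallest wins
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 1], dtype=bool)
        roc = roc_youden(x, y)
        j = roc.youden
        assert j.max() == pytest.approx(0.5)
        assert roc.optimal_cutoff == pytest.approx(1.5)

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(8, 200))
            x = np.round(rng.normal(size=n) * rng.integers(1, 5), 1)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            roc = roc_youden(x, y)
            t_star, j_star = youden_oracle(x, y)
            assert roc.optimal_cutoff == pytest.approx(t_star)
            assert roc.optimal_youden == pytest.approx(j_star)

    def test_auc_equals_trapezoidal_integration(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=600) + rng.random(600)
        y = rng.random(600) < 0.3
        roc = roc_youden(x, y)
        fpr = (1.0 - roc.specificity)[::-1]
        tpr = roc.sensitivity[::-1]
        assert roc.auc == pytest.approx(float(np.trapezoid(tpr, fpr)), abs=1e-10)

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_youden(np.arange(5.0), np.ones(5, dtype=bool))


def table_from_counts(groups):
    """Participant-level table reconstructed from printed per-group counts.

    ``groups``: list of (group_value_dict, n, {outcome: successes}).
    """
    frames = []
    for values, n, successes in groups:
        df = pd.DataFrame({k: [v] * n for k, v in values.items()})
        for outcome, k in successes.items():
            df[outcome] = [1] * k + [0] * (n - k)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestCutoffTable:
    def test_printed_counts_reproduce_published_rates(self):
        # 832 participants with <=3 abstinent days vs 659 with >=4
        table = table_from_counts(
            [
                ({"dsld": 0}, 832, {"abstinent": 23, "completer": 688}),
                ({"dsld": 4}, 659, {"abstinent": 128, "completer": 598}),
            ]
        )
        cut = cutoff_table(table, 3.5, outcomes=["abstinent", "completer"])
        row = cut.table.loc["abstinent"]
        assert round(row["pct_low"], 1) == 2.8
        assert round(row["pct_high"], 1) == 19.4
        assert round(cut.table.loc["completer", "pct_high"], 1) == 90.7
        assert bool(row["significant"]) is True

    def test_no_association(self):
        table = table_from_counts(
            [({"dsld": 0}, 20, {"abstinent": 10}), ({"dsld": 4}, 20, {"abstinent": 10})]
        )
        cut = cutoff_table(table, 2.0, outcomes=["abstinent"])
        assert cut.table.loc["abstinent", "chi2"] == pytest.approx(0.0)
        assert cut.table.loc["abstinent", "p"] == pytest.approx(1.0)

    def test_statistic_equals_closed_form(self):
        table = table_from_counts(
            [({"dsld": 0}, 20, {"abstinent": 5}), ({"dsld": 4}, 20, {"abstinent": 15})]
        )
        cut = cutoff_table(table, 2.0, outcomes=["abstinent"])
        expected = chi2_oracle([[5, 15], [15, 5]])
        assert cut.table.loc["abstinent", "chi2"] == pytest.approx(expected)

    def test_cutoff_outside_range_errors(self):
        table = table_from_counts([({"dsld": 1}, 10, {"abstinent": 2})])
        with pytest.raises(ValueError, match="outside"):
            cutoff_table(table, 99.0, outcomes=["abstinent"])

    def test_chi2_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            obs = rng.integers(1, 60, size=(2, 2))
            base = stats.chi2_contingency(obs, correction=False)[0]
            for perm in (obs[::-1], obs[:, ::-1], obs.T):
                assert stats.chi2_contingency(perm, correction=False)[0] == pytest.approx(base)
            assert base == pytest.approx(chi2_oracle(obs))


class TestGroupCompare:
    def test_identical_groups(self):
        df = pd.DataFrame({"g": [0] * 5 + [1] * 5, "x": [3.0] * 10})
        res = group_compare(df, "g", "x")
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert res.flagged is not None

    def test_two_group_t_matches_scipy_variants(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"g": rng.integers(0, 2, 200), "x": rng.normal(size=200)})
        a = df.loc[df.g == 0, "x"]
        b = df.loc[df.g == 1, "x"]
        pooled = group_compare(df, "g", "x")
        assert pooled.statistic == pytest.approx(stats.ttest_ind(a, b).statistic)
        welch = group_compare(df, "g", "x", equal_var=False)
        assert welch.statistic == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).statistic
        )

    def test_three_group_anova_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "g": np.repeat([0, 1, 2], 40),
                "x": np.concatenate(
                    [rng.normal(0, 1, 40), rng.normal(0.5, 1, 40), rng.normal(1.0, 1, 40)]
                ),
            }
        )
        res = group_compare(df, "g", "x")
        groups = [df.loc[df.g == k, "x"].to_numpy() for k in (0, 1, 2)]
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / (120 - 3))
        assert res.test == "anova"
        assert res.statistic == pytest.approx(f_oracle)

    def test_categorical_variable_gets_chi_squared(self):
        df = pd.DataFrame({"g": [0] * 30 + [1] * 30, "flag": [1] * 20 + [0] * 10 + [1] * 5 + [0] * 25})
        res = group_compare(df, "g", "flag")
        assert res.test == "chi2"
        assert res.pvalue < 0.01


class TestTabulate:
    def test_published_medium_risk_abstinence_rate(self):
        table = table_from_counts(
            [
                ({"baseline_rdl": "medium"}, 66, {"abstinent": 9}),
                ({"baseline_rdl": "high"}, 269, {"abstinent": 24}),
                ({"baseline_rdl": "very_high"}, 1156, {"abstinent": 118}),
            ]
        )
        tab = tabulate_outcomes(table, outcomes=["abstinent"])
        assert list(tab.index) == ["medium", "high", "very_high"]
        assert round(tab.loc["medium", "abstinent_pct"], 1) == 13.6
        assert round(tab.loc["high", "abstinent_pct"], 1) == 8.9
        assert round(tab.loc["very_high", "abstinent_pct"], 1) == 10.2
        assert tab["n"].sum() == 1491
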