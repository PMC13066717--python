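"""Predictor screening: logistic models, ROC/Youden cutoffs, contingency tests.

Each binary outcome is modelled by maximum-likelihood logistic regression on
the harmonized baseline predictors (study indicators, treatment arm, baseline
WHO risk level with MEDIUM as reference, days since last drink, age and the
demographic flags), with per-coefficient Wald tests and likelihood-ratio tests
for the multi-level blocks.  Familywise error across the four outcomes is
controlled by Bonferroni correction (0.05/4 = 0.0125 by default).

The ROC machinery evaluates every threshold halfway between consecutive
observed predictor values (plus the two infinite endpoints), so an integer
predictor such as DSLD yields half-integer optimal cutoffs; Youden's
J = sensitivity + specificity - 1 is maximized with ties broken toward the
smallest threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "OUTCOME_COLUMNS",
    "LogisticFit",
    "RocCurve",
    "CutoffTable",
    "GroupCompareResult",
    "bonferroni_threshold",
    "fit_outcome_model",
    "roc_youden",
    "cutoff_table",
    "group_compare",
    "tabulate_outcomes",
]

OUTCOME_COLUMNS = ["abstinent", "no_heavy", "who2plus", "completer"]

#: Predictor columns entered after the study/arm/RDL blocks, in display order.
SCALAR_PREDICTORS = [
    "dsld",
    "age",
    "smoker_10plus",
    "thc_positive",
    "sex_male",
    "employed",
    "education_12plus",
    "married_cohab",
    "income_60k",
    "race_white",
    "race_black",
    "race_hispanic",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling familywise error over m tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"number of tests must be a positive integer, got {m}")
    return alpha / m


@dataclass
class LogisticFit:
    """A fitted per-outcome logistic model with Wald and block tests."""

    outcome: str
    subset: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    block_pvalues: dict
    converged: bool
    n_used: int
    n_dropped: int
    alpha_threshold: float
    reference: dict = field(default_factory=dict)
    llf: float = float("nan")

    @property
    def significant(self) -> pd.Series:
        return self.pvalues < self.alpha_threshold

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: beta, SE, Wald p and significance flag."""
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "p": self.pvalues,
                "ci_low": self.conf_int.iloc[:, 0],
                "ci_high": self.conf_int.iloc[:, 1],
                "significant": self.significant,
            }
        )


def build_design(
    table: pd.DataFrame,
    outcome: str,
    subset: Literal["all", "placebo_only"] = "all",
    predictors: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame, dict, int]:
    """Assemble (y, X, reference-map, n_dropped) for one outcome model.

    ``predictors=None`` uses the full standard predictor set; an explicit list
    restricts to those columns (an empty list gives an intercept-only model).
    Complete-case: rows with a missing value in any used column are dropped
    and counted.
    """
    df = table.copy()
    if subset == "placebo_only":
        df = df[df["arm"].astype(str) == "placebo"]
    elif subset != "all":
        raise ValueError(f"unknown subset: {subset!r}")

    reference: dict = {}
    X = pd.DataFrame(index=df.index)
    if predictors is None:
        studies = sorted(df["study"].astype(str).unique())
        reference["study"] = studies[0]
        for s in studies[1:]:
            X[f"study_{s}"] = (df["study"].astype(str) == s).astype(float)
        if subset == "all":
            X["placebo"] = (df["arm"].astype(str) == "placebo").astype(float)
        reference["baseline_rdl"] = "medium"
        levels = df["baseline_rdl"].astype(str)
        X["rdl_high"] = (levels == "high").astype(float)
        X["rdl_very_high"] = (levels == "very_high").astype(float)
        work = df.assign(sex_male=(df["sex"].astype(str) == "male"))
        for col in SCALAR_PREDICTORS:
            X[col] = pd.to_numeric(work[col]).astype(float)
    else:
        work = df.assign(sex_male=(df["sex"].astype(str) == "male")) if "sex" in df else df
        for col in predictors:
            X[col] = pd.to_numeric(work[col]).astype(float)

    y = pd.to_numeric(df[outcome]).astype(float)
    ok = y.notna() & X.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    return y[ok], X[ok], reference, n_dropped


def _fit_logit(y: pd.Series, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        res.llf  # force evaluation while warnings are suppressed
    return res


def fit_outcome_model(
    table: pd.DataFrame,
    outcome: str,
    subset: Literal["all", "placebo_only"] = "all",
    *,
    alpha: float = 0.05,
    n_tests: int = 4,
    predictors: Sequence[str] | None = None,
) -> LogisticFit:
    """Fit the logistic predictor model for one binary outcome.

    Wald per-coefficient p-values mirror a per-predictor significance column;
    the multi-level study and baseline-RDL blocks additionally get a single
    likelihood-ratio p-value each.  Non-convergence or separation is surfaced
    on the returned fit (``converged=False``), never silently.
    """
    y, X, reference, n_dropped = build_design(table, outcome, subset, predictors)
    classes = set(pd.unique(y))
    if len(y) == 0 or not classes == {0.0, 1.0}:
        raise ValueError(
            f"outcome {outcome!r} must contain both classes; got values {sorted(classes)}"
        )
    try:
        res = _fit_logit(y, X)
        converged = bool(res.mle_retvals.get("converged", False))
        # Huge standard errors indicate (quasi-)separation even when the
        # optimizer formally reports convergence.
        if converged and np.any(np.asarray(res.bse) > 1e3):
            converged = False
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic model for {outcome!r} failed to fit: {exc}") from exc

    block_pvalues: dict = {}
    if predictors is None:
        for block, cols in {
            "study": [c for c in X.columns if c.startswith("study_")],
            "baseline_rdl": ["rdl_high", "rdl_very_high"],
        }.items():
            if not cols:
                continue
            reduced = _fit_logit(y, X.drop(columns=cols))
            with np.errstate(all="ignore"):
                lr = 2.0 * (res.llf - reduced.llf)
            block_pvalues[block] = (
                float(stats.chi2.sf(max(lr, 0.0), df=len(cols))) if np.isfinite(lr) else float("nan")
            )

    return LogisticFit(
        outcome=outcome,
        subset=subset,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(),
        block_pvalues=block_pvalues,
        converged=converged,
        n_used=int(len(y)),
        n_dropped=n_dropped,
        alpha_threshold=bonferroni_threshold(alpha, n_tests),
        reference=reference,
        llf=float(res.llf),
    )


@dataclass
class RocCurve:
    """Full ROC coordinate table with Youden's index at each candidate cutoff.

    Positives are predicted by ``predictor > threshold``; thresholds are the
    midpoints between consecutive observed predictor values plus -inf/+inf.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    optimal_youden: float

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    def frame(self) -> pd.DataFrame:
        """Coordinate table (threshold, sensitivity, specificity, Youden J)."""
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "youden": self.youden,
            }
        )


def roc_youden(predictor: Sequence[float], outcome: Sequence[bool]) -> RocCurve:
    """ROC analysis of a continuous predictor with Youden-optimal cutoff.

    Sensitivity and specificity are evaluated at every midpoint between
    consecutive observed predictor values (so integer predictors give
    half-integer cutoffs) together with the two infinite endpoints.  The
    optimal cutoff maximizes J = sensitivity + specificity - 1, ties broken
    toward the smallest threshold.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predictor and outcome must be aligned 1-D sequences")
    if np.isnan(x).any():
        raise ValueError("predictor contains missing values")
    if y.all() or not y.any():
        raise ValueError("outcome must contain both classes for ROC analysis")

    u = np.unique(x)
    thresholds = np.concatenate([[-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]])
    pos = np.sort(x[y])
    neg = np.sort(x[~y])
    # P(x > t | class): count via binary search on the sorted class values.
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / pos.size
    spec = np.searchsorted(neg, thresholds, side="right") / neg.size
    j = sens + spec - 1.0
    # ties go to the smallest threshold; the tolerance keeps the tie-break
    # stable against float-roundoff differences between equal-J cutoffs
    best = int(np.argmax(j >= j.max() - 1e-9))
    auc = float(roc_auc_score(y, x))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        optimal_youden=float(j[best]),
    )


@dataclass
class CutoffTable:
    """Outcome rates split at a predictor cutoff, with chi-squared tests."""

    predictor: str
    cutoff: float
    n_low: int
    n_high: int
    table: pd.DataFrame
    alpha_threshold: float


def cutoff_table(
    table: pd.DataFrame,
    cutoff: float,
    predictor: str = "dsld",
    outcomes: Sequence[str] = tuple(OUTCOME_COLUMNS),
    *,
    alpha_threshold: float = 0.0125,
) -> CutoffTable:
    """Success counts/percentages by ``predictor <= cutoff`` vs ``> cutoff``.

    Pearson chi-squared per outcome, without continuity correction.  An empty
    group is flagged (NaN statistic) rather than raising.
    """
    x = pd.to_numeric(table[predictor])
    if not (x.min() <= cutoff <= x.max()):
        raise ValueError(f"cutoff {cutoff} outside the observed {predictor} range")
    low = table[x <= cutoff]
    high = table[x > cutoff]
    rows = []
    for out in outcomes:
        a = int(pd.to_numeric(low[out]).sum())
        b = int(pd.to_numeric(high[out]).sum())
        row = {
            "outcome": out,
            "n_low": a,
            "pct_low": 100.0 * a / len(low) if len(low) else np.nan,
            "n_high": b,
            "pct_high": 100.0 * b / len(high) if len(high) else np.nan,
        }
        if len(low) == 0 or len(high) == 0:
            row.update(chi2=np.nan, p=np.nan, significant=None)
            warnings.warn(f"empty group at cutoff {cutoff}; chi-squared not defined")
        else:
            obs = np.array([[a, len(low) - a], [b, len(high) - b]])
            if obs.sum(axis=0).min() == 0:
                row.update(chi2=np.nan, p=np.nan, significant=None)
            else:
                chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
                row.update(chi2=float(chi2), p=float(p), significant=bool(p < alpha_threshold))
        rows.append(row)
    return CutoffTable(
        predictor=predictor,
        cutoff=float(cutoff),
        n_low=int(len(low)),
        n_high=int(len(high)),
        table=pd.DataFrame(rows).set_index("outcome"),
        alpha_threshold=alpha_threshold,
    )


@dataclass
class GroupCompareResult:
    """A two-group t, k-group ANOVA, or chi-squared comparison."""

    test: str
    statistic: float
    pvalue: float
    group_stats: pd.DataFrame
    flagged: str | None = None


def group_compare(
    table: pd.DataFrame,
    grouping: str,
    variable: str,
    *,
    equal_var: bool = True,
) -> GroupCompareResult:
    """Compare a variable across the levels of a grouping column.

    Numeric variables get a pooled-variance two-sample t test for two groups
    (``equal_var=False`` switches to Welch) or a one-way ANOVA for more;
    non-numeric/binary-flag variables get a Pearson chi-squared test on the
    contingency table.  Zero-variance degenerate cases are flagged, with the
    two-identical-groups case reported as t = 0, p = 1.
    """
    df = table[[grouping, variable]].dropna()
    groups = [g for _, g in df.groupby(grouping, sort=True)[variable]]
    if len(groups) < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than two groups")

    values = df[variable]
    numeric = pd.api.types.is_numeric_dtype(values) and not (
        pd.api.types.is_bool_dtype(values) or set(pd.unique(values)) <= {0, 1}
    )
    if numeric:
        stats_df = df.groupby(grouping, sort=True)[variable].agg(["count", "mean", "std"])
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if len(arrays) == 2:
            if all(a.var(ddof=1) == 0 for a in arrays if a.size > 1):
                equal_means = np.isclose(arrays[0].mean(), arrays[1].mean())
                return GroupCompareResult(
                    test="t",
                    statistic=0.0 if equal_means else np.inf,
                    pvalue=1.0 if equal_means else 0.0,
                    group_stats=stats_df,
                    flagged="zero variance in both groups",
                )
            t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
            return GroupCompareResult("t" if equal_var else "welch_t", float(t), float(p), stats_df)
        if all(a.var(ddof=1) == 0 for a in arrays):
            return GroupCompareResult("anova", np.nan, np.nan, stats_df, "zero variance in all groups")
        f, p = stats.f_oneway(*arrays)
        return GroupCompareResult("anova", float(f), float(p), stats_df)

    ct = pd.crosstab(df[grouping], df[variable])
    if (ct.sum(axis=0) == 0).any() or ct.shape[1] < 2:
        return GroupCompareResult("chi2", np.nan, np.nan, ct, "degenerate contingency table")
    chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
    return GroupCompareResult("chi2", float(chi2), float(p), ct)


def tabulate_outcomes(
    table: pd.DataFrame,
    by: str = "baseline_rdl",
    outcomes: Sequence[str] = tuple(OUTCOME_COLUMNS),
) -> pd.DataFrame:
    """Counts and percentages of each outcome within levels of a column.

    With ``by="baseline_rdl"`` the rows are ordered by ascending risk level.
    """
    levels = list(table[by].astype(str).unique())
    if by == "baseline_rdl":
        order = ["abstinent", "low", "medium", "high", "very_high"]
        levels = [l for l in order if l in levels]
    else:
        levels = sorted(levels)
    rows = []
    for level in levels:
        sub = table[table[by].astype(str) == level]
        row: dict = {by: level, "n": int(len(sub))}
        for out in outcomes:
            k = int(pd.to_numeric(sub[out]).sum())
            row[f"{out}_n"] = k
            row[f"{out}_pct"] = 100.0 * k / len(sub) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(by)
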