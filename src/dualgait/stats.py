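"""Cohort statistics: stratification, test-selection decision tree,
group comparisons, ROC discrimination and MoCA association regressions.

Test selection follows a fixed decision tree.  Between groups: Shapiro-Wilk
per group and a 1.5*IQR box-plot outlier check send the comparison to the
Mann-Whitney U test (asymptotic two-tailed p) if either fails; otherwise
Levene's test decides between Student's and Welch's t-test.  Within group
(single vs dual condition): the same normality/outlier checks on the paired
differences decide between the paired t-test and the Wilcoxon signed-rank
test (asymptotic p).  No multiple-testing correction is applied; per-metric
p-values are reported as-is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "GroupComparisonResult",
    "RocResult",
    "RegressionResult",
    "adjust_moca",
    "stratify",
    "impute_ceiling",
    "between_group_test",
    "within_group_test",
    "roc_discrimination",
    "bivariate_regression",
    "stepwise_forward",
    "auc_label",
    "analyze_cohort",
]


# --------------------------------------------------------------------------
# screening-score helpers
# --------------------------------------------------------------------------


def adjust_moca(raw_score: float, education_years: float) -> int:
    """Education-corrected MoCA: +1 point for <= 12 years, capped at 30."""
    if not 0 <= raw_score <= 30:
        raise ValueError("raw MoCA score must be within [0, 30]")
    if education_years < 0:
        raise ValueError("education_years must be >= 0")
    score = raw_score + (1 if education_years <= 12 else 0)
    return int(min(score, 30))


def stratify(moca: float, cutoff: int = 24) -> str:
    """'control' (normal cognition) iff MoCA >= cutoff, else 'ci'."""
    if not 0 <= moca <= 30:
        raise ValueError("MoCA score must be within [0, 30]")
    return "control" if moca >= cutoff else "ci"


def impute_ceiling(values, not_finished_flags) -> np.ndarray:
    """Replace not-finished entries by the maximum observed finite value."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(not_finished_flags, dtype=bool)
    if len(values) != len(flags):
        raise ValueError("values and flags must have equal length")
    finite = values[~flags]
    finite = finite[np.isfinite(finite)]
    if len(finite) == 0:
        raise ValueError("all values flagged: no finite value to impute from")
    out = values.copy()
    out[flags] = finite.max()
    return out


# --------------------------------------------------------------------------
# decision-tree comparisons
# --------------------------------------------------------------------------


@dataclass
class GroupComparisonResult:
    metric: str
    test_used: str
    statistic: float
    p: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


def _has_outliers(x: np.ndarray) -> bool:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return bool(np.any((x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)))


def _nonnormal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) < 1e-12:
        return True
    return sps.shapiro(x).pvalue < alpha


def between_group_test(
    control,
    ci,
    metric: str = "",
    alpha: float = 0.05,
    continuity: bool = False,
) -> GroupComparisonResult:
    """Two-group comparison via the normality/outlier/variance decision tree."""
    a = np.asarray(control, dtype=float)
    b = np.asarray(ci, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    if np.ptp(a) < 1e-12 and np.ptp(b) < 1e-12:
        raise ValueError("constant data in both groups: comparison degenerate")
    summary = (
        (float(a.mean()), float(b.mean())),
        (float(a.std(ddof=1)), float(b.std(ddof=1))),
    )
    if _nonnormal(a, alpha) or _nonnormal(b, alpha) or _has_outliers(a) or _has_outliers(b):
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=continuity
        )
        return GroupComparisonResult(metric, "mann_whitney", float(res.statistic), float(res.pvalue), *summary)
    if sps.levene(a, b).pvalue < alpha:
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparisonResult(metric, "welch_t", float(res.statistic), float(res.pvalue), *summary)
    res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparisonResult(metric, "student_t", float(res.statistic), float(res.pvalue), *summary)


def within_group_test(
    single,
    dual,
    metric: str = "",
    alpha: float = 0.05,
    continuity: bool = False,
) -> GroupComparisonResult:
    """Paired single-vs-dual comparison (paired t or Wilcoxon signed-rank)."""
    x = np.asarray(single, dtype=float)
    y = np.asarray(dual, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    d = y - x
    if np.all(np.abs(d) < 1e-12):
        raise ValueError("all paired differences are zero: test degenerate")
    summary = (
        (float(x.mean()), float(y.mean())),
        (float(x.std(ddof=1)), float(y.std(ddof=1))),
    )
    if _nonnormal(d, alpha) or _has_outliers(d):
        res = sps.wilcoxon(x, y, correction=continuity, mode="approx")
        return GroupComparisonResult(metric, "wilcoxon", float(res.statistic), float(res.pvalue), *summary)
    res = sps.ttest_rel(x, y)
    return GroupComparisonResult(metric, "paired_t", float(res.statistic), float(res.pvalue), *summary)


# --------------------------------------------------------------------------
# ROC discrimination
# --------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    se_auc: float
    p_auc: float
    sensitivity: float
    specificity: float
    cutpoint: float
    discrimination_label: str
    separation_warning: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must be in [0, 1]")
        for v in (self.sensitivity, self.specificity):
            if not 0 <= v <= 1:
                raise ValueError("sensitivity/specificity must be in [0, 1]")


def auc_label(auc: float) -> str:
    """Discrimination-ability bins for the area under the ROC curve."""
    if auc == 0.5:
        return "no discrimination"
    if auc < 0.7:
        return "poor"
    if auc < 0.8:
        return "acceptable"
    if auc < 0.9:
        return "excellent"
    return "outstanding"


def _logistic_direction(x: np.ndarray, y: np.ndarray) -> float:
    """Sign of the single-predictor logistic slope (maximum likelihood)."""
    X = sm.add_constant((x - x.mean()) / (x.std() or 1.0))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        slope = float(fit.params[1])
        if math.isfinite(slope) and slope != 0.0:
            return math.copysign(1.0, slope)
    except Exception:
        pass
    # complete separation or non-convergence: direction from group means
    return math.copysign(1.0, float(x[y == 1].mean() - x[y == 0].mean()) or 1.0)


def roc_discrimination(values, labels, metric: str = "") -> RocResult:
    """Single-metric discrimination: logistic fit, ROC, optimal cut-point.

    The AUC carries a Hanley-McNeil nonparametric SE and a two-tailed p
    against AUC = 0.5; the optimal cut-point is the observed threshold
    minimising ``(1-sens)^2 + (1-spec)^2`` (closest to the (0,1) corner).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 < 3 or n0 < 3:
        raise ValueError("need >= 3 subjects in each class")

    direction = _logistic_direction(x, y)
    score = direction * x  # logistic probability is monotone in this score
    fpr, tpr, _ = roc_curve(y, score)
    auc = float(np.trapezoid(tpr, fpr))

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        p = 2.0 * (1.0 - sps.norm.cdf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0

    best = None
    for c in np.unique(score):
        pred = score >= c
        sens = float(np.sum(pred & (y == 1)) / n1)
        spec = float(np.sum(~pred & (y == 0)) / n0)
        d2 = (1 - sens) ** 2 + (1 - spec) ** 2
        if best is None or d2 < best[0] - 1e-15:
            best = (d2, sens, spec, c)
    _, sens, spec, cut = best

    return RocResult(
        auc=auc,
        se_auc=se,
        p_auc=float(p),
        sensitivity=sens,
        specificity=spec,
        cutpoint=float(direction * cut),
        discrimination_label=auc_label(auc),
        separation_warning=bool(auc >= 1.0 - 1e-12),
    )


# --------------------------------------------------------------------------
# regressions
# --------------------------------------------------------------------------


@dataclass
class RegressionResult:
    r2: float
    adj_r2: float
    se_estimate: float
    b_unstandardized: float
    beta_standardized: float
    p: float

    def __post_init__(self) -> None:
        if self.adj_r2 > self.r2 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed R^2")
        if not 0 <= self.r2 <= 1:
            raise ValueError("R^2 must be in [0, 1]")


def bivariate_regression(x, y, metric: str = "") -> RegressionResult:
    """OLS of the outcome (MoCA) on one gait metric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples of length >= 3")
    if np.ptp(x) < 1e-12:
        raise ValueError("constant predictor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    b = float(fit.params[1])
    sy = y.std(ddof=1)
    beta = b * x.std(ddof=1) / sy if sy > 0 else float("nan")
    return RegressionResult(
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        se_estimate=float(np.sqrt(fit.mse_resid)),
        b_unstandardized=b,
        beta_standardized=float(beta),
        p=float(fit.pvalues[1]),
    )


def stepwise_forward(
    candidates: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    covariates: pd.DataFrame | None = None,
) -> tuple[list[str], object | None]:
    """Stepwise forward selection with backward pruning.

    Variables enter one at a time (the eligible candidate with the smallest
    partial p < ``p_enter``; ties broken by larger |standardised beta|, then
    column order) and entered variables whose p rises above ``p_remove`` are
    removed.  Optional covariates are always kept in the design but are not
    selectable/removable.  Returns the selected column names and the final
    statsmodels OLS fit (None if the model is empty).
    """
    y = np.asarray(y, dtype=float)
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    if len(y) <= candidates.shape[1]:
        raise ValueError("n must exceed the number of candidates")
    cov = covariates if covariates is not None else pd.DataFrame(index=candidates.index)
    selected: list[str] = []

    def fit_with(cols: list[str]):
        X = pd.concat([cov, candidates[cols]], axis=1)
        X = sm.add_constant(X.astype(float), has_constant="add")
        return sm.OLS(y, X).fit()

    while True:
        changed = False
        remaining = [c for c in candidates.columns if c not in selected]
        entries = []
        base = pd.concat([cov, candidates[selected]], axis=1).astype(float)
        base = sm.add_constant(base, has_constant="add")
        for order, c in enumerate(remaining):
            # skip candidates that the current design already spans
            resid = sm.OLS(candidates[c].astype(float), base).fit().resid
            if float(np.var(resid)) < 1e-10 * max(float(candidates[c].var()), 1e-30):
                continue
            try:
                fit = fit_with(selected + [c])
            except Exception:
                continue
            p = float(fit.pvalues.get(c, np.nan))
            if not math.isfinite(p) or p >= p_enter:
                continue
            b = float(fit.params[c])
            sy = y.std(ddof=1)
            beta = abs(b * candidates[c].std(ddof=1) / sy) if sy > 0 else 0.0
            entries.append((p, -beta, order, c))
        if entries:
            entries.sort()
            selected.append(entries[0][3])
            changed = True
        if selected:
            fit = fit_with(selected)
            worst = max(selected, key=lambda c: float(fit.pvalues[c]))
            if float(fit.pvalues[worst]) > p_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            break
    return selected, (fit_with(selected) if selected else None)


# --------------------------------------------------------------------------
# whole-cohort report
# --------------------------------------------------------------------------


def analyze_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    moca_cutoff: int = 24,
) -> dict:
    """Group comparisons, ROC and MoCA regressions over a cohort table.

    ``table`` is the wide per-subject table from
    :func:`dualgait.dualtask.build_cohort_table`; it must contain
    ``moca_raw`` (or ``moca``), ``education_years``, and metric columns.
    Groups are stratified from the education-adjusted MoCA.  Returns a dict
    of DataFrames: ``group_comparisons``, ``roc``, ``bivariate``, plus the
    stepwise-selected variables.
    """
    table = table.copy()
    if "moca" not in table:
        if "moca_raw" not in table or "education_years" not in table:
            raise ValueError("cohort table must contain MoCA and education columns")
        table["moca"] = [
            adjust_moca(r, e)
            for r, e in zip(table["moca_raw"], table["education_years"])
        ]
    table["group"] = [stratify(m, moca_cutoff) for m in table["moca"]]
    is_ci = (table["group"] == "ci").to_numpy()
    if is_ci.sum() < 3 or (~is_ci).sum() < 3:
        raise ValueError("need >= 3 subjects per stratified group")

    metric_cols = [
        c
        for c in table.columns
        if c.startswith(("single_", "dual_", "dte_"))
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    comparisons = []
    for c in metric_cols:
        vals = table[c].to_numpy(dtype=float)
        keep = np.isfinite(vals)
        a, b = vals[keep & ~is_ci], vals[keep & is_ci]
        if len(a) < 3 or len(b) < 3 or (np.ptp(a) < 1e-12 and np.ptp(b) < 1e-12):
            continue
        r = between_group_test(a, b, metric=c, alpha=alpha)
        comparisons.append(
            {
                "metric": c,
                "test": r.test_used,
                "statistic": r.statistic,
                "p": r.p,
                "control_mean": r.group_means[0],
                "control_sd": r.group_sds[0],
                "ci_mean": r.group_means[1],
                "ci_sd": r.group_sds[1],
                "significant": r.p < alpha,
            }
        )
    comparisons = pd.DataFrame(comparisons)

    sig = (
        comparisons.loc[comparisons["significant"], "metric"].tolist()
        if len(comparisons)
        else []
    )
    roc_rows = []
    for c in sig:
        vals = table[c].to_numpy(dtype=float)
        keep = np.isfinite(vals)
        if (keep & is_ci).sum() < 3 or (keep & ~is_ci).sum() < 3:
            continue
        r = roc_discrimination(vals[keep], is_ci[keep], metric=c)
        roc_rows.append(
            {
                "metric": c,
                "auc": r.auc,
                "se": r.se_auc,
                "p": r.p_auc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "cutpoint": r.cutpoint,
                "label": r.discrimination_label,
            }
        )
    roc_df = pd.DataFrame(roc_rows)

    moca = table["moca"].to_numpy(dtype=float)
    reg_rows = []
    for c in sig:
        vals = table[c].to_numpy(dtype=float)
        keep = np.isfinite(vals)
        if keep.sum() < 3 or np.ptp(vals[keep]) < 1e-12:
            continue
        r = bivariate_regression(vals[keep], moca[keep], metric=c)
        reg_rows.append(
            {
                "metric": c,
                "r2": r.r2,
                "adj_r2": r.adj_r2,
                "se": r.se_estimate,
                "b": r.b_unstandardized,
                "beta": r.beta_standardized,
                "p": r.p,
            }
        )
    reg_df = pd.DataFrame(reg_rows)

    selected: list[str] = []
    if sig:
        X = table[sig].astype(float)
        keep = np.isfinite(X.to_numpy()).all(axis=1)
        if keep.sum() > len(sig) + 2:
            selected, _ = stepwise_forward(X.loc[keep], moca[keep])

    return {
        "group_comparisons": comparisons,
        "roc": roc_df,
        "bivariate": reg_df,
        "stepwise_selected": selected,
        "n_control": int((~is_ci).sum()),
        "n_ci": int(is_ci.sum()),
    }
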