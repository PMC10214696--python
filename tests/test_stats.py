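import numpy as np
import pandas as pd
import pytest

from dualgait.stats import (
    adjust_moca,
    auc_label,
    between_group_test,
    bivariate_regression,
    impute_ceiling,
    roc_discrimination,
    stepwise_forward,
    stratify,
    within_group_test,
)


# ------------------------------------------------------- screening scores


@pytest.mark.parametrize(
    "raw, edu, expected",
    [(23, 10, 24), (25, 16, 25), (30, 8, 30), (12, 12, 13)],
)
def test_adjust_moca(raw, edu, expected):
    assert adjust_moca(raw, edu) == expected


def test_adjust_moca_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_moca(31, 10)


@pytest.mark.parametrize("moca, group", [(24, "control"), (23, "ci"), (17, "ci"), (30, "control")])
def test_stratify_boundary(moca, group):
    assert stratify(moca) == group


def test_impute_ceiling_replaces_flagged_with_max():
    out = impute_ceiling([55.0, 340.0, np.nan, np.nan], [False, False, True, True])
    np.testing.assert_allclose(out, [55.0, 340.0, 340.0, 340.0])
    np.testing.assert_allclose(impute_ceiling([1.0, 2.0], [False, False]), [1.0, 2.0])
    np.testing.assert_allclose(impute_ceiling([5.0, np.nan], [False, True]), [5.0, 5.0])
    with pytest.raises(ValueError):
        impute_ceiling([np.nan, np.nan], [True, True])


# ------------------------------------------------------ decision tree


def test_between_clean_gaussian_goes_student_t():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.5, 1, 30)
    res = between_group_test(a, b)
    assert res.test_used == "student_t"


def test_between_outlier_forces_mann_whitney():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 30)
    b = rng.normal(0, 1, 30)
    q1, q3 = np.percentile(a, [25, 75])
    a[0] = q3 + 10 * (q3 - q1)
    res = between_group_test(a, b)
    assert res.test_used == "mann_whitney"


def test_between_unequal_variance_goes_welch():
    # find a fixture that passes Shapiro + outlier checks but fails Levene
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 5, 40)
        from scipy import stats as sps

        if (
            sps.shapiro(a).pvalue > 0.05
            and sps.shapiro(b).pvalue > 0.05
            and not _outliers(a)
            and not _outliers(b)
            and sps.levene(a, b).pvalue < 0.05
        ):
            res = between_group_test(a, b)
            assert res.test_used == "welch_t"
            return
    pytest.fail("no fixture found")


def _outliers(x):
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return bool(np.any((x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)))


def test_between_constant_data_rejected():
    with pytest.raises(ValueError):
        between_group_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


def test_within_shifted_gaussian_goes_paired_t():
    rng = np.random.default_rng(5)
    x = rng.normal(1.0, 0.2, 25)
    y = x + 0.5 + rng.normal(0, 0.1, 25)
    res = within_group_test(x, y)
    assert res.test_used == "paired_t"
    assert res.p < 1e-6


def test_within_heavy_tailed_goes_wilcoxon():
    from scipy import stats as sps

    for seed in range(50):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 0.2, 25)
        y = x + rng.standard_cauchy(25) * 0.3
        if sps.shapiro(y - x).pvalue < 0.05:
            res = within_group_test(x, y)
            assert res.test_used == "wilcoxon"
            return
    pytest.fail("no fixture found")


def test_within_zero_differences_degenerate():
    x = np.ones(10)
    with pytest.raises(ValueError, match="degenerate"):
        within_group_test(x, x)


def test_within_type_one_error_rate_near_alpha():
    """Identical conditions: rejection rate ~ alpha over seeded replicates."""
    rng = np.random.default_rng(12)
    rejections = 0
    reps = 400
    for _ in range(reps):
        x = rng.normal(1.0, 0.2, 50)
        y = x + rng.normal(0, 0.1, 50)
        rejections += within_group_test(x, y).p < 0.05
    rate = rejections / reps
    assert 0.02 <= rate <= 0.09


# ------------------------------------------------------------------ ROC


def _pair_count_auc(x, y):
    """Brute-force concordant-pair AUC oracle (ties counted half)."""
    pos = x[y == 1]
    neg = x[y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation():
    x = np.r_[np.zeros(5), np.ones(5)]
    y = np.r_[np.zeros(5, int), np.ones(5, int)]
    res = roc_discrimination(x, y)
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0
    assert res.separation_warning


def test_roc_independent_scores_near_chance():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 400)
    y = (rng.uniform(size=400) < 0.5).astype(int)
    res = roc_discrimination(x, y)
    assert abs(res.auc - 0.5) < 0.08
    assert res.p_auc > 0.05


def test_roc_auc_equals_pair_counting_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n1, n0 = rng.integers(3, 7), rng.integers(3, 7)
        x = rng.permutation(np.arange(n1 + n0, dtype=float))  # tie-free
        y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        res = roc_discrimination(x, y)
        oracle = _pair_count_auc(x, y)
        assert abs(res.auc - max(oracle, 1 - oracle)) < 1e-12


def test_roc_cutpoint_matches_brute_force():
    rng = np.random.default_rng(9)
    for _ in range(20):
        x = rng.normal(0, 1, 12)
        y = (x + rng.normal(0, 1, 12) > 0).astype(int)
        if y.sum() < 3 or (1 - y).sum() < 3:
            continue
        res = roc_discrimination(x, y)
        # brute force over all observed thresholds in the oriented score
        direction = 1.0 if x[y == 1].mean() >= x[y == 0].mean() else -1.0
        score = direction * x
        best = min(
            (
                (1 - (score >= c)[y == 1].mean()) ** 2
                + (1 - (score < c)[y == 0].mean()) ** 2
            )
            for c in np.unique(score)
        )
        got = (1 - res.sensitivity) ** 2 + (1 - res.specificity) ** 2
        assert abs(got - best) < 1e-12


def test_roc_invariant_to_monotone_transform():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, 40)
    y = (x + rng.normal(0, 1, 40) > 0).astype(int)
    a = roc_discrimination(x, y).auc
    b = roc_discrimination(np.exp(2 * x), y).auc
    assert abs(a - b) < 1e-12


def test_auc_interpretation_bins():
    assert auc_label(0.5) == "no discrimination"
    assert auc_label(0.65) == "poor"
    assert auc_label(0.74) == "acceptable"
    assert auc_label(0.85) == "excellent"
    assert auc_label(0.95) == "outstanding"


# ----------------------------------------------------------- regressions


def test_bivariate_exact_line():
    x = np.arange(10, dtype=float)
    res = bivariate_regression(x, 2 * x)
    assert abs(res.r2 - 1.0) < 1e-12
    assert abs(res.beta_standardized - 1.0) < 1e-12
    assert abs(res.b_unstandardized - 2.0) < 1e-12


def test_bivariate_independent_near_zero_r2():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 500)
    y = rng.normal(0, 1, 500)
    res = bivariate_regression(x, y)
    assert res.r2 < 0.02
    assert res.adj_r2 <= res.r2


def test_bivariate_constant_predictor_rejected():
    with pytest.raises(ValueError):
        bivariate_regression(np.ones(10), np.arange(10.0))


def test_stepwise_pure_noise_selects_nothing():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(0, 1, (100, 5)), columns=list("abcde"))
    y = rng.normal(0, 1, 100)
    selected, fit = stepwise_forward(X, y)
    assert selected == [] and fit is None


def test_stepwise_finds_true_predictor_among_noise():
    exact = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(0, 1, (200, 10)), columns=[f"c{i}" for i in range(10)]
        )
        y = 0.8 * X["c3"].to_numpy() + rng.normal(0, 1, 200)
        selected, _ = stepwise_forward(X, y)
        # the true predictor always enters, and enters first
        assert selected and selected[0] == "c3"
        exact += selected == ["c3"]
    # chance entries of noise variables (p_enter = 0.05 across 9 columns)
    # occur in a minority of runs
    assert exact >= 10


def test_stepwise_collinear_copies_enter_once():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 150)
    X = pd.DataFrame({"a": x, "b": x})
    y = x + rng.normal(0, 0.5, 150)
    selected, _ = stepwise_forward(X, y)
    assert len(selected) == 1


def test_stepwise_keeps_forced_covariates_out_of_selection():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(0, 1, 120)})
    cov = pd.DataFrame({"age": rng.normal(70, 5, 120)})
    y = 0.9 * X["a"].to_numpy() + rng.normal(0, 1, 120)
    selected, fit = stepwise_forward(X, y, covariates=cov)
    assert selected == ["a"]
    assert "age" in fit.params.index
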