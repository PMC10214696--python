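import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dualgait.dualtask import (
    aggregate_condition,
    build_cohort_table,
    coefficient_of_variation,
    dual_task_effect,
    dual_task_effects,
    symmetry_index,
)

finite = st.floats(-1e3, 1e3, allow_nan=False)
nonzero = finite.filter(lambda v: abs(v) > 1e-6)


@pytest.mark.parametrize(
    "values, expected",
    [
        ([0.95, 1.0, 1.05], 100 * np.std([0.95, 1.0, 1.05], ddof=1) / 1.0),
        ([2.0, 2.0, 2.0], 0.0),
    ],
)
def test_cv_examples(values, expected):
    assert abs(coefficient_of_variation(values) - expected) < 1e-12


def test_cv_signed_mean_gives_negative_cv_for_strike_angles():
    angles = np.array([-24.0, -20.0, -16.0])  # mean -20, sd 4
    assert abs(coefficient_of_variation(angles) - (-20.0)) < 1e-12


def test_cv_undefined_near_zero_mean():
    assert math.isnan(coefficient_of_variation([-1.0, 1.0]))


@given(vals=st.lists(st.floats(0.5, 2.0), min_size=3, max_size=20), k=st.floats(0.1, 10))
def test_cv_scale_invariant_and_sign_flips(vals, k):
    base = coefficient_of_variation(vals)
    scaled = coefficient_of_variation([v * k for v in vals])
    flipped = coefficient_of_variation([-v for v in vals])
    assert abs(scaled - base) < 1e-6 * max(1, abs(base))
    assert abs(flipped + base) < 1e-6 * max(1, abs(base))


@pytest.mark.parametrize(
    "left, right, expected",
    [(1.0, 1.0, 0.0), (1.1, 0.9, 20.0), (2.0, 0.0, 200.0)],
)
def test_si_examples(left, right, expected):
    assert abs(symmetry_index(left, right) - expected) < 1e-12


def test_si_undefined_for_zero_sum():
    assert math.isnan(symmetry_index(1.0, -1.0))


@given(a=nonzero, b=nonzero)
def test_si_symmetric_and_bounded(a, b):
    if abs(a + b) < 1e-6:
        return
    s_ab = symmetry_index(a, b)
    s_ba = symmetry_index(b, a)
    assert abs(s_ab - s_ba) < 1e-9 * max(1, abs(s_ab))
    if a > 0 and b > 0:
        assert -1e-12 <= s_ab <= 200.0 + 1e-9
    assert symmetry_index(a, a) == 0.0


@pytest.mark.parametrize(
    "single, dual, expected",
    [(1.0, 1.2, 20.0), (1.3, 1.3, 0.0), (0.90, 0.72, -20.0)],
)
def test_dte_examples(single, dual, expected):
    assert abs(dual_task_effect(single, dual) - expected) < 1e-12


def test_dte_undefined_for_zero_single():
    assert math.isnan(dual_task_effect(0.0, 1.0))


@given(a=nonzero, b=finite, k=st.floats(0.1, 10))
def test_dte_scale_invariance(a, b, k):
    base = dual_task_effect(a, b)
    scaled = dual_task_effect(k * a, k * b)
    assert abs(base - scaled) < 1e-6 * max(1.0, abs(base))
    assert dual_task_effect(a, a) == 0.0


def test_aggregate_pools_both_feet():
    left = pd.DataFrame({"stride_time": [1.0, 1.2]})
    right = pd.DataFrame({"stride_time": [1.1, 1.3]})
    summ = aggregate_condition(left, right, "s1", "single")
    assert abs(summ.mean["stride_time"] - 1.15) < 1e-12
    assert not summ.incomplete
    # SI from per-side means: |1.1-1.2|/1.15*100
    assert abs(summ.si["stride_time"] - 100 * 0.1 / 1.15) < 1e-9


def test_aggregate_flags_missing_foot():
    left = pd.DataFrame({"stride_time": [1.0]})
    right = pd.DataFrame({"stride_time": []})
    summ = aggregate_condition(left, right, "s1", "single")
    assert summ.incomplete
    assert abs(summ.mean["stride_time"] - 1.0) < 1e-12


def test_single_stride_cv_degenerate():
    left = pd.DataFrame({"stride_time": [1.0]})
    right = pd.DataFrame({"stride_time": [1.1]})
    summ = aggregate_condition(left, right, "s1", "single")
    assert np.isfinite(summ.cv["stride_time"])  # two pooled values
    one = aggregate_condition(left, pd.DataFrame({"stride_time": []}), "s1", "single")
    assert math.isnan(one.cv["stride_time"])


def test_cohort_table_wide_columns():
    left = pd.DataFrame({"gait_speed": [1.0, 1.1]})
    right = pd.DataFrame({"gait_speed": [0.9, 1.0]})
    s = aggregate_condition(left, right, "s1", "single")
    d = aggregate_condition(left * 0.8, right * 0.8, "s1", "dual")
    meta = pd.DataFrame([{"subject_id": "s1", "moca_raw": 25, "education_years": 14}])
    table = build_cohort_table(meta, {("s1", "single"): s, ("s1", "dual"): d})
    assert "single_mean_gait_speed" in table
    assert "dual_cv_gait_speed" in table
    assert abs(table.loc[0, "dte_gait_speed"] + 20.0) < 1e-9


def test_dte_mismatched_subjects_rejected():
    a = aggregate_condition(
        pd.DataFrame({"x": [1.0]}), pd.DataFrame({"x": [1.0]}), "s1", "single"
    )
    b = aggregate_condition(
        pd.DataFrame({"x": [1.0]}), pd.DataFrame({"x": [1.0]}), "s2", "dual"
    )
    with pytest.raises(ValueError):
        dual_task_effects(a, b)


def test_subject_dte_recovers_configured_mean_at_large_n():
    """Monte-Carlo: per-subject speed DTEs average to the configured value."""
    from dualgait.synth import CI_PROFILE, draw_speed_dte

    rng = np.random.default_rng(0)
    dte = draw_speed_dte(CI_PROFILE, 4000, rng)
    # expected DTE implied by the stride-length and stride-time shifts
    l = 1 + CI_PROFILE.dte["stride_length"][0] / 100
    t = 1 + CI_PROFILE.dte["stride_time"][0] / 100
    # second-order correction from the DTE spreads (Jensen term of 1/t)
    st_sd = CI_PROFILE.dte["stride_time"][1] / 100
    expected = 100 * (l / t * (1 + st_sd**2 / t**2) - 1)
    assert abs(dte.mean() - expected) < 1.0
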