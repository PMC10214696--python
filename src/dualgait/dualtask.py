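"""Per subject x condition aggregation and the derived dual-task measures.

Three derived measures quantify how walking changes when a cognitive task
is added and how regular/symmetric it is:

``CV [%]  = 100 * SD / mean``                     (stride-to-stride variability)
``SI [%]  = 100 * |L - R| / (0.5 * (L + R))``     (left/right asymmetry)
``DTE [%] = 100 * (dual - single) / single``      (dual-task effect)

Means use both feet pooled; CV uses the pooled stride values with the
SIGNED mean (metrics with negative means, e.g. the strike angle, yield
negative CV); SI uses the per-side means.  A positive DTE is an increase
of the metric under dual-tasking.  Sample (n-1) standard deviations are
used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSummary",
    "coefficient_of_variation",
    "symmetry_index",
    "dual_task_effect",
    "aggregate_condition",
    "dual_task_effects",
    "build_cohort_table",
]

_TOL = 1e-9


def coefficient_of_variation(values) -> float:
    """100 * sample SD / signed mean; NaN (undefined) if |mean| < 1e-9."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("CV needs >= 2 values")
    mean = values.mean()
    if abs(mean) < _TOL:
        return float("nan")
    return float(100.0 * values.std(ddof=1) / mean)


def symmetry_index(left_mean: float, right_mean: float) -> float:
    """100 * |L - R| / (0.5 * (L + R)); NaN when the denominator vanishes."""
    denom = 0.5 * (left_mean + right_mean)
    if abs(denom) < _TOL:
        return float("nan")
    return float(100.0 * abs(left_mean - right_mean) / denom)


def dual_task_effect(single_score: float, dual_score: float) -> float:
    """100 * (dual - single) / single; NaN when the single-task score is 0."""
    if abs(single_score) < _TOL:
        return float("nan")
    return float(100.0 * (dual_score - single_score) / single_score)


@dataclass
class ConditionSummary:
    """Aggregates of one subject x condition over all retained strides."""

    subject_id: str
    condition: str
    n_strides_left: int
    n_strides_right: int
    mean: dict[str, float] = field(default_factory=dict)
    cv: dict[str, float] = field(default_factory=dict)
    si: dict[str, float] = field(default_factory=dict)
    mad: dict[str, float] = field(default_factory=dict)
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.n_strides_left < 1 or self.n_strides_right < 1:
            self.incomplete = True


def aggregate_condition(
    left: pd.DataFrame,
    right: pd.DataFrame,
    subject_id: str = "unknown",
    condition: str = "single",
    mad: dict[str, float] | None = None,
) -> ConditionSummary:
    """Pool both feet into per-metric mean, CV and SI for one condition.

    ``left`` / ``right`` are per-stride metric tables (one row per retained
    stride).  A foot with zero retained strides flags the summary
    incomplete; metrics are then computed from the available side only.
    """
    metrics = sorted(set(left.columns) | set(right.columns))
    summary = ConditionSummary(
        subject_id=subject_id,
        condition=condition,
        n_strides_left=len(left),
        n_strides_right=len(right),
        mad=dict(mad or {}),
    )
    for m in metrics:
        l_vals = left[m].to_numpy(dtype=float) if m in left else np.array([])
        r_vals = right[m].to_numpy(dtype=float) if m in right else np.array([])
        pooled = np.concatenate([l_vals, r_vals])
        pooled = pooled[np.isfinite(pooled)]
        if len(pooled) == 0:
            continue
        summary.mean[m] = float(pooled.mean())
        summary.cv[m] = coefficient_of_variation(pooled) if len(pooled) >= 2 else float("nan")
        if len(l_vals) and len(r_vals):
            summary.si[m] = symmetry_index(float(np.nanmean(l_vals)), float(np.nanmean(r_vals)))
        else:
            summary.si[m] = float("nan")
    return summary


def dual_task_effects(
    single: ConditionSummary,
    dual: ConditionSummary,
) -> dict[str, float]:
    """Per-metric DTE from the per-condition mean scores of one subject."""
    if single.subject_id != dual.subject_id:
        raise ValueError("summaries belong to different subjects")
    out = {}
    for m in single.mean:
        if m in dual.mean:
            out[m] = dual_task_effect(single.mean[m], dual.mean[m])
    return out


def build_cohort_table(
    metadata: pd.DataFrame,
    summaries: dict[tuple[str, str], ConditionSummary],
) -> pd.DataFrame:
    """Wide per-subject table joining metadata, condition aggregates, DTEs.

    Columns are ``{condition}_{stat}_{metric}`` (e.g. ``dual_cv_stride_time``,
    ``dual_si_liftoff_angle``, ``single_mean_gait_speed``), ``dte_{metric}``,
    and ``dual_mad_{label}`` for trajectory MAD aggregates when present.
    """
    rows = []
    for _, meta in metadata.iterrows():
        sid = meta["subject_id"]
        row = dict(meta)
        for condition in ("single", "dual"):
            summ = summaries.get((sid, condition))
            if summ is None:
                continue
            for m, v in summ.mean.items():
                row[f"{condition}_mean_{m}"] = v
            for m, v in summ.cv.items():
                row[f"{condition}_cv_{m}"] = v
            for m, v in summ.si.items():
                row[f"{condition}_si_{m}"] = v
            for label, v in summ.mad.items():
                row[f"{condition}_mad_{label}"] = v
        s, d = summaries.get((sid, "single")), summaries.get((sid, "dual"))
        if s is not None and d is not None:
            for m, v in dual_task_effects(s, d).items():
                row[f"dte_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
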