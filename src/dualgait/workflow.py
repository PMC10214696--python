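"""High-level orchestration: recordings -> stride tables -> cohort table.

Thin glue between the strapdown pipeline, the trajectory-variability
module and the per-subject aggregation, shared by the command-line
interface, the tests and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dualtask, pipeline, trajectory
from .config import PipelineConfig
from .io import ImuRecording

__all__ = [
    "strides_to_frame",
    "mad_aggregates",
    "summarize_recordings",
    "cohort_table_from_simulation",
]


def strides_to_frame(records: list[pipeline.StrideRecord]) -> pd.DataFrame:
    """Per-stride metric table (one row per retained stride)."""
    return pd.DataFrame([r.metrics for r in records])


def _stride_components(
    records: list[pipeline.StrideRecord],
    which: str,
    grid_points: int,
) -> list[trajectory.NormalizedStrideTrajectory]:
    """Time-normalised heel/toe trajectories in walk-aligned components."""
    out = []
    for r in records:
        traj = r.traj_heel if which == "heel" else r.traj_toe
        if traj is None or r.time is None or r.forward is None:
            continue
        fwd = r.forward
        side = np.array([-fwd[1], fwd[0], 0.0])
        comp = np.column_stack([traj @ fwd, traj @ side, traj[:, 2]])
        grid, vals = trajectory.resample_stride(r.time, comp, grid_points)
        vals = vals * 1000.0  # m -> mm
        out.append(
            trajectory.NormalizedStrideTrajectory(
                grid=grid,
                forward=vals[:, 0] - vals[0, 0],
                sideward=vals[:, 1],
                vertical=vals[:, 2],
                point_label=which,
            )
        )
    return out


def mad_aggregates(
    records: list[pipeline.StrideRecord],
    grid_points: int = 101,
) -> dict[str, float]:
    """Set-level MAD per trajectory point and component, mm."""
    out: dict[str, float] = {}
    for which in ("heel", "toe"):
        strides = _stride_components(records, which, grid_points)
        if len(strides) < 2:
            continue
        for comp in trajectory.COMPONENTS:
            out[f"{which}_{comp}"] = trajectory.compute_mad(strides, comp).mean
    return out


def summarize_recordings(
    left: ImuRecording,
    right: ImuRecording,
    config: PipelineConfig | None = None,
) -> tuple[dualtask.ConditionSummary, dict[str, list[pipeline.StrideRecord]]]:
    """Run the pipeline on both feet and aggregate one condition."""
    cfg = config or PipelineConfig()
    recs = {"left": pipeline.extract_strides(left, cfg), "right": pipeline.extract_strides(right, cfg)}
    mad = mad_aggregates(recs["left"] + recs["right"], cfg.resample_points)
    summary = dualtask.aggregate_condition(
        strides_to_frame(recs["left"]),
        strides_to_frame(recs["right"]),
        subject_id=left.subject_id,
        condition=left.condition,
        mad=mad,
    )
    return summary, recs


def cohort_table_from_simulation(
    sim: dict,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Wide per-subject cohort table from a ``simulate_cohort`` result.

    Parameter-mode simulations aggregate the drawn per-stride tables
    directly; signal-mode simulations are pushed through the full
    strapdown pipeline first.
    """
    cfg = config or PipelineConfig()
    summaries: dict[tuple[str, str], dualtask.ConditionSummary] = {}
    meta = sim["metadata"]
    for sid in meta["subject_id"]:
        for condition in ("single", "dual"):
            if sim["recordings"]:
                left = sim["recordings"][(sid, condition, "left")]
                right = sim["recordings"][(sid, condition, "right")]
                summary, _ = summarize_recordings(left, right, cfg)
            else:
                summary = dualtask.aggregate_condition(
                    sim["stride_tables"][(sid, condition, "left")],
                    sim["stride_tables"][(sid, condition, "right")],
                    subject_id=sid,
                    condition=condition,
                )
            summaries[(sid, condition)] = summary
    return dualtask.build_cohort_table(meta, summaries)
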