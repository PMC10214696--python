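"""Stride time-normalisation, trajectory variability (MAD), path lengths.

Trajectory variability is the mean absolute deviation of each
time-normalised stride trajectory from the pointwise cross-stride mean,
computed per component (forward, sideward, vertical) and reported in mm.
The forward component is expressed relative to each stride's own start, so
stride-length variability rather than cumulative distance drives it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedStrideTrajectory",
    "MadResult",
    "resample_stride",
    "compute_mad",
    "path_length_3d",
    "normalize_strides",
]

COMPONENTS = ("forward", "sideward", "vertical")


@dataclass
class NormalizedStrideTrajectory:
    """One stride's trajectory on the uniform 0-100% stride-time grid (mm)."""

    grid: np.ndarray  # percent, 0..100
    forward: np.ndarray
    sideward: np.ndarray
    vertical: np.ndarray
    point_label: str = "heel"

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            arr = getattr(self, name)
            if len(arr) != len(self.grid):
                raise ValueError(f"{name} length does not match grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    def component(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class MadResult:
    """Per-stride and set-level mean absolute deviation, mm."""

    per_stride: np.ndarray
    mean: float

    def __post_init__(self) -> None:
        if np.any(self.per_stride < 0) or self.mean < 0:
            raise ValueError("MAD values must be non-negative")


def resample_stride(
    time: np.ndarray,
    values: np.ndarray,
    grid_points: int = 101,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear resampling onto the uniform 0-100% stride-time grid.

    ``values`` may be (n,) or (n, k); endpoints are preserved exactly.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(time) < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    grid = np.linspace(0.0, 100.0, grid_points)
    frac = (time - time[0]) / (time[-1] - time[0]) * 100.0
    frac[0], frac[-1] = 0.0, 100.0
    if values.ndim == 1:
        out = np.interp(grid, frac, values)
    else:
        out = np.column_stack([np.interp(grid, frac, values[:, k]) for k in range(values.shape[1])])
    return grid, out


def normalize_strides(
    strides: list[tuple[np.ndarray, np.ndarray]],
    grid_points: int = 101,
    point_label: str = "heel",
    forward_axis: int = 0,
) -> list[NormalizedStrideTrajectory]:
    """Time-normalise a set of (time, xyz-position [m]) stride trajectories.

    Positions are converted to mm; the forward component is re-expressed
    relative to each stride's first sample.
    """
    out = []
    for time, xyz in strides:
        grid, vals = resample_stride(time, xyz, grid_points)
        vals = vals * 1000.0  # m -> mm
        fwd = vals[:, forward_axis] - vals[0, forward_axis]
        side_axis = 1 if forward_axis == 0 else 0
        out.append(
            NormalizedStrideTrajectory(
                grid=grid,
                forward=fwd,
                sideward=vals[:, side_axis],
                vertical=vals[:, 2],
                point_label=point_label,
            )
        )
    return out


def compute_mad(
    strides: list[NormalizedStrideTrajectory],
    component: str,
) -> MadResult:
    """Mean absolute deviation from the pointwise cross-stride mean.

    For stride ``x`` on an ``n``-point grid: ``MAD = (1/n) * sum_i |x_i -
    xbar_i|`` where ``xbar_i`` is the average of all strides at grid point
    ``i``.  Requires >= 2 strides on identical grids.
    """
    if len(strides) < 2:
        raise ValueError("need >= 2 strides to compute MAD")
    grid = strides[0].grid
    for s in strides[1:]:
        if len(s.grid) != len(grid) or not np.allclose(s.grid, grid):
            raise ValueError("strides must share a common grid")
    mat = np.vstack([s.component(component) for s in strides])
    mean_curve = mat.mean(axis=0)
    per_stride = np.mean(np.abs(mat - mean_curve), axis=1)
    return MadResult(per_stride=per_stride, mean=float(per_stride.mean()))


def path_length_3d(xyz: np.ndarray) -> float:
    """Sum of Euclidean distances between consecutive 3D samples, metres."""
    xyz = np.asarray(xyz, dtype=float)
    if len(xyz) < 2:
        raise ValueError("need >= 2 samples for a path length")
    return float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
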