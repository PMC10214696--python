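"""Readers and writers for raw IMU text files and tabular artifacts.

The raw on-disk format is a plain-text file with one sample per line and
seven numeric columns — time [s], accel x/y/z [m/s^2], gyro x/y/z — separated
by whitespace or commas, with one optional header line.  Gyro units are rad/s
unless a header declares ``deg/s``, in which case they are converted on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImuRecording",
    "read_imu_text",
    "write_imu_text",
    "write_stride_table",
    "read_stride_table",
]

_HEADER_RE = re.compile(r"[A-Za-z]")


@dataclass
class ImuRecording:
    """One foot's raw inertial streams for a single walk.

    ``accel`` holds specific force in the sensor frame (gravity included),
    m/s^2; ``gyro`` holds angular rate in the sensor frame, rad/s.  ``time``
    is in seconds and strictly increasing.
    """

    subject_id: str
    foot: str  # "left" | "right"
    condition: str  # "single" | "dual"
    time: np.ndarray
    accel: np.ndarray  # (n, 3)
    gyro: np.ndarray  # (n, 3)
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.foot not in ("left", "right"):
            raise ValueError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if self.condition not in ("single", "dual"):
            raise ValueError(f"condition must be 'single' or 'dual', got {self.condition!r}")
        n = len(self.time)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("time, accel and gyro must have matching lengths")
        if n >= 2:
            dts = np.diff(self.time)
            if np.any(dts <= 0):
                raise ValueError("time must be strictly increasing")
            med = float(np.median(dts))
            if abs(med - 1.0 / self.rate_hz) > 0.01 / self.rate_hz:
                raise ValueError(
                    f"median sampling interval {med:.6f} s deviates >1% from "
                    f"nominal 1/{self.rate_hz:g} s"
                )
        for name, arr in (("time", self.time), ("accel", self.accel), ("gyro", self.gyro)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite samples in {name}")

    def __len__(self) -> int:
        return len(self.time)


def read_imu_text(
    path: str | Path,
    subject_id: str = "unknown",
    foot: str = "left",
    condition: str = "single",
    rate_hz: float = 100.0,
) -> ImuRecording:
    """Load a raw 7-column IMU text file into a validated :class:`ImuRecording`.

    Raises ``ValueError`` naming the offending line on malformed or
    non-finite rows, and rejects files with more than 1% missing samples
    (judged from gaps in the timestamp column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    gyro_in_deg = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and _HEADER_RE.search(line):
                gyro_in_deg = "deg" in line.lower()
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: unparsable value ({exc})") from None
            if not all(np.isfinite(vals)):
                raise ValueError(f"{path}: line {lineno}: non-finite sample")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty recording")
    data = np.asarray(rows, dtype=float)
    time = data[:, 0]
    if len(time) >= 2:
        dts = np.diff(time)
        nominal = 1.0 / rate_hz
        n_missing = int(np.sum(np.round(dts / nominal) - 1))
        if n_missing > 0.01 * len(time):
            raise ValueError(
                f"{path}: {n_missing} missing samples (> 1% of {len(time)}); rejected"
            )
    gyro = data[:, 4:7]
    if gyro_in_deg:
        gyro = np.deg2rad(gyro)
    return ImuRecording(
        subject_id=subject_id,
        foot=foot,
        condition=condition,
        time=time,
        accel=data[:, 1:4],
        gyro=gyro,
        rate_hz=rate_hz,
    )


def write_imu_text(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording in the package text dialect (rad/s gyro, header line)."""
    header = "time_s ax_m_s2 ay_m_s2 az_m_s2 gx_rad_s gy_rad_s gz_rad_s"
    data = np.column_stack([rec.time, rec.accel, rec.gyro])
    np.savetxt(path, data, header=header, comments="", fmt="%.17g")


def write_stride_table(strides: list, path: str | Path) -> None:
    """Write per-stride records (one row per stride, one column per metric).

    Accepts a list of objects exposing ``as_row()`` (``StrideRecord``) or a
    list of plain dicts.  The reload via :func:`read_stride_table` is
    loss-free to full float precision.
    """
    if not strides:
        raise ValueError("cannot write an empty stride table")
    rows = [s.as_row() if hasattr(s, "as_row") else dict(s) for s in strides]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_stride_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
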