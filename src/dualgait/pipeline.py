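"""Orientation-invariant strapdown gait reconstruction.

Chain: zero-velocity detection (angular-rate energy), complementary-filter
orientation estimation, gravity removal and direct+reverse ZUPT-anchored
integration, gait-event detection from low-pass-filtered acceleration
signals, and the 13 per-stride spatiotemporal metrics.

The method never assumes a particular sensor mounting: tilt comes from the
accelerometer's gravity direction, the per-stride forward axis comes from
the horizontal displacement between successive mid-stances, and foot pitch
is measured relative to the foot-flat attitude of the same stance, so any
constant mounting rotation cancels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .config import GRAVITY, PipelineConfig
from .io import ImuRecording
from . import trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ZuptMask",
    "OrientationSeries",
    "StrideRecord",
    "detect_zupt",
    "estimate_orientation",
    "reconstruct_displacement",
    "segment_strides",
    "detect_gait_events",
    "compute_stride_metrics",
    "exclude_boundary_strides",
    "extract_strides",
]

METRIC_COLUMNS = [
    "stride_time",
    "swing_time",
    "stance_time",
    "swing_ratio",
    "stance_ratio",
    "foot_flat_ratio",
    "pushing_ratio",
    "loading_ratio",
    "stride_length",
    "gait_speed",
    "strike_angle",
    "liftoff_angle",
    "min_toe_clearance",
    "heel_path_length",
    "toe_path_length",
]


# --------------------------------------------------------------------------
# small quaternion toolkit (scalar-first, unit quaternions)
# --------------------------------------------------------------------------


def _quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(v))
    if angle < 1e-14:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]) / math.sqrt(
            1.0 + 0.25 * angle * angle
        )
    axis = v / angle
    return np.concatenate([[math.cos(0.5 * angle)], math.sin(0.5 * angle) * axis])


def _quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    u = np.array([x, y, z])
    return v + 2.0 * np.cross(u, np.cross(u, v) + w * v)


def _quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def _quats_to_matrices(q: np.ndarray) -> np.ndarray:
    """(n, 4) unit quaternions -> (n, 3, 3) rotation matrices."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    out = np.empty((len(q), 3, 3))
    out[:, 0, 0] = 1 - 2 * (y * y + z * z)
    out[:, 0, 1] = 2 * (x * y - z * w)
    out[:, 0, 2] = 2 * (x * z + y * w)
    out[:, 1, 0] = 2 * (x * y + z * w)
    out[:, 1, 1] = 1 - 2 * (x * x + z * z)
    out[:, 1, 2] = 2 * (y * z - x * w)
    out[:, 2, 0] = 2 * (x * z - y * w)
    out[:, 2, 1] = 2 * (y * z + x * w)
    out[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return out


def _slerp(q0: np.ndarray, q1: np.ndarray, u: float) -> np.ndarray:
    if np.dot(q0, q1) < 0:
        q1 = -q1
    d = float(np.clip(np.dot(q0, q1), -1.0, 1.0))
    if d > 1.0 - 1e-10:
        q = (1 - u) * q0 + u * q1
        return q / np.linalg.norm(q)
    omega = math.acos(d)
    return (
        math.sin((1 - u) * omega) * q0 + math.sin(u * omega) * q1
    ) / math.sin(omega)


# --------------------------------------------------------------------------
# ZUPT detection
# --------------------------------------------------------------------------


@dataclass
class ZuptMask:
    """Per-sample stationarity flags plus the list of stationary intervals."""

    flags: np.ndarray
    intervals: list[tuple[int, int]]  # half-open, disjoint, sorted

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.intervals:
            if not (0 <= s < e <= len(self.flags)):
                raise ValueError("interval out of range")
            if s <= prev_end:
                raise ValueError("intervals must be disjoint and sorted")
            prev_end = e
            if not np.all(self.flags[s:e]):
                raise ValueError("flags inconsistent with intervals")


def detect_zupt(
    rec: ImuRecording,
    window_s: float = 0.1,
    threshold: float = 0.05,
    min_duration_s: float = 0.15,
    edge_min_s: float = 0.5,
    expand_threshold: float | None = None,
) -> ZuptMask:
    """Angular-rate energy detector for zero-velocity (foot-flat) intervals.

    A sample is stationary iff the mean squared angular-rate magnitude over
    the centred window is below ``threshold``.  Interval bounds are then
    refined outward while the instantaneous energy stays below
    ``expand_threshold`` (default ``threshold / 10``): the windowed
    statistic alone clips the bounds by up to half a window, while
    expanding at the full threshold would place the integration anchors
    where the foot already moves at cm/s.  Intervals shorter than
    ``min_duration_s`` are discarded, as are edge-touching intervals
    shorter than ``edge_min_s`` (partial stands).
    """
    n = len(rec)
    w = int(round(window_s * rec.rate_hz))
    if w < 3:
        raise ValueError("window too short: need >= 3 samples")
    if n < w:
        raise ValueError("recording shorter than the detector window")
    if expand_threshold is None:
        expand_threshold = threshold / 10.0
    energy = np.sum(rec.gyro**2, axis=1)
    smoothed = np.convolve(energy, np.ones(w) / w, mode="same")
    raw_flags = smoothed < threshold

    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if raw_flags[i]:
            j = i
            while j < n and raw_flags[j]:
                j += 1
            # core = longest run of per-sample energy below the expand
            # threshold inside the windowed interval (short dips at the
            # gait events must not be mistaken for the foot-flat core)
            low = energy[i:j] < expand_threshold
            best = cur_start = None
            best_len = cur_len = 0
            for k, flag in enumerate(low):
                if flag:
                    if cur_len == 0:
                        cur_start = k
                    cur_len += 1
                    if cur_len > best_len:
                        best, best_len = cur_start, cur_len
                else:
                    cur_len = 0
            if best is None:
                i = j
                continue
            s, e = i + best, i + best + best_len
            while s > 0 and energy[s - 1] < expand_threshold:
                s -= 1
            while e < n and energy[e] < expand_threshold:
                e += 1
            if intervals and s <= intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], max(e, intervals[-1][1]))
            else:
                intervals.append((s, e))
            i = max(j, e)
        else:
            i += 1

    min_len = int(round(min_duration_s * rec.rate_hz))
    edge_len = int(round(edge_min_s * rec.rate_hz))
    kept = []
    for s, e in intervals:
        if e - s < min_len:
            continue
        if (s == 0 or e == n) and e - s < edge_len:
            continue
        kept.append((s, e))

    flags = np.zeros(n, dtype=bool)
    for s, e in kept:
        flags[s:e] = True
    return ZuptMask(flags=flags, intervals=kept)


# --------------------------------------------------------------------------
# orientation
# --------------------------------------------------------------------------


@dataclass
class OrientationSeries:
    """Per-sample sensor-to-world unit quaternions (scalar first)."""

    quats: np.ndarray  # (n, 4)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.quats, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit norm")
        dots = np.sum(self.quats[1:] * self.quats[:-1], axis=1)
        if np.any(dots < 0):
            raise ValueError("quaternion sign flips between neighbours")

    def matrices(self) -> np.ndarray:
        return _quats_to_matrices(self.quats)

    def at_time(self, t: float, dt: float) -> np.ndarray:
        i = int(np.clip(math.floor(t / dt), 0, len(self.quats) - 2))
        u = float(np.clip(t / dt - i, 0.0, 1.0))
        return _slerp(self.quats[i], self.quats[i + 1], u)


def estimate_orientation(
    rec: ImuRecording,
    mask: ZuptMask,
    gain: float = 0.08,
    accel_gate: float = 0.5,
    omega_gate: float = 0.2,
) -> OrientationSeries:
    """Complementary-filter attitude: gyro integration corrected by gravity.

    The initial attitude is taken from the accelerometer direction averaged
    over the first stationary interval (which must start within 0.5 s of the
    recording start); afterwards each gyro step is blended toward the
    measured gravity direction with per-sample ``gain``.  The correction is
    down-weighted when the specific-force magnitude deviates from g by more
    than ``accel_gate`` or the angular rate exceeds ``omega_gate`` (the
    accelerometer no longer points along gravity while the foot moves), so
    it acts essentially during stance and only steadies the tilt between
    ZUPTs.  Yaw is unobservable without a magnetometer and is left free.
    """
    if not mask.intervals or mask.intervals[0][0] > 0.5 * rec.rate_hz:
        raise ValueError(
            "no initial stationary segment; pad the recording with standing "
            "data before the walk"
        )
    dt = 1.0 / rec.rate_hz
    n = len(rec)
    s0, e0 = mask.intervals[0]
    f0 = rec.accel[s0:e0].mean(axis=0)
    u = f0 / np.linalg.norm(f0)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    angle = math.atan2(s, float(np.dot(u, z)))
    q = (
        _quat_from_rotvec(axis / s * angle)
        if s > 1e-12
        else np.array([1.0, 0.0, 0.0, 0.0])
    )

    quats = np.empty((n, 4))
    quats[0] = q
    for k in range(1, n):
        # trapezoidal angular rate: endpoint-rule drift at swing speeds
        # would reach degrees of tilt and leak gravity into the integration
        q = _quat_mul(q, _quat_from_rotvec(0.5 * (rec.gyro[k] + rec.gyro[k - 1]) * dt))
        f = rec.accel[k]
        fn = float(np.linalg.norm(f))
        if fn > 1e-9:
            wn = float(np.linalg.norm(rec.gyro[k]))
            weight = math.exp(
                -(((fn - GRAVITY) / accel_gate) ** 2) - (wn / omega_gate) ** 2
            )
            if not mask.flags[k]:
                # instantaneous near-static moments mid-movement (|f|~g,
                # omega~0 around the gait events) are not true rest; trust
                # the accelerometer there only marginally
                weight *= 0.05
            v_world = _quat_rotate(q, f / fn)
            err = np.cross(v_world, z)
            q = _quat_mul(_quat_from_rotvec(gain * weight * err), q)
        q = q / np.linalg.norm(q)
        if np.dot(q, quats[k - 1]) < 0:
            q = -q
        quats[k] = q
    return OrientationSeries(quats=quats)


# --------------------------------------------------------------------------
# displacement
# --------------------------------------------------------------------------


def reconstruct_displacement(
    rec: ImuRecording,
    orientation: OrientationSeries,
    mask: ZuptMask,
    level_ground: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """ZUPT-anchored world velocity and position (direct+reverse blend).

    Between consecutive stationary intervals the gravity-removed world
    acceleration is integrated forward from zero velocity and backward from
    zero velocity; the two solutions are blended with a weight ramping
    linearly 0 -> 1 across the movement, which pins the velocity to zero at
    both anchors and cancels the linear drift a constant residual bias
    would otherwise cause.  Velocity is identically zero inside stationary
    intervals; position is the trapezoidal integral of the blended velocity.
    With ``level_ground`` (default) the per-movement vertical drift is
    additionally pinned to zero: on the flat walkway every foot-flat sits
    at the same height.
    """
    if len(mask.intervals) < 2:
        raise ValueError("need >= 2 stationary intervals to reconstruct a stride")
    dt = 1.0 / rec.rate_hz
    n = len(rec)
    rot = orientation.matrices()
    f_world = np.einsum("nij,nj->ni", rot, rec.accel)
    acc = f_world - np.array([0.0, 0.0, GRAVITY])

    vel = np.zeros((n, 3))
    for (s0, e0), (s1, e1) in zip(mask.intervals[:-1], mask.intervals[1:]):
        a, b = e0 - 1, s1  # last stationary sample .. first stationary sample
        seg = acc[a : b + 1]
        m = b - a
        if m < 1:
            continue
        steps = 0.5 * dt * (seg[1:] + seg[:-1])
        v_fwd = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        v_rev = v_fwd - v_fwd[-1]
        lam = (np.arange(m + 1) / m)[:, None]
        vel[a : b + 1] = (1.0 - lam) * v_fwd + lam * v_rev

    pos = np.zeros((n, 3))
    pos[1:] = np.cumsum(0.5 * dt * (vel[1:] + vel[:-1]), axis=0)

    if level_ground:
        for (s0, e0), (s1, e1) in zip(mask.intervals[:-1], mask.intervals[1:]):
            a, b = e0 - 1, s1
            m = b - a
            if m < 1:
                continue
            drift = pos[b, 2] - pos[a, 2]
            pos[a : b + 1, 2] -= np.arange(m + 1) / m * drift
            pos[b + 1 :, 2] -= drift
    return vel, pos


# --------------------------------------------------------------------------
# strides and events
# --------------------------------------------------------------------------


def segment_strides(mask: ZuptMask) -> list[tuple[int, int]]:
    """Stride bounds between consecutive stationary-interval midpoints."""
    if len(mask.intervals) < 3:
        raise ValueError("need >= 3 stationary intervals for >= 2 strides")
    mids = [(s + e) // 2 for s, e in mask.intervals]
    return [(mids[j], mids[j + 1]) for j in range(len(mids) - 1)]


def _lowpass(x: np.ndarray, cutoff_hz: float, rate_hz: float) -> np.ndarray:
    nyq = 0.5 * rate_hz
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}) Hz")
    b, a = butter(4, cutoff_hz / nyq)
    return filtfilt(b, a, x)


def _refine_peak(y: np.ndarray, i: int, dt: float) -> float:
    """Parabolic sub-sample refinement of a local maximum at index i."""
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if abs(denom) > 1e-12:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            return (i + float(np.clip(delta, -0.5, 0.5))) * dt
    return i * dt


def detect_gait_events(
    rec: ImuRecording,
    orientation: OrientationSeries,
    mask: ZuptMask,
    lowpass_cutoff_hz: float = 20.0,
    search_frac_hs: float = 0.45,
    search_frac_to: float = 0.6,
) -> pd.DataFrame:
    """Heel-strike and toe-off per stationary interval.

    Heel strike is the peak of the low-pass-filtered specific-force
    magnitude in the landing window (the trailing ``search_frac_hs`` of the
    movement preceding each foot-flat); toe off is the peak of the filtered
    world-frame vertical acceleration in the liftoff window (the leading
    ``search_frac_to`` of the movement after it).
    Foot-flat start/end are the ZUPT interval bounds.  Peak times are
    refined to sub-sample precision by parabolic interpolation.
    """
    dt = 1.0 / rec.rate_hz
    mag = _lowpass(np.linalg.norm(rec.accel, axis=1), lowpass_cutoff_hz, rec.rate_hz)
    rot = orientation.matrices()
    az_world = np.einsum("nij,nj->ni", rot, rec.accel)[:, 2] - GRAVITY
    az = _lowpass(az_world, lowpass_cutoff_hz, rec.rate_hz)
    # band-passed vertical acceleration isolates the impact transient from
    # the slow swing background; used only for sub-sample refinement
    az_bp = az - _lowpass(az_world, 4.0, rec.rate_hz)

    K = len(mask.intervals)
    # heel strikes first: they bound the toe-off search in the same movement
    hs_idx: list[int | None] = [None] * K
    hs_t: list[float | None] = [None] * K
    for j, (s, e) in enumerate(mask.intervals):
        if j >= 1:
            prev_end = mask.intervals[j - 1][1]
            gap = s - prev_end
            lo = max(prev_end, s - max(2, int(round(search_frac_hs * gap))))
            if lo < s:
                win = mag[lo:s]
                i0 = lo + int(np.argmax(win))
                # re-centre on the isolated transient: the magnitude peak
                # rides on the sloping swing deceleration and lands a
                # sample early otherwise
                l2, h2 = max(0, i0 - 4), i0 + 5
                i0 = l2 + int(np.argmax(az_bp[l2:h2]))
                hs_idx[j] = i0
                hs_t[j] = _refine_peak(az_bp, i0, dt)

    rows = []
    for j, (s, e) in enumerate(mask.intervals):
        t_hs, i_hs = hs_t[j], hs_idx[j]
        t_to = i_to = None
        if j <= K - 2:
            next_start = mask.intervals[j + 1][0]
            gap = next_start - e
            hi = min(next_start, e + max(2, int(round(search_frac_to * gap))))
            if hs_idx[j + 1] is not None:
                # the pre-strike deceleration and impact of the upcoming
                # heel strike must stay outside the liftoff window
                hi = min(hi, hs_idx[j + 1] - max(2, int(round(0.15 * gap))))
            if hi > e:
                # push-off transient = vertical-accel peak flanked by deep
                # negative lobes on BOTH sides; smooth swing peaks can be
                # taller but lack the two-sided drop
                side = max(2, int(round(0.05 * rec.rate_hz)))
                best_prom, i_to = -np.inf, None
                for k in range(e + 1, hi - 1):
                    if not (az[k] >= az[k - 1] and az[k] > az[k + 1] and az[k] > 15.0):
                        continue
                    drop_before = az[k] - az[max(0, k - side) : k].min()
                    drop_after = az[k] - az[k + 1 : min(len(az), k + side + 1)].min()
                    prom = min(drop_before, drop_after)
                    if prom > best_prom:
                        best_prom, i_to = prom, k
                if i_to is None:
                    i_to = e + int(np.argmax(az[e:hi]))
                t_to = _refine_peak(az, i_to, dt)
        rows.append(
            {
                "interval": j,
                "i_foot_flat_start": s,
                "i_foot_flat_end": e,
                "t_foot_flat_start": s * dt,
                "t_foot_flat_end": e * dt,
                "i_heel_strike": i_hs,
                "t_heel_strike": t_hs,
                "i_toe_off": i_to,
                "t_toe_off": t_to,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stride records and metrics
# --------------------------------------------------------------------------


@dataclass
class StrideRecord:
    """One stride's bounds, gait events, trajectories and the 13 metrics."""

    segment: int
    bounds: tuple[int, int]
    events: dict  # heel_strike / foot_flat_start / foot_flat_end / toe_off
    metrics: dict
    traj_sensor: np.ndarray | None = None
    traj_heel: np.ndarray | None = None
    traj_toe: np.ndarray | None = None
    time: np.ndarray | None = None
    forward: np.ndarray | None = None  # horizontal walking direction, unit

    def __post_init__(self) -> None:
        m = self.metrics
        if abs(m["swing_ratio"] + m["stance_ratio"] - 100.0) > 1e-9:
            raise ValueError("swing_ratio + stance_ratio must equal 100")
        sub = m["foot_flat_ratio"] + m["pushing_ratio"] + m["loading_ratio"]
        if abs(sub - 100.0) > 1e-9:
            raise ValueError("stance sub-phase ratios must sum to 100")
        if abs(m["gait_speed"] - m["stride_length"] / m["stride_time"]) > 1e-9:
            raise ValueError("gait_speed must equal stride_length / stride_time")
        if m["strike_angle"] > 0:
            raise ValueError("strike_angle must be <= 0")

    def as_row(self) -> dict:
        row = {"segment": self.segment}
        row.update({k: self.events[k] for k in sorted(self.events)})
        row.update({k: self.metrics[k] for k in METRIC_COLUMNS})
        return row


def _foot_flat_frame(forward: np.ndarray) -> np.ndarray:
    """Foot-to-world rotation at foot flat: x along walking direction, z up."""
    x = np.array([forward[0], forward[1], 0.0])
    x /= np.linalg.norm(x)
    zaxis = np.array([0.0, 0.0, 1.0])
    y = np.cross(zaxis, x)
    return np.column_stack([x, y, zaxis])


def compute_stride_metrics(
    segments: list[tuple[int, int]],
    events: pd.DataFrame,
    pos: np.ndarray,
    orientation: OrientationSeries,
    rate_hz: float,
    heel_offset: np.ndarray,
    toe_offset: np.ndarray,
) -> list[StrideRecord | None]:
    """Per-stride metrics for each segment (None where a stride is invalid).

    Stride ``s`` is anchored on the stance around stationary interval ``s``:
    stride time runs heel-strike(s) -> heel-strike(s+1); stance is
    HS(s) -> TO(s); foot-flat bounds are the ZUPT interval; stride length is
    the horizontal displacement between the two mid-stances; angles are the
    signed foot pitch (relative to this stance's foot-flat attitude,
    projected on the walking direction) at HS and TO; minimum toe clearance
    is the central-swing minimum height of the toe point obtained by
    rigid-body lever arm from the sensor pose.
    """
    dt = 1.0 / rate_hz
    ev = events.set_index("interval")
    out: list[StrideRecord | None] = []
    zaxis = np.array([0.0, 0.0, 1.0])
    rot = orientation.matrices()

    for s_idx, (b0, b1) in enumerate(segments):
        j = s_idx  # stance interval index for this stride
        ok = (
            j in ev.index
            and j + 1 in ev.index
            and ev.loc[j, "t_heel_strike"] is not None
            and not pd.isna(ev.loc[j, "t_heel_strike"])
            and ev.loc[j + 1, "t_heel_strike"] is not None
            and not pd.isna(ev.loc[j + 1, "t_heel_strike"])
            and ev.loc[j, "t_toe_off"] is not None
            and not pd.isna(ev.loc[j, "t_toe_off"])
        )
        if not ok:
            logger.info("stride %d flagged invalid (missing events)", s_idx)
            out.append(None)
            continue
        t_hs = float(ev.loc[j, "t_heel_strike"])
        t_hs_next = float(ev.loc[j + 1, "t_heel_strike"])
        t_ffs = float(ev.loc[j, "t_foot_flat_start"])
        t_ffe = float(ev.loc[j, "t_foot_flat_end"])
        t_to = float(ev.loc[j, "t_toe_off"])
        if not (t_hs <= t_ffs <= t_ffe <= t_to <= t_hs_next):
            logger.info("stride %d flagged invalid (event order)", s_idx)
            out.append(None)
            continue

        stride_time = t_hs_next - t_hs
        stance_time = t_to - t_hs
        swing_time = stride_time - stance_time
        loading = t_ffs - t_hs
        foot_flat = t_ffe - t_ffs
        pushing = t_to - t_ffe
        if min(stride_time, stance_time, swing_time, foot_flat) <= 0:
            logger.info("stride %d flagged invalid (degenerate phase)", s_idx)
            out.append(None)
            continue

        disp = pos[b1] - pos[b0]
        stride_length = float(np.hypot(disp[0], disp[1]))
        if stride_length < 1e-6:
            logger.info("stride %d flagged invalid (no displacement)", s_idx)
            out.append(None)
            continue
        forward = disp / np.linalg.norm(disp[:2])

        # foot-flat reference attitude: mid-stance quaternion of interval j
        mid_ff = (int(ev.loc[j, "i_foot_flat_start"]) + int(ev.loc[j, "i_foot_flat_end"])) // 2
        q_ff = orientation.quats[mid_ff]

        def pitch_at(t: float) -> float:
            q = orientation.at_time(t, dt)
            q_rel = _quat_mul(q, _quat_conj(q_ff))
            fvec = _quat_rotate(q_rel, np.array([forward[0], forward[1], 0.0]))
            return -math.degrees(math.asin(float(np.clip(fvec[2], -1.0, 1.0))))

        strike_angle = min(pitch_at(t_hs), 0.0)
        liftoff_angle = pitch_at(t_to)

        # rigid-body heel/toe via the relative rotation and the yaw-aligned
        # foot-flat frame (mounting cancels in q * q_ff^-1)
        r_ff_foot = _foot_flat_frame(forward)
        lo, hi = b0, b1
        q_rel_mats = np.einsum(
            "nij,jk->nik",
            rot[lo:hi],
            _quats_to_matrices(q_ff[None, :])[0].T,
        )
        foot_rot = np.einsum("nij,jk->nik", q_rel_mats, r_ff_foot)
        heel = pos[lo:hi] + foot_rot @ heel_offset
        toe = pos[lo:hi] + foot_rot @ toe_offset
        tseg = np.arange(lo, hi) * dt

        ground_toe_z = float(toe[mid_ff - lo, 2]) if lo <= mid_ff < hi else float(
            np.min(toe[:, 2])
        )
        sw_lo = t_to + 0.35 * (t_hs_next - t_to)
        sw_hi = t_to + 0.75 * (t_hs_next - t_to)
        swing_sel = (tseg >= sw_lo) & (tseg <= sw_hi)
        if not np.any(swing_sel):
            logger.info("stride %d flagged invalid (no swing samples)", s_idx)
            out.append(None)
            continue
        mtc_cm = 100.0 * float(np.min(toe[swing_sel, 2]) - ground_toe_z)

        gait_speed = stride_length / stride_time
        metrics = {
            "stride_time": stride_time,
            "swing_time": swing_time,
            "stance_time": stance_time,
            "swing_ratio": 100.0 * swing_time / stride_time,
            "stance_ratio": 100.0 * stance_time / stride_time,
            "foot_flat_ratio": 100.0 * foot_flat / stance_time,
            "pushing_ratio": 100.0 * pushing / stance_time,
            "loading_ratio": 100.0 * loading / stance_time,
            "stride_length": stride_length,
            "gait_speed": gait_speed,
            "strike_angle": strike_angle,
            "liftoff_angle": liftoff_angle,
            "min_toe_clearance": mtc_cm,
            "heel_path_length": trajectory.path_length_3d(heel),
            "toe_path_length": trajectory.path_length_3d(toe),
        }
        out.append(
            StrideRecord(
                segment=s_idx,
                bounds=(b0, b1),
                events={
                    "t_heel_strike": t_hs,
                    "t_foot_flat_start": t_ffs,
                    "t_foot_flat_end": t_ffe,
                    "t_toe_off": t_to,
                },
                metrics=metrics,
                traj_sensor=pos[lo:hi].copy(),
                traj_heel=heel,
                traj_toe=toe,
                time=tseg,
                forward=np.array([forward[0], forward[1], 0.0]),
            )
        )
    return out


def exclude_boundary_strides(strides: list, k: int = 2) -> list:
    """Drop the first and last ``k`` strides (steady-state analysis)."""
    if len(strides) <= 2 * k:
        raise ValueError(
            f"only {len(strides)} strides; need > {2 * k} — record a longer walk"
        )
    return strides[k : len(strides) - k] if k else list(strides)


def extract_strides(
    rec: ImuRecording,
    config: PipelineConfig | None = None,
) -> list[StrideRecord]:
    """Full chain: recording -> retained, validated stride records."""
    cfg = config or PipelineConfig()
    mask = detect_zupt(
        rec,
        window_s=cfg.zupt_window_s,
        threshold=cfg.zupt_threshold,
        min_duration_s=cfg.zupt_min_duration_s,
        edge_min_s=cfg.zupt_edge_min_s,
    )
    orientation = estimate_orientation(
        rec,
        mask,
        gain=cfg.filter_gain,
        accel_gate=cfg.accel_gate,
        omega_gate=cfg.omega_gate,
    )
    _, pos = reconstruct_displacement(rec, orientation, mask)
    segments = segment_strides(mask)
    events = detect_gait_events(
        rec,
        orientation,
        mask,
        lowpass_cutoff_hz=cfg.lowpass_cutoff_hz,
        search_frac_hs=cfg.event_search_frac_hs,
        search_frac_to=cfg.event_search_frac_to,
    )
    records = compute_stride_metrics(
        segments,
        events,
        pos,
        orientation,
        rec.rate_hz,
        np.asarray(cfg.sensor_to_heel_offset),
        np.asarray(cfg.sensor_to_toe_offset),
    )
    retained = exclude_boundary_strides(records, cfg.boundary_strides_to_drop)
    valid = [r for r in retained if r is not None]
    if len(valid) < len(retained):
        logger.info("dropped %d invalid strides", len(retained) - len(valid))
    return valid
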