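"""Forward model: foot-IMU signals and cohorts with known ground truth.

The simulator inverts the measurement chain: it constructs world-frame foot
kinematics for straight walks directly from the per-stride spatiotemporal
parameters (times, stride length, strike/liftoff angles, minimum toe
clearance), then renders sensor-frame accelerometer and gyroscope streams
under an arbitrary mounting rotation, additive white noise and constant
biases.  Every quantity the analysis pipeline later estimates is therefore
known exactly.

Kinematic construction
----------------------
A walk is a 2 s quiet stand, ``n`` movement intervals separated by foot-flat
(full ground contact) intervals, and a final 2 s stand.  A movement between
foot-flats ``m-1`` and ``m`` is composed of pushing of stance ``m-1``, the
swing, and loading of stance ``m``, so each reconstructed stance aggregates a
single gait cycle's sub-phase durations.  Within a movement:

* foot pitch follows quintic smoothsteps (zero velocity and acceleration at
  every phase knot) from 0 to the liftoff angle at toe-off, to the strike
  angle at heel strike, back to 0 at foot flat;
* sensor forward position follows a single minimum-jerk quintic covering the
  movement, so the net displacement equals the stride length exactly;
* toe height is pinned to the ground during pushing, follows a piecewise
  quintic swing curve whose mid-swing local minimum equals the configured
  minimum toe clearance exactly, and during loading follows the rigid foot
  pivoting on the grounded heel;
* short compact vertical position dips (~1 cm, ~0.1 s) are centred at the
  true heel-strike and toe-off instants.  They leave net displacement and
  pitch untouched but give the acceleration signals the sharp impact peaks
  that real foot-worn IMUs show, which is what the event detector keys on.

Positions are evaluated on a 5x-oversampled grid and differentiated by
central differences, so the rendered inertial signals are consistent with
the stored ground-truth trajectories to discretisation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GRAVITY
from .io import ImuRecording

__all__ = [
    "StrideParams",
    "GroupProfile",
    "GroundTruth",
    "WalkKinematics",
    "CONTROL_PROFILE",
    "CI_PROFILE",
    "simulate_stride_kinematics",
    "synthesize_imu",
    "simulate_walk",
    "simulate_cohort",
    "draw_stride_metrics",
]

# Metrics drawn directly by the generator; everything else is derived.
CORE_METRICS = (
    "stride_time",
    "stance_ratio",
    "loading_ratio",
    "foot_flat_ratio",
    "pushing_ratio",
    "stride_length",
    "strike_angle",
    "liftoff_angle",
    "min_toe_clearance",
    "heel_path_length",
    "toe_path_length",
)

DEFAULT_HEEL_OFFSET = np.array([-0.12, 0.0, -0.07])
DEFAULT_TOE_OFFSET = np.array([0.13, 0.0, -0.07])


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class StrideParams:
    """Ground-truth parameters of one gait cycle (SI units, angles in deg)."""

    stride_time: float
    stance_time: float
    loading_time: float
    foot_flat_time: float
    pushing_time: float
    stride_length: float
    strike_angle: float  # deg, negative
    liftoff_angle: float  # deg, positive
    min_toe_clearance: float  # m

    def __post_init__(self) -> None:
        if not self.stance_time < self.stride_time:
            raise ValueError("stance_time must be < stride_time")
        s = self.loading_time + self.foot_flat_time + self.pushing_time
        if abs(s - self.stance_time) > 1e-9:
            raise ValueError("sub-phase times must sum to stance_time")
        if self.stride_length <= 0:
            raise ValueError("stride_length must be positive")
        if self.strike_angle >= 0:
            raise ValueError("strike_angle must be negative")
        if self.liftoff_angle <= 0:
            raise ValueError("liftoff_angle must be positive")
        if self.min_toe_clearance <= 0:
            raise ValueError("min_toe_clearance must be positive")

    @property
    def swing_time(self) -> float:
        return self.stride_time - self.stance_time


@dataclass
class GroupProfile:
    """Population statistics one cohort group is generated from.

    ``single`` holds per-metric (mean, SD) of subject-level single-task
    means; ``dte`` per-metric (mean, SD) of subject-level dual-task effects
    in percent; ``cv`` stride-to-stride coefficient-of-variation targets in
    percent; ``si`` left/right symmetry-index targets in percent.  The MoCA
    link is ``moca = moca_intercept + moca_slope_per_dte * (speed DTE -
    moca_dte_center) + noise``, i.e. the configured slope is the
    within-group slope of MoCA on the subject's true speed DTE.
    """

    label: str
    single: dict[str, tuple[float, float]]
    dte: dict[str, tuple[float, float]]
    cv: dict[str, float]
    si: dict[str, float]
    moca_intercept: float
    moca_slope_per_dte: float = 0.114
    moca_noise_sd: float = 1.2
    moca_dte_center: float = 0.0
    education: tuple[float, float] = (12.0, 3.0)

    def __post_init__(self) -> None:
        for name, table in (("single", self.single), ("dte", self.dte)):
            for metric, (mean, sd) in table.items():
                if sd < 0:
                    raise ValueError(f"{name}[{metric}] SD must be >= 0")
        for metric, v in {**self.cv, **self.si}.items():
            if v < 0:
                raise ValueError(f"cv/si targets must be >= 0 ({metric})")


@dataclass
class FootTruth:
    """Per-foot ground truth: sampled kinematics plus stride bookkeeping."""

    time: np.ndarray
    pos_sensor: np.ndarray  # (n, 3) world
    pos_heel: np.ndarray
    pos_toe: np.ndarray
    vel_sensor: np.ndarray
    pitch: np.ndarray  # rad
    zupt_intervals: list[tuple[int, int]]  # half-open sample ranges
    events: pd.DataFrame  # per analyzable stride: event times/indices
    strides: pd.DataFrame  # per analyzable stride: true metric values


@dataclass
class GroundTruth:
    """Ground truth for one walk (or a pair of feet)."""

    feet: dict[str, FootTruth] = field(default_factory=dict)


@dataclass
class WalkKinematics:
    """World-frame kinematics of one foot before sensor rendering."""

    dt: float
    time: np.ndarray
    pos: np.ndarray  # sensor position (n, 3)
    vel: np.ndarray
    acc: np.ndarray
    pitch: np.ndarray  # rad
    pitch_rate: np.ndarray  # rad/s
    pos_heel: np.ndarray
    pos_toe: np.ndarray
    zupt_intervals: list[tuple[int, int]]
    events: pd.DataFrame
    strides: pd.DataFrame


# --------------------------------------------------------------------------
# smooth primitives
# --------------------------------------------------------------------------


def _smoothstep(s: np.ndarray) -> np.ndarray:
    """Septic smoothstep: zero 1st-3rd derivatives at both ends.

    Keeps the assembled walk jerk-continuous across phase knots, as real
    foot motion is; lower-order knots would put spurious high-frequency
    content into the rendered inertial signals.
    """
    s = np.clip(s, 0.0, 1.0)
    return s**4 * (35.0 - 84.0 * s + 70.0 * s**2 - 20.0 * s**3)


def _bump(u: np.ndarray) -> np.ndarray:
    """Compact C2 unit bump on |u| < 1 (cos^4 window)."""
    out = np.zeros_like(u)
    m = np.abs(u) < 1.0
    out[m] = np.cos(0.5 * np.pi * u[m]) ** 4
    return out


def _rot_z_component(theta: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of Ry(theta) @ v for a fixed foot-frame vector v."""
    return -v[0] * np.sin(theta) + v[2] * np.cos(theta)


def _ry_matrices(theta: np.ndarray) -> np.ndarray:
    """(n, 3, 3) rotation matrices about +y (foot -> world for pitch)."""
    c, s = np.cos(theta), np.sin(theta)
    out = np.zeros((len(theta), 3, 3))
    out[:, 0, 0] = c
    out[:, 0, 2] = s
    out[:, 1, 1] = 1.0
    out[:, 2, 0] = -s
    out[:, 2, 2] = c
    return out


# --------------------------------------------------------------------------
# walk construction
# --------------------------------------------------------------------------


@dataclass
class _Movement:
    """One movement interval: pushing_{k-1} + swing_{k-1} + loading_k."""

    t0: float
    push: float
    swing: float
    load: float
    length: float  # net forward displacement
    liftoff: float  # rad, > 0 (cycle k-1)
    strike: float  # rad, < 0 (cycle k)
    clearance: float  # m (cycle k-1)
    x0: float  # forward position at movement start

    @property
    def duration(self) -> float:
        return self.push + self.swing + self.load


def _movement_curves(
    tau: np.ndarray,
    mv: _Movement,
    o_heel: np.ndarray,
    o_toe: np.ndarray,
    impact_hs: float,
    impact_to: float,
    impact_halfwidth: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate (x, z, pitch) of the sensor at movement-local times tau."""
    P, W, L, M = mv.push, mv.swing, mv.load, mv.duration
    aL, aS = mv.liftoff, mv.strike
    h_lever = o_toe - o_heel
    # keep the transients inside the movement even for short sub-phases
    hw = min(impact_halfwidth, 0.45 * P, 0.45 * L)

    pitch = np.where(
        tau < P,
        aL * _smoothstep(tau / P),
        np.where(
            tau < P + W,
            aL + (aS - aL) * _smoothstep((tau - P) / W),
            aS * (1.0 - _smoothstep((tau - P - W) / L)),
        ),
    )

    x = mv.x0 + mv.length * _smoothstep(tau / M)

    # toe height: grounded in pushing; swing curve with exact mid-swing
    # minimum; rigid pivot on the grounded heel during loading
    z_hs = float(_rot_z_component(np.array([aS]), h_lever)[0])
    z_peak = max(0.03, mv.clearance + 0.01)
    sw = np.clip((tau - P) / W, 0.0, 1.0)
    z_toe_swing = np.where(
        sw < 0.32,
        z_peak * _smoothstep(sw / 0.32),
        np.where(
            sw < 0.62,
            z_peak + (mv.clearance - z_peak) * _smoothstep((sw - 0.32) / 0.30),
            mv.clearance + (z_hs - mv.clearance) * _smoothstep((sw - 0.62) / 0.38),
        ),
    )
    z_toe = np.where(
        tau < P,
        0.0,
        np.where(tau < P + W, z_toe_swing, _rot_z_component(pitch, h_lever)),
    )

    z = np.where(
        tau < P + W,
        z_toe - _rot_z_component(pitch, o_toe),
        -_rot_z_component(pitch, o_heel),
    )

    # impact transients: compact downward position dips at TO and HS; a
    # steeper strike drops the foot further and lands harder, so the
    # transient amplitude scales with the strike (resp. liftoff) angle
    a_to = impact_to * max(1.0, math.sin(abs(aL)) / math.sin(math.radians(50.0)))
    a_hs = impact_hs * max(1.0, math.sin(abs(aS)) / math.sin(math.radians(20.0)))
    z = z - a_to * _bump((tau - P) / hw)
    z = z - a_hs * _bump((tau - (P + W)) / hw)
    return x, z, pitch


def _build_walk(
    cycles: list[StrideParams],
    dt: float,
    o_heel: np.ndarray,
    o_toe: np.ndarray,
    stand_s: float = 2.0,
    impact_hs: float = 0.030,
    impact_to: float = 0.028,
    impact_halfwidth: float = 0.05,
) -> WalkKinematics:
    """Assemble a straight walk from ``K+1`` cycle draws (``K`` movements).

    ``cycles[k]`` supplies pushing/swing/length/liftoff/clearance of
    movement ``k+1`` and loading/strike of movement ``k``; the interior
    foot-flat interval ``k`` lasts ``cycles[k].foot_flat_time``.  Analyzable
    ground-truth strides are cycles ``1 .. K-1``.
    """
    if abs(o_heel[2] - o_toe[2]) > 1e-12:
        raise ValueError("heel and toe offsets must share the sole-plane z")
    K = len(cycles) - 1
    if K < 1:
        raise ValueError("need at least 2 cycle draws (1 movement)")
    h0 = -float(o_toe[2])

    # timeline: [stand+FF_0][mv 1][FF_1][mv 2]...[mv K][FF_K+stand]
    movements: list[_Movement] = []
    ff_bounds: list[tuple[float, float]] = []
    t = stand_s + cycles[0].foot_flat_time
    ff_bounds.append((0.0, t))
    x = 0.0
    for m in range(1, K + 1):
        prev, cur = cycles[m - 1], cycles[m]
        mv = _Movement(
            t0=t,
            push=prev.pushing_time,
            swing=prev.swing_time,
            load=cur.loading_time,
            length=prev.stride_length,
            liftoff=math.radians(prev.liftoff_angle),
            strike=math.radians(cur.strike_angle),
            clearance=prev.min_toe_clearance,
            x0=x,
        )
        movements.append(mv)
        t += mv.duration
        x += mv.length
        ff_end = t + (cur.foot_flat_time if m < K else cur.foot_flat_time + stand_s)
        ff_bounds.append((t, ff_end))
        t = ff_end
    total = t

    # oversampled evaluation then central differences
    over = 5
    dt_f = dt / over
    n_f = int(round(total / dt_f)) + 1
    tf = np.arange(n_f) * dt_f
    xf = np.zeros(n_f)
    zf = np.full(n_f, h0)
    pf = np.zeros(n_f)
    for mv in movements:
        sel = (tf >= mv.t0) & (tf < mv.t0 + mv.duration)
        xi, zi, pi = _movement_curves(
            tf[sel] - mv.t0, mv, o_heel, o_toe, impact_hs, impact_to, impact_halfwidth
        )
        xf[sel], zf[sel], pf[sel] = xi, zi, pi
    # foot-flat forward positions
    for (a, b), xpos in zip(ff_bounds, np.concatenate([[0.0], np.cumsum([m.length for m in movements])])):
        sel = (tf >= a) & (tf < b)
        xf[sel] = xpos
    xf[-1] = sum(m.length for m in movements)

    pos_f = np.column_stack([xf, np.zeros(n_f), zf])
    vel_f = np.gradient(pos_f, dt_f, axis=0)
    acc_f = np.gradient(vel_f, dt_f, axis=0)
    rate_f = np.gradient(pf, dt_f)

    idx = np.arange(0, n_f, over)
    time = tf[idx]
    pos, vel, acc = pos_f[idx], vel_f[idx], acc_f[idx]
    pitch, pitch_rate = pf[idx], rate_f[idx]

    rot = _ry_matrices(pitch)
    pos_heel = pos + rot @ o_heel
    pos_toe = pos + rot @ o_toe

    to_idx = lambda s: int(round(s / dt))  # noqa: E731
    zupt = [(to_idx(a), min(to_idx(b), len(time))) for a, b in ff_bounds]

    ev_rows, st_rows = [], []
    for k in range(1, K):  # analyzable cycles
        cyc = cycles[k]
        mv_k, mv_next = movements[k - 1], movements[k]
        t_hs = mv_k.t0 + mv_k.push + mv_k.swing
        t_to = mv_next.t0 + mv_next.push
        t_ffs, t_ffe = ff_bounds[k]
        ev_rows.append(
            {
                "segment": k,
                "t_heel_strike": t_hs,
                "t_foot_flat_start": t_ffs,
                "t_foot_flat_end": t_ffe,
                "t_toe_off": t_to,
                "i_heel_strike": to_idx(t_hs),
                "i_foot_flat_start": to_idx(t_ffs),
                "i_foot_flat_end": to_idx(t_ffe),
                "i_toe_off": to_idx(t_to),
            }
        )
        st_rows.append(
            {
                "segment": k,
                "stride_time": cyc.stride_time,
                "stance_time": cyc.stance_time,
                "swing_time": cyc.swing_time,
                "swing_ratio": 100.0 * cyc.swing_time / cyc.stride_time,
                "stance_ratio": 100.0 * cyc.stance_time / cyc.stride_time,
                "foot_flat_ratio": 100.0 * cyc.foot_flat_time / cyc.stance_time,
                "pushing_ratio": 100.0 * cyc.pushing_time / cyc.stance_time,
                "loading_ratio": 100.0 * cyc.loading_time / cyc.stance_time,
                "stride_length": cyc.stride_length,
                "gait_speed": cyc.stride_length / cyc.stride_time,
                "strike_angle": cyc.strike_angle,
                "liftoff_angle": cyc.liftoff_angle,
                "min_toe_clearance": 100.0 * cyc.min_toe_clearance,  # cm
            }
        )

    return WalkKinematics(
        dt=dt,
        time=time,
        pos=pos,
        vel=vel,
        acc=acc,
        pitch=pitch,
        pitch_rate=pitch_rate,
        pos_heel=pos_heel,
        pos_toe=pos_toe,
        zupt_intervals=zupt,
        events=pd.DataFrame(ev_rows),
        strides=pd.DataFrame(st_rows),
    )


def simulate_stride_kinematics(params: StrideParams, dt: float = 0.01) -> WalkKinematics:
    """World-frame kinematics of a single stride cycle.

    The cycle parameters are replicated for the lead-in/lead-out context so
    the single movement interval realises exactly this cycle's pushing,
    swing, loading, stride length, angles and toe clearance.
    """
    return _build_walk([params, params], dt, DEFAULT_HEEL_OFFSET, DEFAULT_TOE_OFFSET, stand_s=0.5)


# --------------------------------------------------------------------------
# sensor rendering
# --------------------------------------------------------------------------


def _random_mounting(rng: np.random.Generator, max_angle_deg: float = 40.0) -> np.ndarray:
    """Random rotation matrix with angle uniform in [0, max_angle_deg]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_angle_deg))
    return _axis_angle_matrix(axis, angle)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def synthesize_imu(
    kin: WalkKinematics,
    mounting: np.ndarray | None = None,
    noise_accel: float = 0.05,
    noise_gyro: float = 0.005,
    accel_bias: np.ndarray | None = None,
    gyro_bias: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    foot: str = "left",
    condition: str = "single",
) -> tuple[ImuRecording, FootTruth]:
    """Render sensor-frame IMU streams from world-frame kinematics.

    ``mounting`` is the constant sensor-in-foot rotation matrix (foot ->
    sensor axes are ``mounting.T``); noise and biases are applied after
    rotation into the sensor frame.  The returned ground truth keeps the
    unrotated world-frame kinematics.
    """
    rng = rng or np.random.default_rng(0)
    if mounting is None:
        mounting = np.eye(3)
    mounting = np.asarray(mounting, dtype=float)
    if not np.allclose(mounting @ mounting.T, np.eye(3), atol=1e-9) or not math.isclose(
        float(np.linalg.det(mounting)), 1.0, abs_tol=1e-9
    ):
        raise ValueError("mounting must be a proper rotation matrix")

    n = len(kin.time)
    rot_foot = _ry_matrices(kin.pitch)  # foot -> world
    rot_sensor = rot_foot @ mounting  # sensor -> world

    g_world = np.array([0.0, 0.0, -GRAVITY])
    f_world = kin.acc - g_world  # specific force
    accel = np.einsum("nij,nj->ni", rot_sensor.transpose(0, 2, 1), f_world)
    omega_world = np.column_stack(
        [np.zeros(n), kin.pitch_rate, np.zeros(n)]
    )
    gyro = np.einsum("nij,nj->ni", rot_sensor.transpose(0, 2, 1), omega_world)

    if accel_bias is None:
        accel_bias = rng.normal(0.0, 0.02, size=3)
    if gyro_bias is None:
        gyro_bias = rng.normal(0.0, 0.002, size=3)
    accel = accel + accel_bias + rng.normal(0.0, noise_accel, size=(n, 3))
    gyro = gyro + gyro_bias + rng.normal(0.0, noise_gyro, size=(n, 3))

    rec = ImuRecording(
        subject_id=subject_id,
        foot=foot,
        condition=condition,
        time=kin.time.copy(),
        accel=accel,
        gyro=gyro,
        rate_hz=1.0 / kin.dt,
    )
    truth = FootTruth(
        time=kin.time,
        pos_sensor=kin.pos,
        pos_heel=kin.pos_heel,
        pos_toe=kin.pos_toe,
        vel_sensor=kin.vel,
        pitch=kin.pitch,
        zupt_intervals=kin.zupt_intervals,
        events=kin.events,
        strides=kin.strides,
    )
    return rec, truth


# --------------------------------------------------------------------------
# stride-parameter draws
# --------------------------------------------------------------------------

_RATIO_TRIPLE = ("loading_ratio", "foot_flat_ratio", "pushing_ratio")


def _sanitize_means(m: dict[str, float]) -> dict[str, float]:
    """Clip a metric-mean dict into the physically valid region."""
    out = dict(m)
    out["stride_time"] = max(out["stride_time"], 0.6)
    out["stance_ratio"] = float(np.clip(out["stance_ratio"], 55.0, 85.0))
    total = sum(max(out[k], 5.0) for k in _RATIO_TRIPLE)
    for k in _RATIO_TRIPLE:
        out[k] = 100.0 * max(out[k], 5.0) / total
    out["stride_length"] = max(out["stride_length"], 0.3)
    out["strike_angle"] = min(out["strike_angle"], -6.0)
    out["liftoff_angle"] = max(out["liftoff_angle"], 10.0)
    # clearance cannot exceed the toe height the strike angle implies at
    # heel contact (heel-toe lever ~25 cm), or the mid-swing local minimum
    # would no longer be the minimum
    cap = 0.8 * 25.0 * math.sin(math.radians(abs(out["strike_angle"])))
    out["min_toe_clearance"] = float(np.clip(out["min_toe_clearance"], 0.3, cap))  # cm
    out["heel_path_length"] = max(out["heel_path_length"], 0.3)
    out["toe_path_length"] = max(out["toe_path_length"], 0.3)
    return out


def _subject_state(profile: GroupProfile, rng: np.random.Generator) -> dict:
    """Draw one subject: single-task means, DTEs, side-asymmetry factors."""
    single = {
        m: rng.normal(mu, sd) for m, (mu, sd) in profile.single.items()
    }
    single = _sanitize_means(single)
    dte = {m: rng.normal(mu, sd) for m, (mu, sd) in profile.dte.items()}
    dual = {m: single[m] * (1.0 + np.clip(dte[m], -80.0, 150.0) / 100.0) for m in single}
    dual = _sanitize_means(dual)
    asym = {
        m: rng.normal(0.0, profile.si.get(m, 0.0) / 100.0 * math.sqrt(math.pi / 2.0))
        for m in single
    }
    # true speed DTE implied by the drawn stride length / time DTEs
    speed_s = single["stride_length"] / single["stride_time"]
    speed_d = dual["stride_length"] / dual["stride_time"]
    true_speed_dte = 100.0 * (speed_d - speed_s) / speed_s
    return {"single": single, "dual": dual, "asym": asym, "speed_dte": true_speed_dte}


def draw_stride_metrics(
    means: dict[str, float],
    cv: dict[str, float],
    asym: dict[str, float],
    side: str,
    n_strides: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-stride metric draws for one foot around subject condition means.

    The side factor splits the subject mean as ``mean * (1 +/- r/2)`` so the
    symmetry index of the per-side means equals ``|r| * 100`` exactly;
    stride-to-stride spread follows the CV targets (capped at 50% relative
    so signed metrics keep their sign).
    """
    sign = +0.5 if side == "left" else -0.5
    rows = {}
    for m, mu in means.items():
        mu_side = mu * (1.0 + sign * asym.get(m, 0.0))
        rel = min(abs(cv.get(m, 0.0)), 50.0) / 100.0
        rows[m] = rng.normal(mu_side, abs(mu_side) * rel, size=n_strides)
    df = pd.DataFrame(rows)
    for i in range(len(df)):
        fixed = _sanitize_means({k: float(df.iloc[i][k]) for k in df.columns})
        for k, v in fixed.items():
            df.iat[i, df.columns.get_loc(k)] = v
    # derived metrics
    df["stance_time"] = df["stance_ratio"] / 100.0 * df["stride_time"]
    df["swing_time"] = df["stride_time"] - df["stance_time"]
    df["swing_ratio"] = 100.0 - df["stance_ratio"]
    df["gait_speed"] = df["stride_length"] / df["stride_time"]
    return df


def _stride_params_from_row(row: pd.Series) -> StrideParams:
    stance = float(row["stance_time"])
    lr = float(row["loading_ratio"])
    fr = float(row["foot_flat_ratio"])
    pr = float(row["pushing_ratio"])
    loading = lr / 100.0 * stance
    foot_flat = fr / 100.0 * stance
    pushing = stance - loading - foot_flat
    # full ground contact shorter than ~0.18 s is not seen in this slow,
    # mobility-impaired population and would be unresolvable to a windowed
    # stationarity detector; redistribute into loading/pushing if needed
    if foot_flat < 0.18:
        deficit = 0.18 - foot_flat
        total = loading + pushing
        loading -= deficit * loading / total
        pushing -= deficit * pushing / total
        foot_flat = 0.18
    return StrideParams(
        stride_time=float(row["stride_time"]),
        stance_time=stance,
        loading_time=loading,
        foot_flat_time=foot_flat,
        pushing_time=pushing,
        stride_length=float(row["stride_length"]),
        strike_angle=float(row["strike_angle"]),
        liftoff_angle=float(row["liftoff_angle"]),
        min_toe_clearance=float(row["min_toe_clearance"]) / 100.0,  # cm -> m
    )


def simulate_walk(
    profile: GroupProfile,
    condition: str = "single",
    n_strides: int | None = None,
    seed: int | np.random.Generator = 0,
    noise_accel: float = 0.05,
    noise_gyro: float = 0.005,
    accel_bias_sd: float = 0.02,
    gyro_bias_sd: float = 0.002,
    mounting: str | np.ndarray | None = "random",
    subject_id: str = "sim",
    dt: float = 0.01,
    boundary_strides_to_drop: int = 2,
) -> tuple[dict[str, ImuRecording], GroundTruth]:
    """Simulate one straight 20 m pass: left and right foot recordings.

    Stride parameters are drawn per the profile (dual condition applies the
    profile's DTE shifts; spread per the CV targets; left/right offsets per
    the symmetry-index targets).  Each foot is an independent straight walk
    (the two sensors are not temporally synced, matching the measurement
    setup the pipeline assumes).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if condition not in ("single", "dual"):
        raise ValueError("condition must be 'single' or 'dual'")
    subject = _subject_state(profile, rng)
    return _render_subject_walk(
        subject,
        profile,
        condition,
        n_strides,
        rng,
        noise_accel=noise_accel,
        noise_gyro=noise_gyro,
        accel_bias_sd=accel_bias_sd,
        gyro_bias_sd=gyro_bias_sd,
        mounting=mounting,
        subject_id=subject_id,
        dt=dt,
        boundary_strides_to_drop=boundary_strides_to_drop,
    )


def _render_subject_walk(
    subject: dict,
    profile: GroupProfile,
    condition: str,
    n_strides: int | None,
    rng: np.random.Generator,
    noise_accel: float = 0.05,
    noise_gyro: float = 0.005,
    accel_bias_sd: float = 0.02,
    gyro_bias_sd: float = 0.002,
    mounting: str | np.ndarray | None = "random",
    subject_id: str = "sim",
    dt: float = 0.01,
    boundary_strides_to_drop: int = 2,
) -> tuple[dict[str, ImuRecording], GroundTruth]:
    means = subject[condition]
    if n_strides is None:
        n_strides = int(np.clip(round(20.0 / means["stride_length"]), 9, 24))
    if n_strides < 5 + 2 * boundary_strides_to_drop:
        raise ValueError(
            f"n_strides={n_strides} too small to survive boundary exclusion "
            f"(need >= {5 + 2 * boundary_strides_to_drop})"
        )

    recs: dict[str, ImuRecording] = {}
    truth = GroundTruth()
    for foot in ("left", "right"):
        table = draw_stride_metrics(
            means, profile.cv, subject["asym"], foot, n_strides + 1, rng
        )
        cycles = [_stride_params_from_row(table.iloc[i]) for i in range(n_strides + 1)]
        kin = _build_walk(cycles, dt, DEFAULT_HEEL_OFFSET, DEFAULT_TOE_OFFSET)
        if isinstance(mounting, str) and mounting == "random":
            mnt = _random_mounting(rng)
        elif mounting is None:
            mnt = np.eye(3)
        else:
            mnt = np.asarray(mounting, dtype=float)
        rec, ft = synthesize_imu(
            kin,
            mounting=mnt,
            noise_accel=noise_accel,
            noise_gyro=noise_gyro,
            accel_bias=rng.normal(0.0, accel_bias_sd, size=3),
            gyro_bias=rng.normal(0.0, gyro_bias_sd, size=3),
            rng=rng,
            subject_id=subject_id,
            foot=foot,
            condition=condition,
        )
        recs[foot] = rec
        truth.feet[foot] = ft
    return recs, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def _draw_moca(
    profile: GroupProfile,
    speed_dte: float,
    rng: np.random.Generator,
    cutoff: int = 24,
    enforce_cutoff: bool = True,
    max_tries: int = 200,
) -> int:
    base = profile.moca_intercept + profile.moca_slope_per_dte * (
        speed_dte - profile.moca_dte_center
    )
    for _ in range(max_tries):
        score = int(np.clip(round(base + rng.normal(0.0, profile.moca_noise_sd)), 0, 30))
        if not enforce_cutoff:
            return score
        if profile.label == "control" and score >= cutoff:
            return score
        if profile.label != "control" and score < cutoff:
            return score
    raise ValueError(
        "MoCA distribution cannot respect the group cutoff; adjust "
        "moca_intercept / moca_noise_sd for this profile"
    )


def simulate_cohort(
    n_control: int = 13,
    n_ci: int = 16,
    profiles: tuple[GroupProfile, GroupProfile] | None = None,
    seed: int | np.random.Generator = 0,
    mode: str = "parameter",
    n_strides: int = 16,
    moca_cutoff: int = 24,
    enforce_cutoff: bool = True,
    noise_accel: float = 0.05,
    noise_gyro: float = 0.005,
) -> dict:
    """Simulate a two-group cohort (control vs cognitively impaired).

    ``mode='parameter'`` draws per-stride metric values directly (no signal
    synthesis) — the generative stride model is identical to signal mode but
    skips the measurement chain, which makes large Monte-Carlo studies
    tractable.  ``mode='signal'`` additionally renders IMU recordings for
    every subject x condition x foot.

    Returns a dict with ``metadata`` (subject_id, group, moca_raw,
    education_years, true speed DTE), ``stride_tables`` mapping
    (subject_id, condition, foot) -> per-stride metric DataFrame (parameter
    mode), and ``recordings`` / ``truths`` (signal mode).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profiles is None:
        profiles = (CONTROL_PROFILE, CI_PROFILE)
    if n_control < 2 or n_ci < 2:
        raise ValueError("need at least 2 subjects per group")
    if mode not in ("parameter", "signal"):
        raise ValueError("mode must be 'parameter' or 'signal'")

    meta_rows = []
    stride_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    recordings: dict[tuple[str, str, str], ImuRecording] = {}
    truths: dict[tuple[str, str], GroundTruth] = {}

    sid = 0
    for profile, count in ((profiles[0], n_control), (profiles[1], n_ci)):
        for _ in range(count):
            sid += 1
            subject_id = f"S{sid:03d}"
            if mode == "signal":
                subject = _subject_state(profile, rng)
                for condition in ("single", "dual"):
                    recs, truth = _render_subject_walk(
                        subject,
                        profile,
                        condition,
                        n_strides,
                        rng,
                        noise_accel=noise_accel,
                        noise_gyro=noise_gyro,
                        subject_id=subject_id,
                    )
                    for foot, rec in recs.items():
                        recordings[(subject_id, condition, foot)] = rec
                    truths[(subject_id, condition)] = truth
            else:
                subject = _subject_state(profile, rng)
                for condition in ("single", "dual"):
                    for foot in ("left", "right"):
                        stride_tables[(subject_id, condition, foot)] = draw_stride_metrics(
                            subject[condition],
                            profile.cv,
                            subject["asym"],
                            foot,
                            n_strides,
                            rng,
                        )
            education = max(5.0, rng.normal(*profile.education))
            moca = _draw_moca(
                profile,
                subject["speed_dte"],
                rng,
                cutoff=moca_cutoff,
                enforce_cutoff=enforce_cutoff,
            )
            meta_rows.append(
                {
                    "subject_id": subject_id,
                    "group": "control" if profile.label == "control" else "ci",
                    "moca_raw": moca,
                    "education_years": round(education),
                    "true_speed_dte": subject["speed_dte"],
                }
            )

    return {
        "metadata": pd.DataFrame(meta_rows),
        "stride_tables": stride_tables,
        "recordings": recordings,
        "truths": truths,
    }


def draw_speed_dte(
    profile: GroupProfile,
    n_subjects: int,
    rng: np.random.Generator,
    n_strides: int = 16,
) -> np.ndarray:
    """Vectorized per-subject *recovered* speed dual-task effects.

    Follows the same generative hierarchy as :func:`simulate_walk` —
    subject-level single-task means and DTE draws for stride time and
    length, stride-level draws at the CV targets over both feet — but
    computes only the gait-speed chain, so thousand-replicate power and
    type-I studies run in seconds.  The returned DTE is the one the
    analysis recovers: computed from per-condition pooled mean speeds.
    """
    mu_t, sd_t = profile.single["stride_time"]
    mu_l, sd_l = profile.single["stride_length"]
    dmu_t, dsd_t = profile.dte["stride_time"]
    dmu_l, dsd_l = profile.dte["stride_length"]
    cv_t = min(abs(profile.cv.get("stride_time", 0.0)), 50.0) / 100.0
    cv_l = min(abs(profile.cv.get("stride_length", 0.0)), 50.0) / 100.0

    t_s = np.maximum(rng.normal(mu_t, sd_t, n_subjects), 0.6)
    l_s = np.maximum(rng.normal(mu_l, sd_l, n_subjects), 0.3)
    t_d = np.maximum(t_s * (1 + rng.normal(dmu_t, dsd_t, n_subjects) / 100.0), 0.6)
    l_d = np.maximum(l_s * (1 + rng.normal(dmu_l, dsd_l, n_subjects) / 100.0), 0.3)

    def pooled_speed(t_mean: np.ndarray, l_mean: np.ndarray) -> np.ndarray:
        shape = (n_subjects, 2 * n_strides)  # both feet pooled
        t = rng.normal(t_mean[:, None], np.abs(t_mean[:, None]) * cv_t, shape)
        length = rng.normal(l_mean[:, None], np.abs(l_mean[:, None]) * cv_l, shape)
        t = np.maximum(t, 0.4)
        length = np.maximum(length, 0.2)
        return (length / t).mean(axis=1)

    v_s = pooled_speed(t_s, l_s)
    v_d = pooled_speed(t_d, l_d)
    return 100.0 * (v_d - v_s) / v_s


# --------------------------------------------------------------------------
# default group profiles (two-group cohort of older adults with mobility
# limitations; single-task means/SDs, dual-task effects, dual-task CV and
# asymmetry targets)
# --------------------------------------------------------------------------

CONTROL_PROFILE = GroupProfile(
    label="control",
    single={
        "stride_time": (1.15, 0.16),
        "stance_ratio": (68.94, 2.01),
        "loading_ratio": (30.36, 5.0),
        "foot_flat_ratio": (37.67, 6.25),
        "pushing_ratio": (31.97, 3.25),
        "stride_length": (1.10, 0.19),
        "strike_angle": (-20.20, 7.94),
        "liftoff_angle": (53.69, 8.77),
        "min_toe_clearance": (1.14, 0.63),  # cm
        "heel_path_length": (1.31, 0.20),
        "toe_path_length": (1.21, 0.23),
    },
    dte={
        "stride_time": (6.49, 6.63),
        "stance_ratio": (1.57, 1.37),
        "loading_ratio": (-8.18, 6.3),
        "foot_flat_ratio": (7.99, 7.92),
        "pushing_ratio": (-2.50, 6.45),
        "stride_length": (-9.07, 7.48),
        "strike_angle": (-17.04, 20.04),
        "liftoff_angle": (-6.05, 5.28),
        "min_toe_clearance": (-6.35, 18.26),
        "heel_path_length": (-7.28, 5.85),
        "toe_path_length": (-9.06, 7.23),
    },
    cv={
        "stride_time": 4.81,
        "stance_ratio": 2.81,
        "loading_ratio": 12.90,
        "foot_flat_ratio": 11.75,
        "pushing_ratio": 9.80,
        "stride_length": 5.62,
        "strike_angle": 29.18,
        "liftoff_angle": 8.57,
        "min_toe_clearance": 42.57,
        "heel_path_length": 4.70,
        "toe_path_length": 5.55,
    },
    si={
        "stride_time": 0.35,
        "stance_ratio": 1.74,
        "loading_ratio": 7.47,
        "foot_flat_ratio": 10.01,
        "pushing_ratio": 7.95,
        "stride_length": 1.57,
        "strike_angle": 29.78,
        "liftoff_angle": 5.55,
        "min_toe_clearance": 48.14,
        "heel_path_length": 2.00,
        "toe_path_length": 2.79,
    },
    moca_intercept=25.7,
    moca_dte_center=-13.94,
    education=(13.3, 4.2),
)

CI_PROFILE = GroupProfile(
    label="ci",
    single={
        "stride_time": (1.18, 0.19),
        "stance_ratio": (67.64, 1.91),
        "loading_ratio": (31.35, 5.5),
        "foot_flat_ratio": (34.56, 6.73),
        "pushing_ratio": (34.09, 4.88),
        "stride_length": (1.06, 0.18),
        "strike_angle": (-21.13, 7.09),
        "liftoff_angle": (50.38, 7.29),
        "min_toe_clearance": (1.60, 1.10),
        "heel_path_length": (1.29, 0.21),
        "toe_path_length": (1.19, 0.24),
    },
    dte={
        "stride_time": (14.28, 10.69),
        "stance_ratio": (2.18, 1.58),
        "loading_ratio": (-9.89, 10.47),
        "foot_flat_ratio": (21.74, 18.37),
        "pushing_ratio": (-9.70, 8.44),
        "stride_length": (-15.33, 9.14),
        "strike_angle": (-25.24, 30.65),
        "liftoff_angle": (-13.56, 9.58),
        "min_toe_clearance": (-18.36, 22.54),
        "heel_path_length": (-12.23, 6.21),
        "toe_path_length": (-14.60, 7.63),
    },
    cv={
        "stride_time": 7.23,
        "stance_ratio": 3.63,
        "loading_ratio": 16.81,
        "foot_flat_ratio": 14.71,
        "pushing_ratio": 14.45,
        "stride_length": 7.63,
        "strike_angle": 8.45,
        "liftoff_angle": 13.00,
        "min_toe_clearance": 44.56,
        "heel_path_length": 6.47,
        "toe_path_length": 7.41,
    },
    si={
        "stride_time": 0.52,
        "stance_ratio": 2.72,
        "loading_ratio": 13.19,
        "foot_flat_ratio": 13.30,
        "pushing_ratio": 14.06,
        "stride_length": 2.79,
        "strike_angle": 2.01,
        "liftoff_angle": 11.09,
        "min_toe_clearance": 40.22,
        "heel_path_length": 3.16,
        "toe_path_length": 3.53,
    },
    moca_intercept=21.0,
    moca_dte_center=-24.39,
    education=(11.5, 1.9),
)
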