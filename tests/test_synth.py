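import numpy as np
import pytest

from dualgait.config import GRAVITY
from dualgait.synth import (
    CI_PROFILE,
    CONTROL_PROFILE,
    StrideParams,
    draw_stride_metrics,
    simulate_cohort,
    simulate_stride_kinematics,
    simulate_walk,
    synthesize_imu,
    _axis_angle_matrix,
)
from tests.conftest import CLEAN


@pytest.fixture(scope="module")
def single_stride():
    params = StrideParams(
        stride_time=1.15,
        stance_time=0.79,
        loading_time=0.24,
        foot_flat_time=0.30,
        pushing_time=0.25,
        stride_length=1.10,
        strike_angle=-20.0,
        liftoff_angle=53.0,
        min_toe_clearance=0.015,
    )
    return params, simulate_stride_kinematics(params)


def test_stride_params_invariants():
    with pytest.raises(ValueError, match="sum"):
        StrideParams(1.15, 0.79, 0.2, 0.3, 0.25, 1.1, -20, 53, 0.015)
    with pytest.raises(ValueError, match="negative"):
        StrideParams(1.15, 0.79, 0.24, 0.30, 0.25, 1.1, 20, 53, 0.015)
    p = StrideParams(1.15, 0.79, 0.24, 0.30, 0.25, 1.1, -20, 53, 0.015)
    assert abs(p.swing_time - 0.36) < 1e-12


def test_single_stride_displacement_and_phases(single_stride):
    params, kin = single_stride
    assert abs((kin.pos[-1, 0] - kin.pos[0, 0]) - params.stride_length) < 1e-6
    # velocity identically zero through the foot-flat samples
    for s, e in kin.zupt_intervals:
        assert np.abs(kin.vel[s + 1 : e - 1]).max() < 1e-9
        assert np.abs(kin.vel[s:e]).max() < 1e-3  # boundary stencil only


def test_single_stride_pitch_hits_contact_angles(single_stride):
    params, kin = single_stride
    assert abs(np.degrees(kin.pitch.max()) - params.liftoff_angle) < 1e-6
    assert abs(np.degrees(kin.pitch.min()) - params.strike_angle) < 1e-6


def test_single_stride_toe_clearance_is_swing_local_minimum(single_stride):
    params, kin = single_stride
    # movement starts after the 0.5 s lead-in stand + foot flat
    (s0, e0), (s1, e1) = kin.zupt_intervals
    t0, t1 = kin.time[e0], kin.time[s1]
    t_to = t0 + params.pushing_time
    t_hs = t_to + params.swing_time
    mid = (kin.time > t_to + 0.3 * params.swing_time) & (
        kin.time < t_to + 0.8 * params.swing_time
    )
    ground = kin.pos_toe[e0 - 10, 2]
    assert abs(kin.pos_toe[mid, 2].min() - ground - params.min_toe_clearance) < 5e-6


def test_synthesize_imu_gravity_only_when_standing(single_stride):
    _, kin = single_stride
    rec, truth = synthesize_imu(
        kin, noise_accel=0.0, noise_gyro=0.0,
        accel_bias=np.zeros(3), gyro_bias=np.zeros(3),
    )
    s, e = kin.zupt_intervals[0]
    mags = np.linalg.norm(rec.accel[s + 2 : e - 2], axis=1)
    assert np.abs(mags - GRAVITY).max() < 1e-6
    assert np.abs(rec.gyro[s + 2 : e - 2]).max() < 1e-9


def test_synthesize_imu_mounting_must_be_rotation(single_stride):
    _, kin = single_stride
    with pytest.raises(ValueError, match="rotation"):
        synthesize_imu(kin, mounting=np.eye(3) * 2.0)


def test_noise_leaves_ground_truth_unchanged(single_stride):
    _, kin = single_stride
    _, t1 = synthesize_imu(kin, noise_accel=0.05, rng=np.random.default_rng(1))
    _, t2 = synthesize_imu(kin, noise_accel=0.10, rng=np.random.default_rng(2))
    np.testing.assert_array_equal(t1.pos_sensor, t2.pos_sensor)
    np.testing.assert_array_equal(t1.pitch, t2.pitch)


def test_accel_matches_second_derivative_of_position():
    """Finite-difference oracle: de-rotated, gravity-removed accel vs d2p/dt2.

    Uses a slow stride at a fine step so the discrete second difference is
    an adequate derivative estimate, and skips the impact transients, which
    no finite difference at gait time scales can resolve.
    """
    p = StrideParams(2.4, 1.7, 0.5, 0.7, 0.5, 0.6, -10.0, 20.0, 0.012)
    dt = 0.002
    kin = simulate_stride_kinematics(p, dt=dt)
    mnt = _axis_angle_matrix([0.3, 0.5, 0.8], 0.7)
    rec, _ = synthesize_imu(
        kin, mounting=mnt, noise_accel=0.0, noise_gyro=0.0,
        accel_bias=np.zeros(3), gyro_bias=np.zeros(3),
    )
    c, s = np.cos(kin.pitch), np.sin(kin.pitch)
    rot = np.zeros((len(c), 3, 3))
    rot[:, 0, 0] = c; rot[:, 0, 2] = s; rot[:, 1, 1] = 1
    rot[:, 2, 0] = -s; rot[:, 2, 2] = c
    a_world = np.einsum("nij,jk,nk->ni", rot, mnt, rec.accel) - [0, 0, GRAVITY]
    d2p = np.gradient(np.gradient(kin.pos, dt, axis=0), dt, axis=0)
    keep = np.ones(len(kin.time), bool)
    keep[:5] = keep[-5:] = False
    for t_ev in (1.7, 2.4):  # toe-off / heel-strike transients
        keep &= np.abs(kin.time - t_ev) > 0.12
    rms = np.sqrt(np.mean((a_world[keep] - d2p[keep]) ** 2))
    assert rms < 1e-3


def test_sub_phase_conservation_in_drawn_strides():
    rng = np.random.default_rng(0)
    df = draw_stride_metrics(
        {m: mu for m, (mu, sd) in CONTROL_PROFILE.single.items()},
        CONTROL_PROFILE.cv,
        {},
        "left",
        50,
        rng,
    )
    sub = df[["loading_ratio", "foot_flat_ratio", "pushing_ratio"]].sum(axis=1)
    assert np.allclose(sub, 100.0, atol=1e-9)
    assert np.allclose(df["stance_ratio"] + df["swing_ratio"], 100.0, atol=1e-9)
    assert np.allclose(df["gait_speed"], df["stride_length"] / df["stride_time"])


def test_zero_spread_profile_gives_identical_strides():
    prof = CONTROL_PROFILE
    means = {m: mu for m, (mu, sd) in prof.single.items()}
    df = draw_stride_metrics(means, {m: 0.0 for m in means}, {}, "left", 8, np.random.default_rng(0))
    assert float(df["stride_time"].std()) < 1e-12


def test_dual_condition_applies_speed_dte():
    """With zero SDs the generated dual/single speed ratio equals the DTE."""
    import dataclasses
    prof = dataclasses.replace(
        CONTROL_PROFILE,
        single={m: (mu, 0.0) for m, (mu, sd) in CONTROL_PROFILE.single.items()},
        dte={m: (mu, 0.0) for m, (mu, sd) in CONTROL_PROFILE.dte.items()},
        cv={m: 0.0 for m in CONTROL_PROFILE.cv},
        si={m: 0.0 for m in CONTROL_PROFILE.si},
    )
    rng = np.random.default_rng(0)
    rs, ts = simulate_walk(prof, "single", n_strides=9, seed=1, **CLEAN)
    rd, td = simulate_walk(prof, "dual", n_strides=9, seed=1, **CLEAN)
    v_s = ts.feet["left"].strides["gait_speed"].mean()
    v_d = td.feet["left"].strides["gait_speed"].mean()
    l_ratio = 1 + CONTROL_PROFILE.dte["stride_length"][0] / 100
    t_ratio = 1 + CONTROL_PROFILE.dte["stride_time"][0] / 100
    assert abs(v_d / v_s - l_ratio / t_ratio) < 1e-9


def test_generated_cv_matches_target_at_large_n():
    rng = np.random.default_rng(4)
    means = {m: mu for m, (mu, sd) in CONTROL_PROFILE.single.items()}
    df = draw_stride_metrics(means, {"stride_time": 4.81}, {}, "left", 2000, rng)
    cv = 100 * df["stride_time"].std(ddof=1) / df["stride_time"].mean()
    assert abs(cv - 4.81) < 0.4  # Monte-Carlo tolerance


def test_walk_determinism():
    r1, t1 = simulate_walk(CI_PROFILE, "dual", n_strides=9, seed=11)
    r2, t2 = simulate_walk(CI_PROFILE, "dual", n_strides=9, seed=11)
    for foot in ("left", "right"):
        np.testing.assert_array_equal(r1[foot].accel, r2[foot].accel)
        np.testing.assert_array_equal(r1[foot].gyro, r2[foot].gyro)


def test_walk_too_short_rejected():
    with pytest.raises(ValueError, match="boundary"):
        simulate_walk(CONTROL_PROFILE, "single", n_strides=6, seed=0)


def test_cohort_shapes_and_moca_labels():
    sim = simulate_cohort(n_control=13, n_ci=16, seed=0, mode="parameter", n_strides=12)
    meta = sim["metadata"]
    assert len(meta) == 29
    assert (meta.group == "control").sum() == 13
    assert (meta.group == "ci").sum() == 16
    # MoCA respects the stratification cutoff when enforcement is on
    assert (meta.loc[meta.group == "control", "moca_raw"] >= 24).all()
    assert (meta.loc[meta.group == "ci", "moca_raw"] < 24).all()
    # 2 feet x 2 conditions of drawn strides per subject
    assert len(sim["stride_tables"]) == 29 * 4


def test_cohort_signal_mode_emits_recordings():
    sim = simulate_cohort(n_control=2, n_ci=2, seed=1, mode="signal", n_strides=9)
    assert len(sim["recordings"]) == 4 * 4  # subjects x (2 feet x 2 conditions)
    rec = sim["recordings"][("S001", "single", "left")]
    assert rec.rate_hz == 100.0


def test_moca_slope_zero_decouples_moca_from_dte():
    import dataclasses
    prof_c = dataclasses.replace(CONTROL_PROFILE, moca_slope_per_dte=0.0)
    prof_i = dataclasses.replace(CI_PROFILE, moca_slope_per_dte=0.0)
    sim = simulate_cohort(120, 120, profiles=(prof_c, prof_i), seed=3,
                          mode="parameter", n_strides=8, enforce_cutoff=False)
    meta = sim["metadata"]
    grp = meta[meta.group == "ci"]
    r = np.corrcoef(grp["moca_raw"], grp["true_speed_dte"])[0, 1]
    assert abs(r) < 0.2
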