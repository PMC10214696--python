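"""Pipeline configuration.

Every threshold of the measurement chain lives here and is overridable from a
single YAML file, so sensitivity analyses need no code change.  Internal units
are SI throughout (m, s, rad); degrees and centimetres appear only in reported
metric columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Standard gravity used consistently by the simulator and the reconstruction.
GRAVITY = 9.81


@dataclass
class PipelineConfig:
    """Tunable parameters of the gait-analysis pipeline.

    Attributes
    ----------
    rate_hz:
        Nominal IMU sampling rate.
    zupt_window_s:
        Centred window of the angular-rate energy detector.
    zupt_threshold:
        Stationarity threshold on the windowed mean squared angular-rate
        magnitude, (rad/s)^2.
    zupt_min_duration_s:
        Detected stationary intervals shorter than this are discarded.
    zupt_edge_min_s:
        Stationary intervals touching the recording edges are kept as
        integration anchors only if at least this long.
    filter_gain:
        Per-sample complementary-filter blend toward the accelerometer
        gravity direction.
    accel_gate:
        Deviation of |specific force| from g (m/s^2) at which the gravity
        correction is down-weighted (unreliable mid-swing).
    lowpass_cutoff_hz:
        Zero-phase Butterworth cutoff for the event-detection signals.
    event_search_frac_hs / event_search_frac_to:
        Fraction of the adjacent movement interval searched for the
        heel-strike (before foot flat) / toe-off (after foot flat) peaks.
        The toe-off window is wider because pushing can occupy a larger
        share of the movement than loading does.
    boundary_strides_to_drop:
        Strides removed at each end of a walk (steady-state analysis).
    resample_points:
        Grid length for stride time-normalisation (0..100%).
    sensor_to_heel_offset / sensor_to_toe_offset:
        Rigid-body lever arms from the instep-mounted sensor to the heel and
        toe points, metres, in the foot frame (x forward, z up when flat).
    moca_cutoff:
        MoCA score below which a subject is labelled cognitively impaired.
    alpha:
        Significance level of the statistical decision tree.
    mw_continuity:
        Continuity correction for the asymptotic Mann-Whitney / Wilcoxon p.
    """

    rate_hz: float = 100.0
    zupt_window_s: float = 0.1
    zupt_threshold: float = 0.05
    zupt_min_duration_s: float = 0.15
    zupt_edge_min_s: float = 0.5
    filter_gain: float = 0.08
    accel_gate: float = 0.5
    omega_gate: float = 0.2
    lowpass_cutoff_hz: float = 20.0
    event_search_frac_hs: float = 0.45
    event_search_frac_to: float = 0.6
    boundary_strides_to_drop: int = 2
    resample_points: int = 101
    sensor_to_heel_offset: tuple[float, float, float] = (-0.12, 0.0, -0.07)
    sensor_to_toe_offset: tuple[float, float, float] = (0.13, 0.0, -0.07)
    moca_cutoff: int = 24
    alpha: float = 0.05
    mw_continuity: bool = False

    def __post_init__(self) -> None:
        for name in (
            "rate_hz",
            "zupt_window_s",
            "zupt_threshold",
            "zupt_min_duration_s",
            "filter_gain",
            "lowpass_cutoff_hz",
            "event_search_frac_hs",
            "event_search_frac_to",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resample_points < 2:
            raise ValueError("resample_points must be >= 2")
        if self.boundary_strides_to_drop < 0:
            raise ValueError("boundary_strides_to_drop must be >= 0")
        self.sensor_to_heel_offset = tuple(float(v) for v in self.sensor_to_heel_offset)
        self.sensor_to_toe_offset = tuple(float(v) for v in self.sensor_to_toe_offset)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sensor_to_heel_offset"] = list(self.sensor_to_heel_offset)
        data["sensor_to_toe_offset"] = list(self.sensor_to_toe_offset)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
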