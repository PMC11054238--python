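"""Domain containers shared across the simulation, reconstruction and statistics stages.

Conventions
-----------
* Inertial frame: right-handed, z up, gravity (0, 0, -9.81) m/s^2.
* The accelerometer reports *specific force* in the body frame, i.e. the
  kinematic acceleration minus gravity, so a device at rest reads
  (0, 0, +9.81) when level.
* Stride intervals are half-open ``[start, end)`` with boundaries placed at
  stance midpoints (capped near long pauses), so consecutive strides of one
  foot share a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

GRAVITY = 9.81  # m/s^2, magnitude; gravity vector is (0, 0, -GRAVITY)


class ExerciseKind(str, Enum):
    NORMAL_WALK = "normal_walk"
    FAST_WALK = "fast_walk"
    DUAL_TASK_WALK = "dual_task_walk"
    HALF_TURNS = "half_turns"
    TIMED_UP_AND_GO = "timed_up_and_go"


class Foot(str, Enum):
    LEFT = "left"
    RIGHT = "right"


# Defaults per exercise: (mean stride length m, SD m, cadence strides/s).
# Healthy young adults: comfortable pace ~1.2 m/s, fast ~1.8 m/s, dual-task
# and transition exercises slower.
_EXERCISE_GAIT_DEFAULTS: dict[ExerciseKind, tuple[float, float, float]] = {
    ExerciseKind.NORMAL_WALK: (1.50, 0.15, 0.80),
    ExerciseKind.FAST_WALK: (1.90, 0.18, 0.95),
    ExerciseKind.DUAL_TASK_WALK: (1.25, 0.15, 0.75),
    ExerciseKind.HALF_TURNS: (1.25, 0.15, 0.80),
    ExerciseKind.TIMED_UP_AND_GO: (1.00, 0.12, 0.75),
}

#: Hand-clap cue times (s) for the half-turns exercise: seven cues at
#: heterogeneously distributed instants inside the one-minute recording.
DEFAULT_TURN_CUES = (7.0, 14.5, 21.0, 30.5, 38.0, 47.5, 54.0)


@dataclass
class ExerciseProfile:
    """Protocol description of one exercise for one (virtual) subject."""

    exercise_kind: ExerciseKind
    mean_stride_length: float
    stride_length_sd: float
    cadence: float  # strides per second, per foot
    track_half_length: float = 4.0  # m, one-way distance between floor markers
    n_round_trips: int = 10  # 2 * 4 m * 10 = the 80 m protocol distance
    duration_limit: float = 60.0  # s, used by half_turns
    turn_cue_times: tuple[float, ...] = DEFAULT_TURN_CUES
    tug_distance: float = 3.0  # m
    tug_repetitions: int = 3
    stance_fraction: float = 0.35  # fraction of the gait cycle spent in stance
    foot_lateral_offset: float = 0.10  # m; left foot rides the track interior

    def __post_init__(self) -> None:
        self.exercise_kind = ExerciseKind(self.exercise_kind)
        if self.mean_stride_length <= 0:
            raise ValueError("mean_stride_length must be > 0")
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        if self.stride_length_sd < 0:
            raise ValueError("stride_length_sd must be >= 0")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.exercise_kind is ExerciseKind.HALF_TURNS:
            if len(self.turn_cue_times) != 7:
                raise ValueError("half_turns requires exactly 7 turn cues")
            if any(t >= self.duration_limit for t in self.turn_cue_times):
                raise ValueError("turn cues must precede the duration limit")

    @classmethod
    def for_kind(cls, kind: ExerciseKind | str, **overrides) -> "ExerciseProfile":
        kind = ExerciseKind(kind)
        mean, sd, cadence = _EXERCISE_GAIT_DEFAULTS[kind]
        params = dict(
            exercise_kind=kind,
            mean_stride_length=mean,
            stride_length_sd=sd,
            cadence=cadence,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruthTrajectory:
    """Dense noiseless ankle trajectory in the inertial frame (z up)."""

    time: np.ndarray  # (n,) s, strictly increasing
    position: np.ndarray  # (n, 3) m
    velocity: np.ndarray  # (n, 3) m/s; exactly zero wherever stance_mask
    orientation: Rotation  # body -> inertial, length n
    stance_mask: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (self.position.shape == self.velocity.shape == (n, 3)):
            raise ValueError("position/velocity must be (n, 3)")
        if len(self.orientation) != n or self.stance_mask.shape != (n,):
            raise ValueError("orientation/stance_mask length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class StrideTruth:
    """Ground truth for one stride: half-open [start_time, end_time)."""

    start_time: float
    end_time: float
    length: float  # m, horizontal displacement between boundary stance points
    mean_horizontal_velocity: float  # m/s == length / duration
    foot: Foot

    def __post_init__(self) -> None:
        self.foot = Foot(self.foot)
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")
        if self.length < 0:
            raise ValueError("length must be >= 0")
        dur = self.end_time - self.start_time
        if abs(self.mean_horizontal_velocity - self.length / dur) > 1e-9:
            raise ValueError("mean_horizontal_velocity inconsistent with length/duration")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_time + self.end_time)


@dataclass
class NoiseModel:
    """IMU error model: white noise, constant per-recording bias, clock offset."""

    accel_white_sd: float = 0.02  # m/s^2, per axis
    gyro_white_sd: float = 0.002  # rad/s, per axis
    accel_bias: tuple[float, float, float] = (0.01, -0.006, 0.008)  # m/s^2
    gyro_bias: tuple[float, float, float] = (2e-4, -1.5e-4, 3e-4)  # rad/s
    clock_offset: float = 0.25  # s, added to the IMU timestamps
    imu_rate: float = 100.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imu_rate <= 0:
            raise ValueError("imu_rate must be > 0")
        if self.accel_white_sd < 0 or self.gyro_white_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def noiseless(cls, imu_rate: float = 100.0, clock_offset: float = 0.0) -> "NoiseModel":
        return cls(0.0, 0.0, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), clock_offset, imu_rate)


@dataclass
class DropoutModel:
    """Optical-capture error model: residual noise plus speed-dependent gaps.

    A sample is lost with probability ``min(1, base + gain * |v|)``; each
    contiguous run of lost samples is widened by ``gap_extension`` seconds on
    both sides, mimicking rigid-body tracking losing and re-acquiring lock.
    """

    mocap_rate: float = 120.0  # Hz
    position_noise_sd: float = 0.0008  # m, calibration residual scale
    base_dropout_prob: float = 0.001  # per sample
    speed_dropout_gain: float = 0.003  # per (m/s)
    gap_extension: float = 0.05  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mocap_rate <= 0:
            raise ValueError("mocap_rate must be > 0")
        if not 0 <= self.base_dropout_prob <= 1:
            raise ValueError("base_dropout_prob must lie in [0, 1]")
        if self.speed_dropout_gain < 0 or self.gap_extension < 0:
            raise ValueError("gain and gap_extension must be >= 0")

    @classmethod
    def pristine(cls, mocap_rate: float = 120.0) -> "DropoutModel":
        return cls(mocap_rate, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ImuRecording:
    """Body-frame specific force and angular rate at a uniform rate."""

    time: np.ndarray  # (n,) s
    accel: np.ndarray  # (n, 3) m/s^2, specific force
    gyro: np.ndarray  # (n, 3) rad/s

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel/gyro must be (n, 3)")
        if n >= 2:
            dt = np.diff(self.time)
            if np.ptp(dt) > 1e-9:
                raise ValueError("sampling must be uniform within 1e-9 s")
        if not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise ValueError("IMU samples must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def shifted(self, offset: float) -> "ImuRecording":
        """Same samples on a clock shifted by ``-offset`` (post-sync view)."""
        return ImuRecording(self.time - offset, self.accel, self.gyro)


@dataclass
class MocapRecording:
    """Inertial-frame rigid-body positions with a validity mask."""

    time: np.ndarray  # (n,) s
    position: np.ndarray  # (n, 3) m; NaN exactly where invalid
    valid_mask: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.position.shape != (n, 3) or self.valid_mask.shape != (n,):
            raise ValueError("position/valid_mask shape mismatch")
        nan_rows = np.any(np.isnan(self.position), axis=1)
        if np.any(nan_rows != ~self.valid_mask):
            raise ValueError("position must be NaN exactly where valid_mask is false")
        if n >= 2 and np.ptp(np.diff(self.time)) > 1e-9:
            raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class SegmenterConfig:
    """Parameters of the stance detector and gait-event state machine."""

    gyro_energy_threshold: float = 0.05  # rad/s, RMS of |gyro| in stance window
    accel_band: tuple[float, float] = (0.5, 15.0)  # Hz, envelope pre-filter
    min_stance_duration: float = 0.08  # s, RMS window
    min_swing_duration: float = 0.2  # s, shorter stance gaps are closed
    hysteresis_ratio: float = 1.2  # swing entry needs ratio * threshold
    min_stride_duration: float = 0.3  # s
    max_stride_duration: float = 3.0  # s
    boundary_cap: float = 0.75  # s, max boundary offset into a stance
    mocap_speed_threshold: float = 0.08  # m/s, mocap stance detector
    path_length_mode: bool = False  # report path length instead of displacement

    def __post_init__(self) -> None:
        if self.gyro_energy_threshold <= 0:
            raise ValueError("gyro_energy_threshold must be > 0")
        if self.min_stance_duration <= 0 or self.min_swing_duration <= 0:
            raise ValueError("min durations must be > 0")


@dataclass
class StrideInterval:
    """One detected stride: half-open [start, end), with gait events inside."""

    start_time: float
    end_time: float
    foot: Foot
    events: dict = field(default_factory=dict)  # toe_off, mid_swing, heel_strike

    def __post_init__(self) -> None:
        self.foot = Foot(self.foot)
        if self.end_time <= self.start_time:
            raise ValueError("end must exceed start")
        ev = self.events
        if ev:
            order = [self.start_time, ev["toe_off"], ev["mid_swing"],
                     ev["heel_strike"], self.end_time]
            if np.any(np.diff(order) <= 0):
                raise ValueError("events must satisfy start < toe_off < mid_swing "
                                 "< heel_strike < end")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_time + self.end_time)


@dataclass
class ReconstructedStride:
    """Strapdown-reconstructed trajectory and features of one stride."""

    interval: StrideInterval
    time: np.ndarray  # (m,) s
    position: np.ndarray  # (m, 3) m, origin at stride start
    velocity: np.ndarray  # (m, 3) m/s; exactly zero at both ends
    length: float  # m
    mean_horizontal_velocity: float  # m/s

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        dur = self.interval.duration
        if abs(self.mean_horizontal_velocity - self.length / dur) > 1e-9:
            raise ValueError("mean_horizontal_velocity must equal length/duration")


@dataclass
class MocapStride:
    """One mocap-side stride; ``complete`` is false if any sample was lost."""

    interval: StrideInterval
    length: float
    mean_horizontal_velocity: float
    complete: bool


@dataclass
class SyncResult:
    offset: float  # s; subtract from the IMU clock to land on the mocap clock
    peak_correlation: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.peak_correlation):
            raise ValueError("peak correlation must be finite")


@dataclass
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def detected_total(self) -> int:
        return self.tp + self.fp

    @property
    def truth_total(self) -> int:
        return self.tp + self.fn

    @property
    def true_positive_rate(self) -> float | None:
        return self.tp / self.truth_total if self.truth_total else None

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


@dataclass
class MatchedStridePair:
    """One stride seen by both systems, with both feature sets."""

    imu_length: float
    imu_velocity: float
    mocap_length: float
    mocap_velocity: float
    imu_midpoint: float
    mocap_midpoint: float
    exercise: str = ""
    foot: str = ""
    subject: str = ""

    @property
    def signed_diff_length(self) -> float:
        return self.imu_length - self.mocap_length

    @property
    def signed_diff_velocity(self) -> float:
        return self.imu_velocity - self.mocap_velocity
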