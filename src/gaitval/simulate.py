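"""Synthetic paired IMU / motion-capture gait data.

Generates noiseless ground-truth ankle trajectories for the five protocol
exercises (normal / fast / dual-task 80 m walks on a 4 m track, one-minute
half-turns with seven cued reversals, and 3 m timed up-and-go x3), then
derives a noisy body-frame IMU recording and an occlusion-afflicted optical
position recording from the same trajectory.

Kinematic model
---------------
Each stride alternates a stance phase (foot flat, velocity exactly zero) and
a swing phase. During swing the horizontal position follows a quintic
smoothstep along the chord between consecutive footfalls (bell-shaped
horizontal speed), the vertical position a single C1 polynomial hump, and the
foot pitch a smooth +-30 deg profile; yaw tracks the path heading. Stance
occupies a configurable fraction (default 35%) of the gait cycle.

The walk track is modelled as a stadium-shaped loop (two 4 m straights joined
by semicircular ends) with a per-foot lateral offset: the left foot rides the
interior of the track, so the right foot covers slightly more ground per
loop, reproducing the left/right distance asymmetry seen in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .types import (
    GRAVITY,
    DropoutModel,
    ExerciseKind,
    ExerciseProfile,
    Foot,
    GroundTruthTrajectory,
    ImuRecording,
    MocapRecording,
    NoiseModel,
    StrideTruth,
)

INTERNAL_RATE = 600.0  # Hz; divisible by both 100 Hz (IMU) and 120 Hz (mocap)
LEAD_IN = 2.0  # s of quiet stance at each end of a recording
SWING_HEIGHT = 0.12  # m, peak ankle lift
PITCH_AMPLITUDE = math.radians(30.0)
MIN_STRIDE_LENGTH = 0.3  # m, truncation of the stride-length draw
TURN_RADIUS = 1.0  # m, track centreline U-turn radius (subjects take wide turns)
BOUNDARY_CAP = 0.75  # s, max boundary offset into a stance (see inertial module)
TUG_SIT_HEIGHT = 0.03  # m, ankle vertical offset while seated
TUG_RAMP_DURATION = 0.8  # s, sit<->stand vertical ramp
TUG_PAUSE = 2.0  # s of quiet stance around each repetition

_GRAVITY_VEC = np.array([0.0, 0.0, -GRAVITY])


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: h(0)=0, h(1)=1, h'=h''=0 at both ends."""
    return u ** 3 * (10.0 + u * (-15.0 + 6.0 * u))


def _smoothstep_d(u: np.ndarray) -> np.ndarray:
    return 30.0 * u ** 2 * (1.0 - u) ** 2


def _hump(u: np.ndarray) -> np.ndarray:
    """Single symmetric hump, 1 at u=0.5; value, slope *and curvature* vanish
    at both ends, keeping acceleration continuous across segment joints."""
    return 64.0 * u ** 3 * (1.0 - u) ** 3


def _hump_d(u: np.ndarray) -> np.ndarray:
    return 192.0 * u ** 2 * (1.0 - u) ** 2 * (1.0 - 2.0 * u)


_PITCH_GRID = np.linspace(0.0, 1.0, 4001)
_PITCH_NORM = float(np.max(np.abs(np.sin(2 * np.pi * _PITCH_GRID) * _hump(_PITCH_GRID))))


def _pitch_profile(u: np.ndarray) -> np.ndarray:
    """Odd-symmetric C1 pitch motif, peak +-1, zero value and slope at ends."""
    return np.sin(2 * np.pi * u) * _hump(u) / _PITCH_NORM


# ---------------------------------------------------------------------------
# Footfall geometry
# ---------------------------------------------------------------------------


def _stadium_point(s: float, straight: float, radius: float) -> tuple[float, float]:
    """Position on a counterclockwise stadium loop at arc length ``s``."""
    loop = 2.0 * straight + 2.0 * math.pi * radius
    s = s % loop
    if s < straight:  # bottom straight, heading +x
        return s, -radius
    s -= straight
    if s < math.pi * radius:  # right semicircle
        ang = -0.5 * math.pi + s / radius
        return straight + radius * math.cos(ang), radius * math.sin(ang)
    s -= math.pi * radius
    if s < straight:  # top straight, heading -x
        return straight - s, radius
    s -= straight
    ang = 0.5 * math.pi + s / radius  # left semicircle
    return radius * math.cos(ang), radius * math.sin(ang)


def _draw_length(rng: np.random.Generator, mean: float, sd: float) -> float:
    return max(MIN_STRIDE_LENGTH, float(rng.normal(mean, sd)))


def _walk_footfalls(profile: ExerciseProfile, foot: Foot,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Footfall positions for the 80 m back-and-forth walks (stadium loop)."""
    radius = TURN_RADIUS + (profile.foot_lateral_offset if foot is Foot.RIGHT
                            else -profile.foot_lateral_offset)
    target = 2.0 * profile.track_half_length * profile.n_round_trips
    points = [np.array([*_stadium_point(0.0, profile.track_half_length, radius), 0.0])]
    s = 0.0
    while s < target:
        s += _draw_length(rng, profile.mean_stride_length, profile.stride_length_sd)
        points.append(np.array([*_stadium_point(s, profile.track_half_length, radius), 0.0]))
    return points


def _half_turn_footfalls(profile: ExerciseProfile, foot: Foot, rng: np.random.Generator,
                         footfall_times: list[float]) -> list[np.ndarray]:
    """Straight back-and-forth footfalls reversing after each cue time."""
    y = profile.foot_lateral_offset * (-1.0 if foot is Foot.RIGHT else 1.0)
    points = [np.array([0.0, y, 0.0])]
    x, direction = 0.0, 1.0
    cues = sorted(profile.turn_cue_times)
    cue_idx = 0
    for t_footfall in footfall_times:
        while cue_idx < len(cues) and cues[cue_idx] < t_footfall:
            direction = -direction
            cue_idx += 1
        x += direction * _draw_length(rng, profile.mean_stride_length,
                                      profile.stride_length_sd)
        points.append(np.array([x, y, 0.0]))
    return points


def _tug_rep_footfalls(profile: ExerciseProfile, y: float,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """One out-turn-back repetition of the timed up-and-go, x in [0, 3 m]."""
    points = []
    x, direction = 0.0, 1.0
    while True:
        step = _draw_length(rng, profile.mean_stride_length, profile.stride_length_sd)
        nx = x + direction * step
        if direction > 0 and nx > profile.tug_distance:
            nx = 2.0 * profile.tug_distance - nx  # reflect at the turn point
            direction = -1.0
        elif direction < 0 and nx <= 0.0:
            points.append(np.array([0.0, y, 0.0]))
            break
        points.append(np.array([nx, y, 0.0]))
        x = nx
    return points


# ---------------------------------------------------------------------------
# Segment timeline
# ---------------------------------------------------------------------------


@dataclass
class _Stance:
    t0: float
    t1: float
    pos: np.ndarray
    yaw: float


@dataclass
class _Swing:
    t0: float
    t1: float
    p0: np.ndarray
    p1: np.ndarray
    yaw0: float
    yaw1: float


@dataclass
class _Ramp:
    """Purely vertical C1 position ramp (sit<->stand); zero angular rate."""

    t0: float
    t1: float
    pos: np.ndarray  # start position
    dz: float
    yaw: float


def _heading(p0: np.ndarray, p1: np.ndarray, fallback: float) -> float:
    d = p1[:2] - p0[:2]
    if np.hypot(*d) < 1e-9:
        return fallback
    return math.atan2(d[1], d[0])


def _wrap_turn(dyaw: float) -> float:
    """Wrap a heading change to (-pi, pi]; exact reversals turn left (+pi)."""
    dyaw = (dyaw + math.pi) % (2.0 * math.pi) - math.pi
    if abs(abs(dyaw) - math.pi) < 1e-12:
        dyaw = math.pi
    return dyaw


def _build_stride_segments(points: list[np.ndarray], t_start: float, swing_dur: float,
                           stance_dur: float, yaw_in: float
                           ) -> tuple[list, float, float]:
    """Alternate swing/stance segments over a footfall sequence.

    Returns (segments, end time, final yaw). The first segment starts with the
    swing leaving ``points[0]`` at ``t_start``; a stance follows each swing.
    """
    segments = []
    t = t_start
    yaw = yaw_in
    for p0, p1 in zip(points[:-1], points[1:]):
        h = _heading(p0, p1, yaw)
        yaw1 = yaw + _wrap_turn(h - yaw)
        segments.append(_Swing(t, t + swing_dur, p0, p1, yaw, yaw1))
        t += swing_dur
        segments.append(_Stance(t, t + stance_dur, p1, yaw1))
        t += stance_dur
        yaw = yaw1
    return segments, t, yaw


def _boundary_into(stance: _Stance, cap: float = BOUNDARY_CAP) -> float:
    """Stride END boundary inside the stance following its swing."""
    return min(0.5 * (stance.t0 + stance.t1), stance.t0 + cap)


def _boundary_out_of(stance: _Stance, cap: float = BOUNDARY_CAP) -> float:
    """Stride START boundary inside the stance preceding its swing."""
    return max(0.5 * (stance.t0 + stance.t1), stance.t1 - cap)


def generate_trajectory(profile: ExerciseProfile, foot: Foot | str, seed: int
                        ) -> tuple[GroundTruthTrajectory, list[StrideTruth]]:
    """Ground-truth ankle trajectory and per-stride truth for one exercise.

    Stride truth lengths are the horizontal displacement between consecutive
    stance positions (the foot is strictly stationary throughout stance), and
    stride boundaries sit at stance midpoints, capped at 0.75 s from the
    stance edge next to long pauses.
    """
    foot = Foot(foot)
    kind = profile.exercise_kind
    track = (profile.tug_distance if kind is ExerciseKind.TIMED_UP_AND_GO
             else profile.track_half_length)
    if profile.mean_stride_length > track:
        raise ValueError(
            f"mean stride length {profile.mean_stride_length} m cannot fit on a "
            f"{track} m track")

    rng = np.random.default_rng(seed)
    cycle = 1.0 / profile.cadence
    stance_dur = profile.stance_fraction * cycle
    swing_dur = cycle - stance_dur
    # left foot leads by half a cycle so the two feet interleave
    lead = LEAD_IN + (0.0 if foot is Foot.LEFT else 0.5 * cycle)

    segments: list = []
    if kind is ExerciseKind.TIMED_UP_AND_GO:
        y = profile.foot_lateral_offset * (-1.0 if foot is Foot.RIGHT else 1.0)
        t = 0.0
        pos = np.array([0.0, y, TUG_SIT_HEIGHT])
        yaw = 0.0
        for _ in range(profile.tug_repetitions):
            segments.append(_Stance(t, t + lead, pos, yaw))
            t += lead
            segments.append(_Ramp(t, t + TUG_RAMP_DURATION, pos.copy(), -TUG_SIT_HEIGHT, yaw))
            t += TUG_RAMP_DURATION
            pos = pos - np.array([0.0, 0.0, TUG_SIT_HEIGHT])
            segments.append(_Stance(t, t + TUG_PAUSE, pos, yaw))
            t += TUG_PAUSE
            points = [pos] + _tug_rep_footfalls(profile, y, rng)
            strides, t, yaw = _build_stride_segments(points, t, swing_dur, stance_dur, yaw)
            segments.extend(strides)
            pos = strides[-1].pos if isinstance(strides[-1], _Stance) else points[-1]
            # extend the terminal stance into a pause, then sit back down
            segments[-1].t1 += TUG_PAUSE - stance_dur
            t = segments[-1].t1
            segments.append(_Ramp(t, t + TUG_RAMP_DURATION, pos.copy(), TUG_SIT_HEIGHT, yaw))
            t += TUG_RAMP_DURATION
            pos = pos + np.array([0.0, 0.0, TUG_SIT_HEIGHT])
        segments.append(_Stance(t, t + LEAD_IN, pos, yaw))
    else:
        if kind is ExerciseKind.HALF_TURNS:
            n_max = int((profile.duration_limit - lead) / cycle)
            footfall_times = [lead + k * cycle + swing_dur for k in range(n_max)]
            points = _half_turn_footfalls(profile, foot, rng, footfall_times)
        else:
            points = _walk_footfalls(profile, foot, rng)
        yaw0 = _heading(points[0], points[1], 0.0)
        segments.append(_Stance(0.0, lead, points[0], yaw0))
        strides, t, _ = _build_stride_segments(points, lead, swing_dur, stance_dur, yaw0)
        segments.extend(strides)
        segments[-1].t1 += LEAD_IN - stance_dur  # quiet lead-out

    # --- render the dense trajectory -------------------------------------
    t_end = segments[-1].t1
    dt = 1.0 / INTERNAL_RATE
    time = np.arange(0.0, t_end + 0.5 * dt, dt)
    n = len(time)
    position = np.zeros((n, 3))
    velocity = np.zeros((n, 3))
    yaw = np.zeros(n)
    pitch = np.zeros(n)
    stance_mask = np.zeros(n, dtype=bool)

    for k, seg in enumerate(segments):
        i0 = int(np.searchsorted(time, seg.t0 - 0.5 * dt))
        i1 = n if k == len(segments) - 1 else int(np.searchsorted(time, seg.t1 - 0.5 * dt))
        sl = slice(i0, i1)
        if isinstance(seg, _Stance):
            position[sl] = seg.pos
            velocity[sl] = 0.0
            yaw[sl] = seg.yaw
            stance_mask[sl] = True
        elif isinstance(seg, _Ramp):
            dur = seg.t1 - seg.t0
            u = (time[sl] - seg.t0) / dur
            position[sl] = seg.pos
            position[sl, 2] = seg.pos[2] + seg.dz * _smoothstep(u)
            velocity[sl, 2] = seg.dz * _smoothstep_d(u) / dur
            yaw[sl] = seg.yaw
        else:  # _Swing
            dur = seg.t1 - seg.t0
            u = (time[sl] - seg.t0) / dur
            h, hd = _smoothstep(u), _smoothstep_d(u)
            chord = seg.p1 - seg.p0
            position[sl] = seg.p0 + chord[None, :] * h[:, None]
            position[sl, 2] = seg.p0[2] + SWING_HEIGHT * _hump(u) \
                + (seg.p1[2] - seg.p0[2]) * h
            velocity[sl] = chord[None, :] * hd[:, None] / dur
            velocity[sl, 2] = (SWING_HEIGHT * _hump_d(u)
                               + (seg.p1[2] - seg.p0[2]) * hd) / dur
            yaw[sl] = seg.yaw0 + (seg.yaw1 - seg.yaw0) * h
            pitch[sl] = PITCH_AMPLITUDE * _pitch_profile(u)

    orientation = Rotation.from_euler("ZY", np.column_stack([yaw, pitch]))
    traj = GroundTruthTrajectory(time, position, velocity, orientation, stance_mask)

    # --- stride truth ------------------------------------------------------
    truths: list[StrideTruth] = []
    for i, seg in enumerate(segments):
        if not isinstance(seg, _Swing):
            continue
        before = segments[i - 1]
        after = segments[i + 1]
        start = _boundary_out_of(before)
        end = _boundary_into(after)
        length = float(np.hypot(*(seg.p1[:2] - seg.p0[:2])))
        truths.append(StrideTruth(start, end, length, length / (end - start), foot))
    return traj, truths


# ---------------------------------------------------------------------------
# Sensor synthesis
# ---------------------------------------------------------------------------


def _resample_indices(n_dense: int, dense_rate: float, out_rate: float) -> np.ndarray:
    ratio = dense_rate / out_rate
    if abs(ratio - round(ratio)) < 1e-9:
        return np.arange(0, n_dense, int(round(ratio)))
    raise ValueError("output rate must divide the internal synthesis rate")


def body_angular_rate(traj: GroundTruthTrajectory) -> np.ndarray:
    """Body-frame angular rate from the quaternion track (central differences)."""
    q = traj.orientation
    dt = float(np.median(np.diff(traj.time)))
    n = len(traj.time)
    omega = np.zeros((n, 3))
    omega[1:-1] = (q[:-2].inv() * q[2:]).as_rotvec() / (2.0 * dt)
    omega[0] = (q[0].inv() * q[1]).as_rotvec() / dt
    omega[-1] = (q[-2].inv() * q[-1]).as_rotvec() / dt
    return omega


def trajectory_to_imu(traj: GroundTruthTrajectory, noise: NoiseModel) -> ImuRecording:
    """Derive the body-frame specific force / angular rate stream.

    The accelerometer reads ``R_inertial->body (a - g)`` plus bias and white
    noise; timestamps are shifted by the model's clock offset. The trajectory
    must be sampled at least twice as fast as the output rate.
    """
    dense_rate = traj.rate
    if dense_rate < 2.0 * noise.imu_rate:
        raise ValueError("trajectory sampling must be >= 2x the IMU rate")

    a_inertial = np.gradient(traj.velocity, traj.time, axis=0)
    specific_force = traj.orientation.inv().apply(a_inertial - _GRAVITY_VEC)
    omega = body_angular_rate(traj)

    idx = _resample_indices(len(traj.time), dense_rate, noise.imu_rate)
    rng = np.random.default_rng(noise.seed)
    accel = (specific_force[idx] + np.asarray(noise.accel_bias)
             + rng.normal(0.0, noise.accel_white_sd, (len(idx), 3)))
    gyro = (omega[idx] + np.asarray(noise.gyro_bias)
            + rng.normal(0.0, noise.gyro_white_sd, (len(idx), 3)))
    return ImuRecording(traj.time[idx] + noise.clock_offset, accel, gyro)


def trajectory_to_mocap(traj: GroundTruthTrajectory, dropout: DropoutModel
                        ) -> MocapRecording:
    """Derive the rigid-body position stream with residual noise and gaps.

    Each output sample is lost with probability ``min(1, base + gain * |v|)``;
    lost samples form contiguous gaps that are widened by ``gap_extension``
    seconds on each side (rigid-body tracking needs time to re-acquire).
    """
    idx = _resample_indices(len(traj.time), traj.rate, dropout.mocap_rate)
    time = traj.time[idx]
    rng = np.random.default_rng(dropout.seed)
    position = traj.position[idx].copy()
    if dropout.position_noise_sd > 0:
        position += rng.normal(0.0, dropout.position_noise_sd, position.shape)

    speed = np.linalg.norm(traj.velocity[idx], axis=1)
    p_drop = np.minimum(1.0, dropout.base_dropout_prob
                        + dropout.speed_dropout_gain * speed)
    dropped = rng.random(len(idx)) < p_drop
    if dropout.gap_extension > 0 and dropped.any():
        k = int(round(dropout.gap_extension * dropout.mocap_rate))
        if k > 0:
            dropped = ndimage.binary_dilation(dropped, np.ones(2 * k + 1, dtype=bool))
    valid = ~dropped
    position[dropped] = np.nan
    return MocapRecording(time, position, valid)


def paired_recordings(profile: ExerciseProfile, foot: Foot | str, noise: NoiseModel,
                      dropout: DropoutModel, seed: int
                      ) -> tuple[GroundTruthTrajectory, list[StrideTruth],
                                 ImuRecording, MocapRecording]:
    """Convenience wrapper: one exercise observed by both systems."""
    traj, truths = generate_trajectory(profile, foot, seed)
    imu = trajectory_to_imu(traj, noise)
    moc = trajectory_to_mocap(traj, dropout)
    return traj, truths, imu, moc


def stride_lengths_from_positions(traj: GroundTruthTrajectory,
                                  truths: list[StrideTruth]) -> np.ndarray:
    """Recompute stride lengths from the position track (verification aid)."""
    lengths = []
    for s in truths:
        i0 = int(np.searchsorted(traj.time, s.start_time))
        i1 = int(np.searchsorted(traj.time, s.end_time))
        lengths.append(float(np.hypot(*(traj.position[i1, :2] - traj.position[i0, :2]))))
    return np.asarray(lengths)
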