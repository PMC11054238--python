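"""Stride detection and ZUPT-corrected strapdown reconstruction from raw IMU data.

The pipeline has four stages:

1. **Stance detection** — a sliding-window RMS of the gyroscope magnitude
   below a threshold marks the zero-velocity (stance) phases.
2. **Stride segmentation** — a STANCE -> SWING -> SWING_PEAK -> STANCE state
   machine emits one interval per complete gait cycle, with toe-off,
   mid-swing and heel-strike events, and boundaries at stance midpoints.
3. **Strapdown integration** — per stride: gravity-anchored initial attitude,
   quaternion propagation of the gyroscope, rotation of the specific force to
   the inertial frame, gravity removal, and trapezoidal integration to
   velocity and position.
4. **Drift correction (ZUPT)** — the stance boundaries are known zero-velocity
   instants, so the linear velocity ramp ``c(t) = (t - t0)/(t1 - t0) * v(t1)``
   is subtracted, pinning the velocity to exactly zero at both ends. The
   position error removed by this step is quadratic in time, and a constant
   accelerometer bias (inertial frame) is cancelled exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.spatial.transform import Rotation

from .features import stride_features
from .types import GRAVITY, Foot, ImuRecording, ReconstructedStride, SegmenterConfig, StrideInterval

_GRAVITY_VEC = np.array([0.0, 0.0, -GRAVITY])

FEATURE_COLUMNS = ["stride_id", "foot", "start_s", "end_s", "length_m",
                   "mean_horizontal_velocity_mps"]


def detect_stance(imu: ImuRecording, cfg: SegmenterConfig) -> np.ndarray:
    """Boolean per-sample stance mask from the gyroscope energy.

    True where the RMS of the gyro magnitude over a ``min_stance_duration``
    window falls below ``gyro_energy_threshold``; gaps shorter than
    ``min_swing_duration`` are closed (they cannot be real swings).
    """
    if len(imu.time) == 0:
        raise ValueError("empty recording")
    gmag2 = np.sum(imu.gyro ** 2, axis=1)
    win = max(1, int(round(cfg.min_stance_duration * imu.rate)))
    # the moving average can go slightly negative on exactly-zero stretches
    rms = np.sqrt(np.clip(uniform_filter1d(gmag2, win, mode="nearest"), 0.0, None))
    stance = rms < cfg.gyro_energy_threshold

    min_gap = int(round(cfg.min_swing_duration * imu.rate))
    return _close_short_gaps(stance, min_gap)


def _close_short_gaps(mask: np.ndarray, min_gap: int) -> np.ndarray:
    """Set False-runs shorter than ``min_gap`` samples to True."""
    mask = mask.copy()
    for s, e in _runs(~mask):
        if e - s < min_gap:
            mask[s:e] = True
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where ``mask`` is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def stride_boundaries(stance_start: float, stance_end: float, side: str,
                      cap: float) -> float:
    """Boundary at the stance midpoint, capped at ``cap`` from the stance edge.

    ``side`` is "in" for the boundary that ends a stride (enters the stance)
    and "out" for the one that starts the next stride (leaves the stance).
    For stances shorter than ``2 * cap`` both reduce to the midpoint, so
    consecutive strides share their boundary.
    """
    mid = 0.5 * (stance_start + stance_end)
    if side == "in":
        return min(mid, stance_start + cap)
    return max(mid, stance_end - cap)


def segment_strides(imu: ImuRecording, cfg: SegmenterConfig,
                    foot: Foot | str = Foot.LEFT,
                    stance: np.ndarray | None = None) -> list[StrideInterval]:
    """Gait-phase state machine: one interval per complete stance-swing-stance cycle.

    Toe-off is where the stance mask falls with the gyro rising past
    ``hysteresis_ratio * threshold`` during the swing, mid-swing at the gyro
    magnitude maximum, heel-strike where the mask rises again. Intervals are
    disjoint, sorted, and limited to [min_stride_duration, max_stride_duration].
    """
    foot = Foot(foot)
    if len(imu.time) == 0:
        return []
    if stance is None:
        stance = detect_stance(imu, cfg)
    gmag = np.linalg.norm(imu.gyro, axis=1)
    swing_gate = cfg.hysteresis_ratio * cfg.gyro_energy_threshold

    stance_runs = _runs(stance)
    if len(stance_runs) < 2:
        return []
    # merge stance runs separated by low-energy blips (not true swings)
    merged = [list(stance_runs[0])]
    for s, e in stance_runs[1:]:
        gap = slice(merged[-1][1], s)
        if gmag[gap].size and gmag[gap].max() >= swing_gate:
            merged.append([s, e])
        else:
            merged[-1][1] = e

    intervals: list[StrideInterval] = []
    t = imu.time
    for i in range(len(merged) - 1):
        (a0, a1), (b0, b1) = merged[i], merged[i + 1]
        swing = slice(a1, b0)
        if gmag[swing].size == 0 or gmag[swing].max() < swing_gate:
            continue
        start = stride_boundaries(t[a0], t[a1 - 1], "out", cfg.boundary_cap)
        end = stride_boundaries(t[b0], t[b1 - 1], "in", cfg.boundary_cap)
        if not cfg.min_stride_duration <= end - start <= cfg.max_stride_duration:
            continue
        toe_off = t[a1 - 1]
        heel_strike = t[b0]
        mid_idx = a1 + int(np.argmax(gmag[swing]))
        mid_swing = float(np.clip(t[mid_idx], toe_off + 1e-6, heel_strike - 1e-6))
        if not start < toe_off < mid_swing < heel_strike < end:
            continue
        intervals.append(StrideInterval(start, end, foot, {
            "toe_off": toe_off, "mid_swing": mid_swing, "heel_strike": heel_strike}))
    return intervals


def estimate_initial_attitude(imu: ImuRecording,
                              stance_window: tuple[float, float]) -> Rotation:
    """Gravity-anchored attitude: rotate the mean stance specific force onto +z.

    Returns the body-to-inertial rotation that maps the mean accelerometer
    reading in the window to (0, 0, +|g|). Yaw is unobservable without a
    magnetometer and is left at zero (the shortest-arc rotation has no twist
    about the vertical).
    """
    sel = (imu.time >= stance_window[0]) & (imu.time <= stance_window[1])
    if not sel.any():
        raise ValueError("stance window contains no samples")
    mean_f = imu.accel[sel].mean(axis=0)
    norm = np.linalg.norm(mean_f)
    if norm < 0.5 * GRAVITY:
        raise ValueError("mean stance acceleration too small to anchor gravity")
    u = mean_f / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    c = float(u @ z)
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])  # upside down
    return Rotation.from_rotvec(axis / s * np.arctan2(s, c))


def _integrate_attitude(q0: Rotation, gyro: np.ndarray, dt: float) -> Rotation:
    """Propagate attitude by mid-point quaternion integration of the gyro."""
    dtheta = 0.5 * (gyro[:-1] + gyro[1:]) * dt
    dq = Rotation.from_rotvec(dtheta).as_quat()  # (m-1, 4) xyzw
    q = np.empty((len(gyro), 4))
    q[0] = q0.as_quat()
    for i in range(len(dq)):
        x1, y1, z1, w1 = q[i]
        x2, y2, z2, w2 = dq[i]
        q[i + 1] = (w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                    w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                    w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
                    w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2)
        q[i + 1] /= np.linalg.norm(q[i + 1])
    return Rotation.from_quat(q)


def reconstruct_stride(imu: ImuRecording, interval: StrideInterval,
                       cfg: SegmenterConfig,
                       initial_attitude: Rotation | None = None
                       ) -> ReconstructedStride:
    """Strapdown reconstruction of one stride with ZUPT drift correction.

    The corrected velocity is exactly zero at both interval boundaries; the
    reported length is the horizontal displacement between them (or the
    horizontal path length when ``cfg.path_length_mode`` is set).
    """
    t = imu.time
    i0 = int(np.searchsorted(t, interval.start_time - 1e-12))
    i1 = int(np.searchsorted(t, interval.end_time - 1e-12))
    if i0 >= len(t) or i1 >= len(t) or i1 <= i0 + 1:
        raise ValueError("interval outside the recording")
    sl = slice(i0, i1 + 1)
    time = t[sl]
    if initial_attitude is None:
        w = max(cfg.min_stance_duration, 3.0 / imu.rate)
        initial_attitude = estimate_initial_attitude(
            imu, (interval.start_time - w, interval.start_time + w))

    rot = _integrate_attitude(initial_attitude, imu.gyro[sl], imu.dt)
    a_inertial = rot.apply(imu.accel[sl]) + _GRAVITY_VEC

    v_raw = cumulative_trapezoid(a_inertial, time, axis=0, initial=0.0)
    ramp = (time - time[0]) / (time[-1] - time[0])
    velocity = v_raw - ramp[:, None] * v_raw[-1]
    position = cumulative_trapezoid(velocity, time, axis=0, initial=0.0)

    length, mhv = stride_features(position, interval.duration, cfg.path_length_mode)
    return ReconstructedStride(interval, time, position, velocity, length, mhv)


def reconstruct_session(imu: ImuRecording, cfg: SegmenterConfig,
                        foot: Foot | str = Foot.LEFT) -> list[ReconstructedStride]:
    """Detect and reconstruct every stride of a recording."""
    stance = detect_stance(imu, cfg) if len(imu.time) else None
    intervals = segment_strides(imu, cfg, foot, stance)
    return [reconstruct_stride(imu, iv, cfg) for iv in intervals]


def compute_session_features(imu: ImuRecording, cfg: SegmenterConfig,
                             foot: Foot | str = Foot.LEFT) -> pd.DataFrame:
    """Per-stride feature table: one row per detected stride."""
    strides = reconstruct_session(imu, cfg, foot) if len(imu.time) else []
    rows = [(k, Foot(foot).value, s.interval.start_time, s.interval.end_time,
             s.length, s.mean_horizontal_velocity) for k, s in enumerate(strides)]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
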