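"""Stride features from optical motion-capture rigid-body positions.

Stance is detected where the windowed displacement speed of the rigid body
falls below a threshold on valid samples; stride boundaries use the same
stance-midpoint convention as the inertial pipeline and the feature
definitions are the identical shared code path. Strides containing any
invalid (occluded) sample are flagged incomplete and excluded from the
feature table — this exclusion is what halves the mocap-measured distance
relative to the wearable when marker dropout is active.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import stride_features
from .inertial import FEATURE_COLUMNS, _close_short_gaps, _runs, stride_boundaries
from .types import Foot, MocapRecording, MocapStride, SegmenterConfig, StrideInterval

#: a swing must reach this multiple of the stance speed threshold
_SWING_SPEED_GATE = 5.0


def _windowed_speed(moc: MocapRecording, half_window_s: float = 0.05) -> np.ndarray:
    """Displacement speed over a ~2x``half_window_s`` window; NaN when invalid.

    Averaging displacement over ~0.1 s suppresses the per-sample residual
    noise (sub-millimetre) that would otherwise swamp a finite-difference
    speed at 120 Hz.
    """
    w = max(1, int(round(half_window_s / moc.dt)))
    n = len(moc.time)
    speed = np.full(n, np.nan)
    lo = np.clip(np.arange(n) - w, 0, n - 1)
    hi = np.clip(np.arange(n) + w, 0, n - 1)
    disp = moc.position[hi] - moc.position[lo]
    dt = moc.time[hi] - moc.time[lo]
    ok = dt > 0
    speed[ok] = np.linalg.norm(disp[ok], axis=1) / dt[ok]
    return speed


def segment_strides_mocap(moc: MocapRecording, cfg: SegmenterConfig,
                          foot: Foot | str = Foot.LEFT) -> list[StrideInterval]:
    """Stride intervals from the position stream (same boundary convention).

    Stance is where the windowed speed is below ``cfg.mocap_speed_threshold``
    on valid samples; short gaps in stance are closed, and a candidate swing
    must exceed a gated peak speed to count as a stride.
    """
    foot = Foot(foot)
    if len(moc.time) == 0 or not moc.valid_mask.any():
        return []
    speed = _windowed_speed(moc)
    stance = np.zeros(len(moc.time), dtype=bool)
    ok = np.isfinite(speed)
    stance[ok] = speed[ok] < cfg.mocap_speed_threshold
    stance &= moc.valid_mask
    min_gap = int(round(cfg.min_swing_duration / moc.dt))
    stance = _close_short_gaps(stance, min_gap)
    # closing may have bridged occluded spans; stance requires valid data
    stance &= moc.valid_mask

    runs = [r for r in _runs(stance)
            if (r[1] - r[0]) * moc.dt >= cfg.min_stance_duration]
    if len(runs) < 2:
        return []

    gate = _SWING_SPEED_GATE * cfg.mocap_speed_threshold
    t = moc.time
    intervals: list[StrideInterval] = []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap = speed[merged[-1][1]:s]
        gap_valid = gap[np.isfinite(gap)]
        has_occlusion = bool(np.any(~moc.valid_mask[merged[-1][1]:s]))
        if (gap_valid.size and gap_valid.max() >= gate) or has_occlusion:
            merged.append([s, e])
        else:
            merged[-1][1] = e

    for (a0, a1), (b0, b1) in zip(merged[:-1], merged[1:]):
        start = stride_boundaries(t[a0], t[a1 - 1], "out", cfg.boundary_cap)
        end = stride_boundaries(t[b0], t[b1 - 1], "in", cfg.boundary_cap)
        if not cfg.min_stride_duration <= end - start <= cfg.max_stride_duration:
            continue
        sw_speed = speed[a1:b0]
        fin = np.isfinite(sw_speed)
        toe_off = t[a1 - 1]
        heel_strike = t[b0]
        if fin.any():
            mid_idx = a1 + int(np.argmax(np.where(fin, sw_speed, -np.inf)))
            mid = float(np.clip(t[mid_idx], toe_off + 1e-6, heel_strike - 1e-6))
        else:
            mid = 0.5 * (toe_off + heel_strike)
        if not start < toe_off < mid < heel_strike < end:
            continue
        intervals.append(StrideInterval(start, end, foot, {
            "toe_off": toe_off, "mid_swing": mid, "heel_strike": heel_strike}))
    return intervals


def mocap_strides(moc: MocapRecording, intervals: list[StrideInterval],
                  cfg: SegmenterConfig) -> list[MocapStride]:
    """Attach features and completeness to segmented intervals."""
    out: list[MocapStride] = []
    t = moc.time
    for iv in intervals:
        i0 = int(np.searchsorted(t, iv.start_time - 1e-12))
        i1 = int(np.searchsorted(t, iv.end_time - 1e-12))
        sl = slice(i0, min(i1 + 1, len(t)))
        complete = bool(np.all(moc.valid_mask[sl]))
        if complete:
            length, mhv = stride_features(moc.position[sl], iv.duration,
                                          cfg.path_length_mode)
        else:
            length, mhv = float("nan"), float("nan")
        out.append(MocapStride(iv, length, mhv, complete))
    return out


def compute_features_mocap(moc: MocapRecording, intervals: list[StrideInterval],
                           cfg: SegmenterConfig,
                           foot: Foot | str = Foot.LEFT) -> pd.DataFrame:
    """Feature table over complete strides only (incomplete ones are dropped)."""
    strides = mocap_strides(moc, intervals, cfg)
    rows = [(k, Foot(foot).value, s.interval.start_time, s.interval.end_time,
             s.length, s.mean_horizontal_velocity)
            for k, s in enumerate(strides) if s.complete]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
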