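"""Clock synchronization, stride pairing, and TP/FP/FN detection scoring.

The two systems share no hardware clock; a constant offset between them is
estimated by cross-correlating gait-locked signal envelopes (gyroscope
magnitude on the wearable side, rigid-body speed on the optical side — both
peak at mid-swing and are symmetric about it, so the correlation peak lands
at the true offset).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import DetectionCounts, ImuRecording, MatchedStridePair, MocapRecording, SyncResult

_CORR_RATE = 100.0  # Hz grid for the cross-correlation


def _mocap_speed_signal(moc: MocapRecording) -> np.ndarray:
    """Per-sample rigid-body speed, linearly bridged across occlusions.

    Zeroing occluded samples would notch the speed envelope asymmetrically
    (occlusion probability grows with speed) and bias the correlation peak;
    interpolating across the gaps keeps the envelope shape intact.
    """
    speed = np.zeros(len(moc.time))
    p = moc.position
    dt = moc.dt
    d = np.linalg.norm(p[2:] - p[:-2], axis=1) / (2.0 * dt)
    speed[1:-1] = np.where(np.isfinite(d), d, np.nan)
    ok = np.isfinite(speed)
    if not ok.any():
        return np.zeros_like(speed)
    return np.interp(moc.time, moc.time[ok], speed[ok])


def estimate_offset(imu: ImuRecording, moc: MocapRecording,
                    window: float = 2.0) -> SyncResult:
    """Constant clock offset between the IMU and mocap streams.

    Resamples both envelopes to a common grid and returns the lag in
    ``[-window, +window]`` maximizing the normalized cross-correlation.
    Subtracting the returned offset from the IMU timestamps aligns the two
    clocks. Requires >= 10 s of overlap after the worst-case shift.
    """
    overlap = (min(imu.time[-1], moc.time[-1] + window)
               - max(imu.time[0], moc.time[0] - window))
    if overlap < 10.0:
        raise ValueError("need at least 10 s of overlap to synchronize")

    sig_a = np.linalg.norm(imu.gyro, axis=1)
    sig_b = _mocap_speed_signal(moc)
    if np.std(sig_a) < 1e-9 or np.std(sig_b) < 1e-9:
        raise ValueError("degenerate (constant) signal; cannot synchronize")

    dt = 1.0 / _CORR_RATE
    t0 = min(imu.time[0], moc.time[0]) - window
    t1 = max(imu.time[-1], moc.time[-1]) + window
    grid = np.arange(t0, t1, dt)
    a = np.interp(grid, imu.time, sig_a, left=0.0, right=0.0)
    b = np.interp(grid, moc.time, sig_b, left=0.0, right=0.0)
    a = a - a.mean()
    b = b - b.mean()

    max_lag = int(round(window / dt))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(len(lags))
    for k, lag in enumerate(lags):
        # positive lag: the IMU envelope is delayed relative to mocap
        if lag >= 0:
            x, y = a[lag:], b[:len(b) - lag]
        else:
            x, y = a[:lag], b[-lag:]
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        corr[k] = float(x @ y) / denom if denom > 0 else 0.0
    best = int(np.argmax(corr))
    offset = float(lags[best] * dt)
    # parabolic sub-sample refinement of the correlation peak
    if 0 < best < len(lags) - 1:
        c0, c1, c2 = corr[best - 1], corr[best], corr[best + 1]
        denom = c0 - 2.0 * c1 + c2
        if denom < 0:
            offset += 0.5 * (c0 - c2) / denom * dt
    return SyncResult(offset=offset, peak_correlation=float(corr[best]))


def _interval_overlap(a_start: float, a_end: float,
                      b_start: float, b_end: float) -> float:
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def score_detections(detected: list, truth: list,
                     min_overlap: float = 0.5) -> DetectionCounts:
    """Greedy one-to-one matching of detected vs truth intervals.

    A detection matches a truth stride when their overlap covers at least
    ``min_overlap`` of the truth duration; pairs are claimed in decreasing
    overlap order. Unmatched truth strides are false negatives, unmatched
    detections false positives. Intervals need ``start_time``/``end_time``.
    """
    candidates = []
    for i, tr in enumerate(truth):
        for j, de in enumerate(detected):
            ov = _interval_overlap(tr.start_time, tr.end_time,
                                   de.start_time, de.end_time)
            if ov >= min_overlap * (tr.end_time - tr.start_time):
                candidates.append((ov, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, i, j in candidates:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        tp += 1
    return DetectionCounts(tp=tp, fp=len(detected) - tp, fn=len(truth) - tp)


def match_strides(imu_table: pd.DataFrame, mocap_table: pd.DataFrame,
                  max_midpoint_gap: float = 0.3,
                  exercise: str = "", foot: str = "", subject: str = ""
                  ) -> list[MatchedStridePair]:
    """Pair strides detected by both systems by interval-midpoint proximity.

    Greedy one-to-one pairing in increasing midpoint-distance order; strides
    left unpaired on either side are dropped. Both tables must be on the
    synchronized clock and follow the shared feature-table schema.
    """
    if imu_table.empty or mocap_table.empty:
        return []
    mid_a = (imu_table["start_s"].to_numpy() + imu_table["end_s"].to_numpy()) / 2.0
    mid_b = (mocap_table["start_s"].to_numpy() + mocap_table["end_s"].to_numpy()) / 2.0
    gaps = np.abs(mid_a[:, None] - mid_b[None, :])
    ii, jj = np.nonzero(gaps < max_midpoint_gap)
    order = np.argsort(gaps[ii, jj], kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[MatchedStridePair] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ra = imu_table.iloc[i]
        rb = mocap_table.iloc[j]
        pairs.append(MatchedStridePair(
            imu_length=float(ra["length_m"]),
            imu_velocity=float(ra["mean_horizontal_velocity_mps"]),
            mocap_length=float(rb["length_m"]),
            mocap_velocity=float(rb["mean_horizontal_velocity_mps"]),
            imu_midpoint=float(mid_a[i]),
            mocap_midpoint=float(mid_b[j]),
            exercise=exercise, foot=foot or str(ra.get("foot", "")),
            subject=subject))
    pairs.sort(key=lambda p: p.imu_midpoint)
    return pairs


def read_annotation(path) -> list:
    """Read an interval annotation CSV (columns foot, start_s, end_s)."""
    from .io import read_intervals_csv

    return read_intervals_csv(path)
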