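"""CSV / YAML readers and writers for recordings, intervals and features.

All files are plain delimited text. Floats are written with 9 significant
digits so that a re-run under the same seed is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import Foot, ImuRecording, MocapRecording, StrideInterval, StrideTruth

FLOAT_FMT = "%.9g"


def _uniform_time(time: np.ndarray) -> np.ndarray:
    """Snap a nominally uniform timestamp column back onto its exact grid.

    Nine significant digits resolve the sample period to much better than one
    sample, but late timestamps of repeating-decimal periods (e.g. 1/120 s)
    re-read with ~1e-8 s jitter, which the recording types reject.
    """
    if len(time) < 2:
        return time
    dt = float(np.median(np.diff(time)))
    return time[0] + np.round((time - time[0]) / dt) * dt


def write_imu_csv(imu: ImuRecording, path) -> None:
    df = pd.DataFrame({
        "time_s": imu.time,
        "ax": imu.accel[:, 0], "ay": imu.accel[:, 1], "az": imu.accel[:, 2],
        "gx": imu.gyro[:, 0], "gy": imu.gyro[:, 1], "gz": imu.gyro[:, 2],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_imu_csv(path) -> ImuRecording:
    df = pd.read_csv(path)
    return ImuRecording(
        time=_uniform_time(df["time_s"].to_numpy()),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
    )


def write_mocap_csv(moc: MocapRecording, path) -> None:
    df = pd.DataFrame({
        "time_s": moc.time,
        "x": moc.position[:, 0], "y": moc.position[:, 1], "z": moc.position[:, 2],
        "valid": moc.valid_mask.astype(int),
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_mocap_csv(path) -> MocapRecording:
    df = pd.read_csv(path)
    valid = df["valid"].to_numpy().astype(bool)
    pos = df[["x", "y", "z"]].to_numpy()
    pos[~valid] = np.nan
    return MocapRecording(time=_uniform_time(df["time_s"].to_numpy()),
                          position=pos, valid_mask=valid)


def write_truth_csv(truths: list[StrideTruth], path) -> None:
    df = pd.DataFrame({
        "foot": [s.foot.value for s in truths],
        "start_s": [s.start_time for s in truths],
        "end_s": [s.end_time for s in truths],
        "length_m": [s.length for s in truths],
        "mean_horizontal_velocity_mps": [s.mean_horizontal_velocity for s in truths],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_truth_csv(path) -> list[StrideTruth]:
    df = pd.read_csv(path)
    # mean velocity is recomputed so the length/duration invariant survives
    # the 9-significant-digit serialization
    return [StrideTruth(r.start_s, r.end_s, r.length_m,
                        r.length_m / (r.end_s - r.start_s), Foot(r.foot))
            for r in df.itertuples()]


def write_intervals_csv(intervals: list[StrideInterval], path) -> None:
    df = pd.DataFrame({
        "foot": [iv.foot.value for iv in intervals],
        "start_s": [iv.start_time for iv in intervals],
        "end_s": [iv.end_time for iv in intervals],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_intervals_csv(path) -> list[StrideInterval]:
    """Annotation / interval CSV with columns foot, start_s, end_s."""
    df = pd.read_csv(path)
    missing = {"foot", "start_s", "end_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    intervals = []
    for i, r in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            intervals.append(StrideInterval(float(r.start_s), float(r.end_s),
                                            Foot(r.foot)))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return intervals


def write_features_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(data: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
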