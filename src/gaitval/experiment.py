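"""Seeded end-to-end experiments: generate -> detect -> reconstruct -> match -> report.

One :class:`ExperimentConfig` describes a whole validation session (virtual
subjects, exercises, sensor error models, segmentation and matching
parameters). A single master seed deterministically derives independent named
sub-streams per subject / exercise / foot / sensor, so adding a subject never
perturbs the data of the others, and re-running a config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .agreement import (
    BlandAltmanResult,
    IccResult,
    absolute_error_quartiles,
    bland_altman,
    detection_summary,
    distance_summary,
    icc2k_for_feature,
    left_right_tests,
    pairs_frame,
)
from .inertial import FEATURE_COLUMNS, detect_stance, reconstruct_stride, segment_strides
from .mocap import compute_features_mocap, segment_strides_mocap
from .simulate import generate_trajectory, trajectory_to_imu, trajectory_to_mocap
from .sync import estimate_offset, match_strides, score_detections
from .types import (
    DetectionCounts,
    DropoutModel,
    ExerciseKind,
    ExerciseProfile,
    Foot,
    NoiseModel,
    SegmenterConfig,
)

log = logging.getLogger("gaitval")

__version__ = "0.1.0"

ALL_EXERCISES = tuple(e.value for e in ExerciseKind)


@dataclass
class MatchingConfig:
    min_overlap: float = 0.5  # fraction of truth duration for TP scoring
    max_midpoint_gap: float = 0.3  # s, stride pairing tolerance
    sync_window: float = 0.8  # s, clock-offset search half-window


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_subjects: int = 12
    exercises: tuple[str, ...] = ALL_EXERCISES
    noise: NoiseModel = field(default_factory=NoiseModel)
    dropout: DropoutModel = field(default_factory=DropoutModel)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    subject_scale_sd: float = 0.05  # between-subject stride length / cadence spread
    clock_offset_range: tuple[float, float] = (0.05, 0.45)  # s, per subject
    output_dir: str | None = None
    profile_overrides: dict = field(default_factory=dict)  # exercise -> field -> value

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exercises"] = list(self.exercises)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("noise", NoiseModel), ("dropout", DropoutModel),
                         ("segmenter", SegmenterConfig), ("matching", MatchingConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for tup in ("accel_bias", "gyro_bias", "accel_band"):
                    if tup in sub_d and isinstance(sub_d[tup], list):
                        sub_d[tup] = tuple(sub_d[tup])
                d[key] = sub(**sub_d)
        if "exercises" in d:
            d["exercises"] = tuple(d["exercises"])
        if "clock_offset_range" in d and isinstance(d["clock_offset_range"], list):
            d["clock_offset_range"] = tuple(d["clock_offset_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(gio.load_yaml(path))

    def to_yaml(self, path) -> None:
        gio.dump_yaml(_jsonable(self.to_dict()), path)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _substream_seed(master: int, *key: int) -> int:
    """Named deterministic sub-seed (< 2**31) of the master seed."""
    ss = np.random.SeedSequence(master, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class AgreementReport:
    """Aggregated validation outputs of one experiment run."""

    pairs: pd.DataFrame
    error_tables: dict[str, pd.DataFrame]  # feature -> quartile table (SI)
    icc: dict[str, IccResult]
    bland_altman: dict[str, BlandAltmanResult]
    mann_whitney: pd.DataFrame
    detections: pd.DataFrame
    distances: pd.DataFrame
    truth_errors: pd.DataFrame  # wearable vs generator ground truth
    sync: pd.DataFrame
    manifest: dict

    def summary_dict(self) -> dict:
        out: dict = {"n_pairs": int(len(self.pairs))}
        for feat in ("length", "velocity"):
            icc = self.icc.get(feat)
            ba = self.bland_altman.get(feat)
            tab = self.error_tables.get(feat)
            overall = tab[(tab.exercise == "overall") & (tab.side == "overall")]
            out[feat] = {
                "abs_error_q1": float(overall.q1.iloc[0]),
                "abs_error_median": float(overall["median"].iloc[0]),
                "abs_error_q3": float(overall.q3.iloc[0]),
                "icc2k": icc.icc2k if icc else None,
                "icc2k_ci95": list(icc.ci95) if icc else None,
                "bland_altman_bias": ba.bias if ba else None,
                "bland_altman_sd": ba.sd if ba else None,
                "fraction_outside_band": ba.fraction_outside if ba else None,
            }
        det = self.detections
        total = det[(det.exercise == "all") & (det.side == "all")].iloc[0]
        out["detection"] = {k: int(total[k]) for k in ("tp", "fp", "fn")}
        out["detection"]["true_positive_rate"] = float(total["true_positive_rate"])
        out["mann_whitney"] = self.mann_whitney.to_dict(orient="records")
        return _jsonable(out)


def _session_streams(cfg: ExperimentConfig, si: int, ei: int, fi: int
                     ) -> tuple[int, int, int]:
    return (_substream_seed(cfg.seed, si, ei, fi, 0),
            _substream_seed(cfg.seed, si, ei, fi, 1),
            _substream_seed(cfg.seed, si, ei, fi, 2))


def _subject_traits(cfg: ExperimentConfig, si: int) -> tuple[float, float, float]:
    rng = np.random.default_rng(_substream_seed(cfg.seed, si))
    length_scale = float(rng.normal(1.0, cfg.subject_scale_sd))
    cadence_scale = float(rng.normal(1.0, cfg.subject_scale_sd))
    offset = float(rng.uniform(*cfg.clock_offset_range))
    return length_scale, cadence_scale, offset


def run_session(cfg: ExperimentConfig, subject_idx: int, exercise: str,
                foot: Foot, out_dir: Path | None = None) -> dict:
    """One (subject, exercise, foot) recording through the whole pipeline."""
    ei = list(cfg.exercises).index(exercise)
    fi = 0 if foot is Foot.LEFT else 1
    seed_t, seed_n, seed_d = _session_streams(cfg, subject_idx, ei, fi)
    ls, cs, clock_offset = _subject_traits(cfg, subject_idx)

    base = ExerciseProfile.for_kind(exercise)
    overrides = dict(cfg.profile_overrides.get(exercise, {}))
    profile = replace(base,
                      mean_stride_length=base.mean_stride_length * ls,
                      cadence=base.cadence * cs, **overrides)

    traj, truths = generate_trajectory(profile, foot, seed_t)
    imu = trajectory_to_imu(traj, replace(cfg.noise, seed=seed_n,
                                          clock_offset=clock_offset))
    moc = trajectory_to_mocap(traj, replace(cfg.dropout, seed=seed_d))

    sync = estimate_offset(imu, moc, window=cfg.matching.sync_window)
    imu_s = imu.shifted(sync.offset)

    seg = cfg.segmenter
    stance = detect_stance(imu_s, seg)
    intervals = segment_strides(imu_s, seg, foot, stance)
    recon = [reconstruct_stride(imu_s, iv, seg) for iv in intervals]
    subject = f"{subject_idx + 1:02d}"
    imu_df = pd.DataFrame(
        [(k, foot.value, r.interval.start_time, r.interval.end_time, r.length,
          r.mean_horizontal_velocity) for k, r in enumerate(recon)],
        columns=FEATURE_COLUMNS)

    moc_intervals = segment_strides_mocap(moc, seg, foot)
    moc_df = compute_features_mocap(moc, moc_intervals, seg, foot)

    counts = score_detections(intervals, truths, cfg.matching.min_overlap)
    pairs = match_strides(imu_df, moc_df, cfg.matching.max_midpoint_gap,
                          exercise=exercise, foot=foot.value, subject=subject)

    truth_df = pd.DataFrame(
        [(k, foot.value, s.start_time, s.end_time, s.length,
          s.mean_horizontal_velocity) for k, s in enumerate(truths)],
        columns=FEATURE_COLUMNS)
    truth_pairs = match_strides(imu_df, truth_df, cfg.matching.max_midpoint_gap,
                                exercise=exercise, foot=foot.value, subject=subject)

    if out_dir is not None:
        stem = f"{subject}_{exercise}_{foot.value}"
        gio.write_imu_csv(imu, out_dir / f"imu_{stem}.csv")
        gio.write_mocap_csv(moc, out_dir / f"mocap_{stem}.csv")
        gio.write_truth_csv(truths, out_dir / f"truth_{stem}.csv")
        gio.write_features_csv(imu_df, out_dir / f"features_imu_{stem}.csv")
        gio.write_features_csv(moc_df, out_dir / f"features_mocap_{stem}.csv")

    distances = [
        dict(subject=subject, exercise=exercise, foot=foot.value, system=sysname,
             length_m=val)
        for sysname, frame in (("imu", imu_df), ("mocap", moc_df), ("truth", truth_df))
        for val in frame["length_m"].tolist()]
    return dict(subject=subject, exercise=exercise, foot=foot.value,
                sync=sync, clock_offset_true=clock_offset, counts=counts,
                pairs=pairs, truth_pairs=truth_pairs, distances=distances,
                n_imu=len(imu_df), n_mocap=len(moc_df), n_truth=len(truths))


def run_experiment(cfg: ExperimentConfig, write_files: bool | None = None
                   ) -> AgreementReport:
    """Run every (subject, exercise, foot) session and aggregate the report.

    A session that fails is logged and skipped; the run continues.
    """
    out_dir = None
    if write_files is None:
        write_files = cfg.output_dir is not None
    if write_files:
        out_dir = Path(cfg.output_dir or "gaitval_out")
        (out_dir / "sessions").mkdir(parents=True, exist_ok=True)

    all_pairs = []
    truth_pairs = []
    counts: dict[tuple[str, str], DetectionCounts] = {}
    distances_rows: list[dict] = []
    sync_rows = []
    for si in range(cfg.n_subjects):
        for ex in cfg.exercises:
            for foot in (Foot.LEFT, Foot.RIGHT):
                try:
                    res = run_session(cfg, si, ex, foot,
                                      out_dir / "sessions" if out_dir else None)
                except Exception:  # noqa: BLE001 - partial failure tolerated
                    log.exception("session failed: subject %d %s %s; skipping",
                                  si + 1, ex, foot.value)
                    continue
                all_pairs.extend(res["pairs"])
                truth_pairs.extend(res["truth_pairs"])
                key = (ex, foot.value)
                counts[key] = counts.get(key, DetectionCounts(0, 0, 0)) + res["counts"]
                distances_rows.extend(res["distances"])
                sync_rows.append((res["subject"], ex, foot.value,
                                  res["sync"].offset, res["clock_offset_true"],
                                  res["sync"].peak_correlation))

    pairs_df = pairs_frame(all_pairs)
    error_tables = {f: absolute_error_quartiles(all_pairs, f)
                    for f in ("length", "velocity")} if all_pairs else {}
    icc = {f: icc2k_for_feature(all_pairs, f)
           for f in ("length", "velocity")} if len(all_pairs) >= 5 else {}
    ba = {f: bland_altman(all_pairs, f) for f in ("length", "velocity")} \
        if len(all_pairs) >= 2 else {}
    mw = left_right_tests(all_pairs) if all_pairs else pd.DataFrame()
    det = detection_summary(counts)
    dist = distance_summary(pd.DataFrame(distances_rows)) if distances_rows \
        else pd.DataFrame()
    terr = pairs_frame(truth_pairs)
    sync_df = pd.DataFrame(sync_rows, columns=["subject", "exercise", "foot",
                                               "offset_est_s", "offset_true_s",
                                               "peak_correlation"])

    manifest = {
        "config": _jsonable(cfg.to_dict()),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "n_sessions": int(len(sync_rows)),
        "n_pairs": int(len(all_pairs)),
    }
    report = AgreementReport(pairs=pairs_df, error_tables=error_tables, icc=icc,
                             bland_altman=ba, mann_whitney=mw, detections=det,
                             distances=dist, truth_errors=terr, sync=sync_df,
                             manifest=manifest)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: AgreementReport, out_dir: Path) -> None:
    """Write the report tables (cm / cm/s units), JSON summary and manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gio.write_features_csv(report.pairs, out_dir / "matched_pairs.csv")
    for feat, tab in report.error_tables.items():
        t = tab.copy()
        scale = 100.0  # m -> cm, m/s -> cm/s
        for c in ("q1", "median", "q3"):
            t[c] = t[c] * scale
        unit = "cm" if feat == "length" else "cm_per_s"
        t = t.rename(columns={c: f"{c}_{unit}" for c in ("q1", "median", "q3")})
        gio.write_features_csv(t, out_dir / f"error_table_{feat}.csv")
    gio.write_features_csv(report.detections, out_dir / "detection_summary.csv")
    gio.write_features_csv(report.distances, out_dir / "distance_summary.csv")
    gio.write_features_csv(report.sync, out_dir / "sync_summary.csv")
    if not report.mann_whitney.empty:
        gio.write_features_csv(report.mann_whitney, out_dir / "mann_whitney.csv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)


def validate_against_annotation(imu_csv, annotation_csv,
                                seg: SegmenterConfig | None = None,
                                min_overlap: float = 0.5) -> DetectionCounts:
    """Score the inertial segmentation against a manual annotation file."""
    seg = seg or SegmenterConfig()
    imu = gio.read_imu_csv(imu_csv)
    truth = gio.read_intervals_csv(annotation_csv)
    detected = segment_strides(imu, seg, truth[0].foot if truth else Foot.LEFT)
    return score_detections(detected, truth, min_overlap)
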