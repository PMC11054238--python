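# gaitval

Analytical validation of ankle-worn IMU gait reconstruction against optical
motion capture, on fully synthetic data.

`gaitval` simulates paired recordings of the same walking bout as seen by two
measurement systems — a 100 Hz ankle-mounted inertial sensor (accelerometer +
gyroscope) and a 120 Hz optical motion-capture rigid body — then runs two
independent stride-measurement pipelines and quantifies their agreement:

- **Simulator** — a kinematic ankle-trajectory model for five exercises
  (normal walk, fast walk, dual-task walk, half turns, timed up-and-go) with
  per-stride ground truth, an IMU error model (white noise, constant biases,
  clock offset) and an optical error model (residual noise, speed-dependent
  marker dropout).
- **Inertial pipeline** — gait-phase state-machine stride segmentation,
  gravity-anchored attitude initialization, strapdown integration with
  zero-velocity updates and a linear velocity-ramp drift correction
  (equivalently: removal of a quadratic position drift), yielding stride
  length and mean horizontal velocity.
- **Mocap pipeline** — the same stride features from optical positions, with
  strides touched by occlusion gaps rejected as incomplete.
- **Matching & statistics** — cross-correlation clock synchronization,
  TP/FP/FN detection scoring, stride pairing, absolute-error quartiles,
  ICC(2,k) with F-based confidence intervals, Bland–Altman analysis and
  Mann–Whitney left-vs-right tests.

Everything is seeded: a single master seed derives independent named
sub-streams per subject, exercise, foot and sensor, and re-running a
configuration is byte-identical.

## Worked example

Simulate one normal-walk session, measure it with both pipelines, pair the
strides and compute agreement statistics:

```sh
gaitval simulate --exercise normal_walk --seed 11 --out demo
# wrote 54 strides to demo

gaitval reconstruct demo/imu.csv --out demo/imu_features.csv
# 54 strides -> demo/imu_features.csv

gaitval mocap-features demo/mocap.csv --out demo/moc_features.csv
# 27 complete strides -> demo/moc_features.csv   (dropout rejects the rest)

gaitval match demo/imu_features.csv demo/moc_features.csv --out demo/pairs.csv
# 24 matched pairs -> demo/pairs.csv

gaitval report demo/pairs.csv --out demo/report
cat demo/report/summary.json
```

which reports, for stride length, ICC(2,k) ≈ 0.99997 with a bias of
−0.5 mm and an SD of differences of 1.4 mm. (The `match`/`report` stages
assume synchronized clocks; `run-all` below performs the clock-offset
estimation automatically.)

The full study-scale experiment — 12 virtual subjects × 5 exercises × both
feet, default error models — runs in well under a minute:

```sh
gaitval run-all --seed 0 --out results/run0
```

With the default configuration and seed 0 this yields 5369 detected strides
(true-positive rate 1.000, no false positives), 2847 jointly measured
stride pairs, a median absolute stride-length error of 1.3 mm
(Q3 2.4 mm) and ICC(2,k) = 0.99999 for length; velocity agrees with a
median absolute error of 5.0 mm/s and ICC(2,k) = 0.9968. The optical
system's dropout roughly halves its measured walking distance relative to
the inertial system, so jointly detected strides are always scarcer than
inertial detections.

From Python:

```python
from gaitval import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(seed=0))
print(report.summary_dict()["length"]["abs_error_median"])  # metres
```

To score the inertial segmentation against a manual annotation CSV
(columns `foot,start_s,end_s`):

```sh
gaitval validate-annotation recording.csv annotation.csv
```

## Reproduction

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities (detection-rate
arithmetic, optical-residual ratios, study-scale ICC simulation) at run time
and writes them as JSON.

See `docs/methods.md` for the kinematic model, sensor error models, the
drift-correction mathematics and the calibration rationale behind every
default parameter.
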