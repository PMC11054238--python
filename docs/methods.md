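# Methods

This note documents the mathematical models behind `gaitval`: the synthetic
gait generator, the two measurement pipelines, the synchronization and
matching layer, and the agreement statistics — together with the rationale
for every non-obvious default parameter.

## 1. Synthetic gait generator (`gaitval.simulate`)

### Trajectory model

The generator synthesizes the 3-D trajectory of a point on the ankle at an
internal rate of 600 Hz, then derives both sensors' outputs from that single
ground-truth trajectory, so any disagreement between the pipelines reflects
the sensor models and algorithms, never two different notions of "truth".

Each stride is a stance–swing cycle with a fixed stance fraction of 0.35 of
the gait cycle (configurable). During stance the ankle is exactly
stationary — this is the modelling assumption that makes zero-velocity
updates exact on noiseless data. During swing, with phase
`u = (t − t_toe_off) / T_swing ∈ [0, 1]`:

- **Horizontal progression** follows the quintic smoothstep
  `s(u) = 6u⁵ − 15u⁴ + 10u³`, which has zero velocity *and* zero
  acceleration at both ends, so the transition into and out of stance is C².
- **Vertical motion** is the bump `h(u) = H · 64 u³ (1 − u)³` with swing
  height `H = 0.12` m. The cubic-cubic form has zero value, slope and
  curvature at `u ∈ {0, 1}`; an earlier quadratic-quadratic form
  (`16u²(1−u)²`) had non-zero end curvature, which produced a ≈6 m/s²
  acceleration discontinuity at toe-off/heel-strike and limited how well any
  integrator could reconstruct the trajectory. With the C² form, noiseless
  double integration of the exact signals recovers positions to well under a
  millimetre.
- **Orientation**: foot pitch follows a smooth ±30° swing motif
  (`sin(2πu)` shaped by the bump), yaw follows the path heading, roll is 0.
  This makes the gyroscope informative for segmentation while staying
  analytic.

Per-stride lengths are drawn from a per-exercise Gaussian
(mean/SD/cadence defaults per exercise kind), and a per-subject scale factor
perturbs mean stride length and cadence (SD 5%).

### Track geometry and exercises

Walking exercises traverse a stadium-shaped track: 4 m straights joined by
half-circle turns of radius 1.0 m. The radius is a compromise: small enough
that turning strides are visibly shorter than straight ones (as in real
shuttle walking), large enough that the turn curvature does not violate the
per-stride length model. Each foot walks on its own lateral offset
(±0.10 m) from the centreline; with the turn direction fixed, the outer foot
travels measurably farther than the inner one over a session, giving a
systematic left/right asymmetry for the Mann–Whitney layer to examine.

Five exercise kinds are modelled: `normal_walk`, `fast_walk`,
`dual_task_walk` (slower, more variable), `half_turns` (seven cued
about-turns within a fixed duration) and `timed_up_and_go` (three 3 m
out-and-back repetitions with small vertical sit/stand ramps). A 2 s
stationary lead-in precedes all movement so that attitude initialization and
stance detection have a clean anchor.

### IMU error model

The trajectory is differentiated analytically to body-frame specific force
(kinematic acceleration minus gravity, rotated into the body frame;
`g = 9.81 m/s²`, z-up) and angular rate, sampled at exactly 100 Hz. The
error model adds white noise (accelerometer SD 0.02 m/s², gyroscope SD
0.002 rad/s), constant per-axis biases (order 10⁻² m/s² and 10⁻⁴ rad/s) and
a constant clock offset (default 0.25 s; per-subject uniform on
[0.05, 0.45] s in experiments).

### Optical error model

The trajectory is sampled at 120 Hz with small residual position noise. A
sample is occluded with probability `min(1, p₀ + γ·|v|)` — dropout grows
with speed, as marker tracking degrades with motion — and each contiguous
occlusion run is widened on both sides (`gap_extension`), mimicking a
rigid-body tracker losing and re-acquiring lock. Occluded samples are NaN
and flagged invalid.

**Calibration.** `p₀ = 0.001` and `γ = 0.003 s/m` were chosen (before the
contract tests were written) so that the optical system's total measured
walking distance is roughly half the inertial system's on fast walking —
the qualitative regime of real capture volumes, where a large share of
strides is touched by at least one gap and rejected. Over 8 seeds the
mocap/IMU distance ratio spans ≈0.41–0.57 (mean 0.50).

## 2. Inertial pipeline (`gaitval.inertial`)

### Stance detection and stride segmentation

Stance is detected where the sliding-window RMS of gyroscope magnitude
(window = `min_stance_duration`) falls below `gyro_energy_threshold`, with
morphological closing to remove sub-swing gaps. A
STANCE → SWING → SWING-PEAK → STANCE state machine then emits one stride
interval per complete cycle — toe-off where the stance mask falls, mid-swing
at the gyro-magnitude maximum, heel strike where the mask rises — with
interval boundaries at the surrounding stance midpoints. Intervals are
disjoint, sorted, and constrained to plausible durations.

**Threshold calibration.** `gyro_energy_threshold = 0.05 rad/s` was set by
scanning thresholds on *noiseless* synthetic data and choosing the value
maximizing stance-mask agreement with the generator's ground-truth mask
(≥99% agreement across seeds, noiseless and noisy). It sits ≈14× above the
RMS noise floor of the default gyro model, so it is far from the
noise-driven failure regime.

### Attitude initialization and strapdown reconstruction

The initial attitude of each stride is anchored to gravity: the rotation
(zero yaw — unobservable without a magnetometer) mapping the mean stance
accelerometer vector to (0, 0, +9.81). Attitude is then propagated by
midpoint-rule quaternion integration of the gyro (local error O(dt³)).

Per stride:

1. rotate specific force to the inertial frame and add (0, 0, −g);
2. trapezoidal integration to raw velocity with `v(t₀) = 0`;
3. **drift correction**: subtract the linear ramp
   `c(t) = ((t − t₀)/(t₁ − t₀)) · v_raw(t₁)`, so that corrected velocity is
   *exactly* zero at both stride boundaries (both are stance midpoints, where
   the true velocity is zero);
4. trapezoidal integration of corrected velocity to position;
5. stride length = horizontal (x, y) straight-line displacement;
   mean horizontal velocity = length / duration.

The position-level error removed by step 3 is quadratic in time. The
correction cancels a *constant* inertial-frame accelerometer bias `b`
exactly: the bias contributes `v_b(t) = b·(t − t₀)` to raw velocity, which
is precisely linear and therefore equals its own ramp; the subtraction
removes it identically (a unit test verifies max position deviation
< 10⁻⁹ m). On noiseless synthetic walks the reconstruction recovers
per-stride lengths with sub-millimetre median error.

## 3. Mocap pipeline (`gaitval.mocap`)

Stride segmentation on the optical side uses the same state-machine logic on
the speed signal derived from positions; a stride is **complete** only if no
sample inside it is occluded, and incomplete strides are discarded. Features
(length, mean horizontal velocity) are computed by the *same shared
implementation* (`gaitval.features.stride_features`) as the inertial
pipeline — asserted by identity in the tests — so feature-definition skew is
impossible.

## 4. Synchronization, scoring and matching (`gaitval.sync`)

### Clock-offset estimation

The IMU and optical clocks are synchronized by normalized cross-correlation
of two envelopes resampled to a common 100 Hz grid: gyroscope magnitude
versus optical speed, searched over ±`sync_window` (default 0.8 s, below the
gait period to avoid period ambiguity). Two details matter:

- occluded spans of the speed envelope are **bridged by linear
  interpolation**, not zeroed — zeroing produced speed-dependent asymmetric
  notches that biased the correlation peak by tens of milliseconds;
- the discrete peak is refined by **parabolic interpolation** over the three
  surrounding correlation samples.

With both, the estimated offset is within ≈2 ms of truth across exercises,
seeds and injected offsets — a fifth of an IMU sample.

### Detection scoring and stride pairing

Detected intervals are scored against truth greedily by temporal overlap: a
detection is a true positive if it overlaps a (not previously claimed) truth
stride by more than `min_overlap` (default 0.5) of the truth duration;
unmatched detections are false positives, unmatched truths false negatives.
Cross-system stride pairing is greedy on interval-midpoint distance with a
`max_midpoint_gap` of 0.3 s; matching is one-to-one and symmetric in count.

## 5. Agreement statistics (`gaitval.agreement`)

- **Absolute-error quartiles**: Q1/median/Q3 of |IMU − mocap| per
  (exercise, side) and overall (linear-interpolation quantiles, the NumPy
  default).
- **ICC(2,k)** — two-way random effects, absolute agreement, average
  measures over k = 2 systems — is computed from the two-way ANOVA mean
  squares, `ICC(2,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)`, with a 95%
  CI from the standard F-based interval for the single-measure form stepped
  up via the Spearman–Brown relation. The implementation is validated
  against an independent ANOVA oracle (agreement to 10⁻¹⁰) and against
  `pingouin`'s ICC(A,k). Perfect agreement (zero error mean square) is
  special-cased to ICC = 1 with a degenerate CI.
- **Bland–Altman**: per-pair difference vs mean; bias, SD of differences,
  band `bias ± m·SD` (default multiplier 1), and the fraction of points
  outside the band. For Gaussian differences with `m = 1` that fraction
  concentrates near 0.317.
- **Mann–Whitney U** (two-sided), applied to left- vs right-foot error
  distributions per exercise and globally and to both features: exact
  enumeration for tie-free samples with both n ≤ 8 (verified equal to
  exhaustive permutation), otherwise the tie-corrected normal approximation
  with continuity correction (type-I error calibrated at 0.05 ± 0.02 in
  2000-rep simulation). Computation is delegated to SciPy behind the module
  interface.

## 6. Determinism and seeding

A single master seed drives everything. Named sub-streams are derived with
`numpy.random.SeedSequence(master, spawn_key=(subject, exercise, foot,
sensor))`, reduced modulo 2³¹; consequently adding a subject or exercise to a
configuration never perturbs the data of existing ones, and re-running a
configuration reproduces every output file byte-for-byte (floats serialized
with 9 significant digits; readers snap timestamps back onto the exact
uniform grid).

## 7. Limitations

- The ankle model is kinematic, not biomechanical: no soft-tissue artifact,
  no mid-stance micro-motion, no magnetometer/barometer, and turning is
  modelled geometrically rather than dynamically.
- Stance velocity is exactly zero by construction, which flatters
  zero-velocity updates relative to real gait.
- Strides are pooled across subjects in the statistics (no mixed-effects
  modelling of within-subject correlation).
- Occlusion is modelled per rigid-body sample, not per marker/camera ray.
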