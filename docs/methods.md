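# Methods

This note records how `frailtykit` models the 20-second repetitive elbow
flexion/extension test, the defaults it ships with and why, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would want to know about.

## Signal model and conventions

The quantity every feature is computed from is the forearm angular velocity
ω(t) in deg/s on a uniform time grid, with the **flexion-positive**
convention: the sign of the series is normalised so that the first prominent
peak (the first sample whose |ω| reaches half the global maximum) is
positive. In a 2-D projection the anatomical flexion direction is not
identifiable — a left arm mirrors a right arm — but every feature depends
only on the |ω| structure and the alternation of half-cycles, so the choice
is consequence-free. The first-lobe rule is preferred over "make the global
extremum positive" because with near-symmetric flexion and extension the
global extremum can fall on either kind depending on noise, which would flip
the series between two recordings of the same movement; the first lobe is
the same physical stroke in both.

Image coordinates are raster coordinates (origin top-left, y down); the
video path converts to mathematical angles (counter-clockwise positive,
x-axis zero) internally, so a wrist exactly to the right of the elbow is at
θ = 0°.

**Video path.** Per-frame wrist/elbow keypoints (30 fps nominal) give
θ(t) = atan2(−Δy, Δx) of the elbow→wrist vector, unwrapped; when a shoulder
joint is present with sufficient confidence the elbow-interior angle
(180° for a straight arm) is used instead, and the per-half-cycle range of
motion is then read directly off θ. θ is low-pass filtered (zero-phase
4th-order Butterworth, cutoff 6 Hz) and differentiated with an interpolating
cubic spline. Central differences were rejected: their O(h²) transfer
function attenuates the movement's third harmonic by ≈1.3 % in ω and ≈13 %
in the derived acceleration at 30 fps, which broke frame-rate independence
of the power feature; the spline derivative keeps 30 and 60 fps renderings
of the same movement within 2 % on every feature.

**Sensor path.** The tri-axial wrist gyroscope (100 Hz nominal) is resampled
to a uniform grid and projected onto its first principal direction — the
maximum-variance linear combination of the three channels — which is the
flexion/extension axis as long as the dominant wrist rotation during the
test is elbow flexion/extension. Total variance below 1 deg²/s² raises a
"no movement detected" error. The pipeline then applies the same 6 Hz
zero-phase low-pass as the video path so that both paths measure identically
filtered signals (the projection function itself does not filter).

The 6 Hz cutoff sits far above the ≲1.5 Hz movement band (content at
1.5 Hz is preserved within 2 %) while suppressing pixel jitter; movement
reversals are sharp enough that a much lower cutoff would round the peaks
that the weakness feature depends on.

## Cycle segmentation

Half-cycles are sign-consistent runs of ω between zero crossings. A ±2 deg/s
hysteresis band suppresses chatter near zero; run boundaries are then
refined to the interpolated zero crossing, so on clean signals the result
matches a plain sign-run scan to within one sample (asserted against a
brute-force oracle in the tests). A run becomes a half-cycle when its
extreme |ω| ≥ 10 deg/s, it lasts ≥ 0.1 s, and its peak is interior.
Sub-threshold runs are noise blips splitting a real half-cycle: the weakest
is removed and its (same-signed) neighbours merged, iterating until all runs
pass. The thresholds are far below observed peaks (hundreds of deg/s) and
far above velocity noise, so results are insensitive to their exact values.
Partial half-cycles touching the recording edges are kept when they contain
an interior peak and meet the thresholds — the test starts and ends
mid-movement, and dropping them would bias the repetition count low.

Peak times are localised sub-sample by a least-squares parabola over the
contiguous samples within 75 % of the run extreme. The wide fit (rather
than a 3-point parabola) both removes the frame-period quantisation of
rise/fall times at 30 fps and averages measurement noise in the peak time,
which the rise-time variability features are sensitive to.

## The 20 features

Per full cycle (a flexion immediately followed by an extension): speed =
max ω − min ω; angular acceleration = derivative of the already-filtered ω
(no second smoothing pass, which would bias amplitudes); power = speed ×
acceleration range; cycle time. Per half-cycle: duration, rise (onset→peak),
fall (peak→offset), and range of motion = |∫ω dt| by trapezoidal
integration. Per-cycle extrema and the acceleration are evaluated on a
200 Hz spline-upsampled copy of the cycle so that a 30 fps video and a
100 Hz gyro measure the same waveform.

Aggregates: level features are per-cycle means; a full cycle is counted for
`n_repetitions` (half-cycle counts are also exposed on `CycleSet`).
Exhaustion features are `100·(mean_last − mean_first)/mean_all` with cycles
assigned to the first/last window by their temporal midpoint (half-open at
the 10 s split; a midpoint exactly at the split goes to the last window).
The whole-test mean as denominator makes the measure symmetric in the two
windows. Unsteadiness features are `100·sd(n−1)/mean` across cycles.
Speed is computed per cycle and then averaged (rather than as a global
range) because the per-cycle series is needed for its CV anyway, keeping the
level/variability pair coherent.

A feature that cannot be computed (no cycles, an empty window, fewer than
two cycles for a CV, a zero mean) is flagged unavailable with a structured
reason — never silently zeroed, since zero is a meaningful value for most of
these quantities.

## The frailty index

FI_raw = −1.7357×10⁻³·Ph₁ − 1.2026×10⁻³·Ph₂ + 0.36848×10⁻³·Ph₃
− 0.49396·Ph₄ + 0.48974·Ph₅ + 0.24495, clamped to [0, 1] for reporting
(both values are returned; the linear form can leave the interval even
though the published empirical range did not). The input units — degrees,
signed percent, milliseconds, and unitless CV fractions — are not printed
alongside the published equation; they were fixed by requiring that the
published cohort mean feature values (111 deg, −4.1 %, 343.6 ms, 0.08,
0.07) reproduce the published cohort mean index (0.18) through the linear
form, which only this convention does. That derivation is kept as a
regression test, exploiting the model's linearity (index of the mean equals
mean of the raw indices).

## Agreement statistics

Differences in Bland–Altman analysis are method A − method B with A the
benchmark (sensor) method; limits of agreement are bias ± 1.96·SD(n−1).
Pearson r is labelled on |r| with the conventional bands (≥0.8 very strong,
0.6–0.8 strong, 0.4–0.6 moderate, else weak); p-values are two-sided
throughout. Cohen's d uses the pooled-SD formula and the bands ≥1.3 very
large, 0.8–1.3 large, 0.5–0.8 medium, 0.2–0.5 small, else none. The
adjusted group comparison is OLS of the outcome on intercept + group + age +
BMI (statsmodels); the reported p is the two-sided t-test on the group
coefficient. Cohen's d is reported from the raw group values, with an
adjusted variant (|group coefficient| / residual SD) exposed separately,
because published practice does not specify whether effect sizes were
covariate-adjusted. A covariate that is constant across subjects is absorbed
into the intercept; genuine rank deficiency raises an error naming the
collinear columns.

## Synthetic data

The generator emulates a supervised 20-s test seen side-on: θ(t) is a train
of half-cosine flexion/extension strokes (half-cosines rather than a pure
sinusoid so flexion and extension durations can differ via
`flexion_fraction`). Per cycle, the period and amplitude are jittered with
the programmed CVs, and the mean amplitude ramps linearly from
(1+decay)·rom to (1−decay)·rom. With this parameterisation the expected
first-vs-last-window decline in per-cycle speed is exactly −100·decay
percent, i.e. `decay` programs the exhaustion biomarker directly. (A naive
"fraction of amplitude lost" parameter d would produce a window delta of
only −100·(d/2)/(1−d/2); the window-referenced definition is the one a
recovery test can be stated against.)

Defaults describe a plausible moderately-frail adult and match the scales of
published sensor-based cohort values: cycle period 0.7 s (flexion time
350 ms), ROM 110°, jitter CVs 0.08 (time-variability CVs of 7–8 %), decay
0.05, angular-velocity noise 2 deg/s, keypoint noise 1 px on a 200 px
forearm, 30 fps video, 100 Hz gyro with the movement axis rotated by
(30°, 20°, 10°) Euler angles. All randomness derives from the integer seed;
every generator is bitwise-deterministic, and the noise streams of the
different renderers are independent sub-streams so the clean series, the
keypoint track and the gyro recording share the identical ground-truth
movement.

What it does *not* emulate — and therefore what passing tests do not show
about real recordings: pose-estimator failure modes (identity swaps,
occlusion, confidence collapse beyond simple low-confidence gaps),
out-of-plane arm motion and camera perspective, soft-tissue/sensor-mount
artefacts, gyroscope bias drift, and any correlation between noise and
movement phase. Cross-path agreement on synthetic cohorts is a consistency
check of the two measurement models, not a clinical validation.

## Numerical choices and degenerate inputs

* Resampling is linear interpolation; video stays at its native frame rate,
  the gyro at 100 Hz — features are time-based so the rates need not match.
* `filtfilt` padding is capped at the series length; a cutoff at or above
  Nyquist disables filtering rather than erroring.
* Keypoint gaps: confidence below 0.1 marks a joint missing; internal gaps
  of ≤ 5 frames are linearly interpolated (interpolated frames keep
  confidence 0.1 as a marker), longer gaps and > 20 % missing wrist/elbow
  frames raise quality errors; missing frames at the recording edges are
  trimmed. These thresholds are this package's own policy — supervised
  recordings rarely trip them.
* Integration windows interpolate ω at their exact endpoints, so
  half-cycle ROM is insensitive to where the zero crossing falls between
  samples.
* Zero-length wrist−elbow vectors, non-monotone timestamps, non-finite
  values and empty windows raise typed errors naming the offending frame or
  record; the CLI maps error classes to distinct exit codes (2 parse,
  3 quality, 4 computation, 5 configuration).

## Problem sizes used in the test suite

The property suites run at the protocol's natural scale — 20-second signals
at 30 fps (video) and 100 Hz (gyro): 50 noiseless subjects for the
segmentation-oracle equivalence, 20 seeded runs for exhaustion-decay
recovery (programmed 20 % decline recovered within ±2 points under 2 deg/s
noise), a 30-subject cohort rendered through both paths for the agreement
suite (every feature r ≥ 0.95, FI mean absolute difference ≤ 0.02), and a
12-subject fixture for the least-squares oracle. The whole suite completes
in a few seconds on one CPU.

## Known limitations

* The video path assumes the movement plane is roughly parallel to the image
  plane; no 3-D reconstruction or camera calibration is attempted.
* The frailty model's coefficients are constants from prior work; no
  re-estimation, calibration or uncertainty quantification is provided.
* Whether the original index computation clamps to [0, 1] or simply never
  left it empirically is unknown; clamping is this package's choice, and the
  raw value is always reported alongside.
* `n_repetitions` counts full flexion–extension pairs; if a protocol counts
  half-cycles, use `CycleSet.n_half_cycles`.
* The pose-backend contract ships with a scripted mock only; plugging in a
  real estimator (and decoding video) is intentionally out of scope.
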