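# frailtykit

Kinematic frailty phenotyping from the 20-second repetitive elbow
flexion/extension test — without a wearable sensor.

Physical frailty screening matters for populations (COPD patients, geriatric
inpatients) for whom gait-based tests are unsafe or infeasible. A validated
alternative is a 20-second test in which the subject flexes and extends the
dominant elbow as fast as possible: the forearm angular-velocity trace
carries signatures of **slowness**, **weakness**, **rigidity**, **exhaustion**
and **unsteadiness**, which combine into a continuous 0–1 **frailty index**
(FI). `frailtykit` implements that pipeline twice over:

* a **video path** — per-frame 2-D wrist/elbow keypoints (e.g. from a pose
  estimator run on tablet video at 30 fps) → forearm angle → angular
  velocity;
* a **sensor path** — a tri-axial wrist gyroscope at 100 Hz → principal-axis
  projection → the same angular velocity,

plus the agreement statistics (Pearson bands, Bland–Altman limits, Cohen's
*d*, age/BMI-adjusted group comparison) used to validate the sensor-less
path against the gyroscope benchmark, and a synthetic-movement generator so
every stage is testable without recordings.

## The model

The angular-velocity series ω(t) (deg/s, flexion positive) is segmented into
alternating flexion/extension half-cycles by zero crossings (±2 deg/s
hysteresis) with peak detection. Twenty digital biomarkers are computed per
test: per-cycle means (speed = ω range, power = ω range × angular-
acceleration range, rise/fall/flexion/extension/cycle times, repetitions,
range of motion by per-half-cycle integration of ω), first-vs-last-10-s
percent changes (exhaustion), and cycle-to-cycle coefficients of variation
(unsteadiness). Five of them feed a fixed linear model:

```
FI = −1.7357×10⁻³·Ph₁ − 1.2026×10⁻³·Ph₂ + 0.36848×10⁻³·Ph₃
     − 0.49396·Ph₄ + 0.48974·Ph₅ + 0.24495
```

with Ph₁ range of motion (deg), Ph₂ decline in power (signed %), Ph₃ flexion
time (ms), Ph₄/Ph₅ flexion/extension-time variability (CV as a fraction).
The coefficients come from a previously published regression and are treated
as constants; the reported index clamps FI to [0, 1] and also exposes the
raw value.

## Worked example

Simulate one subject (seed 42, programmed 10 % exhaustion decline), then run
both pipeline paths:

```sh
$ frailtykit simulate --seed 42 --decay 0.1 --out-dir subject01
$ frailtykit extract-video subject01/keypoints.csv \
    --record-id subject01 --out-features video_features.csv
{
 "clamped": false,
 "frailty_index": 0.20110510767123385,
 "inputs": {
  "cv_extension_time_fraction": 0.060119902124012005,
  "cv_flexion_time_fraction": 0.06251974979628148,
  "decline_in_power_percent": -12.287968583858994,
  "flexion_time_ms": 354.81730086024044,
  "range_of_motion_deg": 108.27121485598825
 },
 "n_half_cycles": 56,
 "raw_linear_value": 0.20110510767123385,
 "record_id": "subject01"
}
$ frailtykit extract-sensor subject01/gyro.csv --record-id subject01
{ ... "frailty_index": 0.2010115605716266, ... }
```

Reading the output: the subject performed 28 full flexion–extension cycles
(56 half-cycles) with a mean flexion time of 355 ms and a range of motion of
108°; power declined 12 % between the first and last 10 seconds; the frailty
index is ≈ 0.20 on both paths (video vs gyroscope differ by 0.0001 here —
the same movement, measured two ways). `video_features.csv` holds all 20
biomarkers with unit-suffixed headers.

Agreement between the two paths on a small synthetic cohort:

```sh
$ frailtykit compare sensor.csv video.csv --out agreement.csv
                   n  pearson_r      r_label  pearson_p     bias  ...  loa_upper
feature
speed              8          1  very strong  1.158e-14  0.05919  ...       2.32
range_of_motion    8     0.9989  very strong  2.933e-09   0.7794  ...      1.408
delta_power        8     0.9977  very strong  3.171e-08  -0.3461  ...      1.825
cv_flexion_time    8     0.9996  very strong  2.082e-10  0.08606  ...     0.1674
...
```

`--plots DIR` additionally writes a Bland–Altman plot and a method-vs-method
scatter per feature. Convention: table A is the benchmark (sensor) method,
and differences are A − B.

The same functionality is available as a library — see
`frailtykit.run_video`, `frailtykit.analyze_gyro`,
`frailtykit.extract_features`, `frailtykit.compute_frailty_index`,
`frailtykit.SyntheticParams`.

## Layout

| module | role |
| --- | --- |
| `frailtykit.io` | keypoint/gyro/feature-table readers and writers, pose-backend registry |
| `frailtykit.kinematics` | keypoints or gyro → flexion-positive ω(t); per-window angle integration |
| `frailtykit.cycles` | zero-crossing + peak-detection half-cycle segmentation |
| `frailtykit.features` | the 20 phenotype biomarkers |
| `frailtykit.frailty` | the fixed linear frailty-index model |
| `frailtykit.agreement` | Pearson / Bland–Altman / Cohen's d / adjusted comparison |
| `frailtykit.synthetic` | seeded movement generator (keypoints, gyro, clean ω) |
| `frailtykit.cli` | `frailtykit` command: extract-video, extract-sensor, index, compare, simulate |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
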