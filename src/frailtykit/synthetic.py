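"""Synthetic elbow flexion/extension test data with controllable phenotype
structure.

The generator emulates the standard 20-second repetitive elbow
flexion/extension protocol: the forearm angle is a concatenation of
half-cosine flexion and extension strokes.  Each phenotype axis has its own
dial —

* ``rom`` (deg): per-half-cycle angular excursion → rigidity;
* ``cycle_period`` (s): flexion + extension duration → slowness;
* ``decay``: programmed fractional decline of the per-cycle amplitude between
  the first and last half of the test → exhaustion.  The mean amplitude ramps
  linearly from (1+decay)·rom to (1−decay)·rom, which makes the expected
  first-vs-last-window speed change exactly −100·decay percent;
* ``period_jitter_cv`` / ``amplitude_jitter_cv``: cycle-to-cycle lognormal-free
  Gaussian jitter → unsteadiness;
* ``omega_noise_sd`` (deg/s), ``keypoint_noise_sd`` (px): measurement noise.

The same ground-truth θ(t) can be rendered three ways — a clean/noisy
angular-velocity series, a keypoint track (wrist rotating about a fixed elbow
anchor in raster coordinates, y down), or a tri-axial gyroscope recording
(ω embedded along a known 3-D axis) — so the video and sensor pipelines can
be validated against each other on common ground truth.  All randomness
derives from ``seed``; every generator is bitwise-deterministic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import json

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .io import GyroRecording, KeypointTrack, PoseBackend, write_gyro, write_keypoints
from .kinematics import AngleSeries, AngularVelocitySeries

MIN_JITTER_FACTOR = 0.05  # floor on jittered multipliers: periods/amplitudes stay positive


@dataclass
class SyntheticParams:
    """Ground-truth parameters of one simulated 20-s test."""

    duration: float = 20.0  # s
    cycle_period: float = 0.7  # s per full flexion+extension cycle
    rom: float = 110.0  # deg per half-cycle
    decay: float = 0.05  # programmed first/last-window fractional decline
    period_jitter_cv: float = 0.08
    amplitude_jitter_cv: float = 0.08
    omega_noise_sd: float = 2.0  # deg/s, also used for gyro channel noise
    keypoint_noise_sd: float = 1.0  # px
    forearm_length: float = 200.0  # px
    elbow_anchor: tuple[float, float] = (320.0, 360.0)  # px, raster coords
    fps: float = 30.0
    gyro_rate: float = 100.0
    gyro_rotation: tuple[float, float, float] = (30.0, 20.0, 10.0)  # xyz Euler, deg
    flexion_fraction: float = 0.5  # share of the cycle spent in flexion
    baseline_angle: float = 20.0  # deg, forearm angle at full extension
    include_shoulder: bool = False
    upper_arm_length: float = 250.0  # px, only used when include_shoulder
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.rom <= 0 or self.cycle_period <= 0:
            raise ConfigurationError("duration, rom and cycle_period must be positive")
        if not (0 <= self.decay < 1):
            raise ConfigurationError("decay must lie in [0, 1)")
        if min(self.period_jitter_cv, self.amplitude_jitter_cv) < 0:
            raise ConfigurationError("jitter CVs must be non-negative")
        if min(self.omega_noise_sd, self.keypoint_noise_sd) < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if not (0 < self.flexion_fraction < 1):
            raise ConfigurationError("flexion_fraction must lie in (0, 1)")


@dataclass
class _StrokePlan:
    """Half-cosine strokes covering (at least) the test duration."""

    t0: np.ndarray  # stroke start times
    dur: np.ndarray
    amp: np.ndarray  # θ excursion of the stroke, deg
    sign: np.ndarray  # +1 flexion (θ rising), −1 extension
    baseline: float


def _plan_strokes(params: SyntheticParams) -> _StrokePlan:
    rng = np.random.default_rng(params.seed)
    t0, dur, amp, sign = [], [], [], []
    t = 0.0
    while t < params.duration:
        period = params.cycle_period * max(
            MIN_JITTER_FACTOR, 1.0 + params.period_jitter_cv * rng.standard_normal()
        )
        mid = t + 0.5 * period
        ramp = 1.0 + 2.0 * params.decay * (0.5 - mid / params.duration)
        a = params.rom * max(MIN_JITTER_FACTOR, ramp) * max(
            MIN_JITTER_FACTOR, 1.0 + params.amplitude_jitter_cv * rng.standard_normal()
        )
        tf = period * params.flexion_fraction
        t0 += [t, t + tf]
        dur += [tf, period - tf]
        amp += [a, a]
        sign += [1.0, -1.0]
        t += period
    return _StrokePlan(
        t0=np.asarray(t0),
        dur=np.asarray(dur),
        amp=np.asarray(amp),
        sign=np.asarray(sign),
        baseline=params.baseline_angle,
    )


def _locate(plan: _StrokePlan, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    j = np.clip(np.searchsorted(plan.t0, t, side="right") - 1, 0, plan.t0.size - 1)
    frac = np.clip((t - plan.t0[j]) / plan.dur[j], 0.0, 1.0)
    return j, frac


def _theta_of(plan: _StrokePlan, t: np.ndarray) -> np.ndarray:
    j, frac = _locate(plan, t)
    rising = plan.sign[j] > 0
    phase = 0.5 * (1.0 - np.cos(np.pi * frac))  # 0 → 1 over the stroke
    return plan.baseline + plan.amp[j] * np.where(rising, phase, 1.0 - phase)


def _omega_of(plan: _StrokePlan, t: np.ndarray) -> np.ndarray:
    """Analytic derivative of the stroke train; peak of a stroke is π·amp/(2·dur)."""
    j, frac = _locate(plan, t)
    return plan.sign[j] * plan.amp[j] * np.pi / (2.0 * plan.dur[j]) * np.sin(np.pi * frac)


def generate_angle(params: SyntheticParams, rate: float = 100.0) -> AngleSeries:
    """Ground-truth forearm angle θ(t) on a uniform grid at ``rate`` Hz."""
    plan = _plan_strokes(params)
    t = np.arange(int(round(params.duration * rate)) + 1) / rate
    t = t[t <= params.duration + 1e-12]
    return AngleSeries(t=t, theta=_theta_of(plan, t))


def generate_omega(
    params: SyntheticParams, rate: float = 100.0
) -> tuple[AngularVelocitySeries, AngularVelocitySeries]:
    """(truth, noisy) angular velocity; truth is the analytic stroke derivative."""
    plan = _plan_strokes(params)
    t = np.arange(int(round(params.duration * rate)) + 1) / rate
    t = t[t <= params.duration + 1e-12]
    w = _omega_of(plan, t)
    truth = AngularVelocitySeries(t=t, omega=w, source="synthetic", rate=rate)
    noise_rng = np.random.default_rng([params.seed, 1])
    noisy_w = w + params.omega_noise_sd * noise_rng.standard_normal(w.size)
    noisy = AngularVelocitySeries(t=t, omega=noisy_w, source="synthetic", rate=rate)
    return truth, noisy


def generate_keypoints(params: SyntheticParams) -> KeypointTrack:
    """Render θ(t) as a wrist rotating about a fixed elbow anchor.

    Raster convention (y down): wrist = elbow + L·(cos θ, −sin θ), plus
    Gaussian pixel noise on each joint; confidences are drawn near 1.
    """
    plan = _plan_strokes(params)
    t = np.arange(int(round(params.duration * params.fps)) + 1) / params.fps
    t = t[t <= params.duration + 1e-12]
    theta = np.radians(_theta_of(plan, t))
    rng = np.random.default_rng([params.seed, 2])
    ex, ey = params.elbow_anchor
    n = t.size

    def noisy(x, y):
        pts = np.column_stack((x, y))
        pts += params.keypoint_noise_sd * rng.standard_normal(pts.shape)
        conf = np.clip(rng.normal(0.97, 0.01, n), 0.0, 1.0)
        return np.column_stack((pts, conf))

    joints = {
        "wrist": noisy(
            ex + params.forearm_length * np.cos(theta),
            ey - params.forearm_length * np.sin(theta),
        ),
        "elbow": noisy(np.full(n, ex), np.full(n, ey)),
    }
    if params.include_shoulder:
        joints["shoulder"] = noisy(np.full(n, ex), np.full(n, ey - params.upper_arm_length))
    return KeypointTrack(t=t, joints=joints, frame_rate=params.fps, subject_side="unknown")


def generate_gyro(params: SyntheticParams) -> GyroRecording:
    """Render ω(t) along a known 3-D axis as a tri-axial gyro recording."""
    plan = _plan_strokes(params)
    t = np.arange(int(round(params.duration * params.gyro_rate)) + 1) / params.gyro_rate
    t = t[t <= params.duration + 1e-12]
    w = _omega_of(plan, t)
    axis = Rotation.from_euler("xyz", params.gyro_rotation, degrees=True).apply([1.0, 0.0, 0.0])
    rng = np.random.default_rng([params.seed, 3])
    channels = np.outer(w, axis) + params.omega_noise_sd * rng.standard_normal((t.size, 3))
    return GyroRecording(t=t, channels=channels, nominal_rate=params.gyro_rate)


def ground_truth_features(params: SyntheticParams, rate: float = 100.0):
    """Features and frailty index of the *noiseless* ground-truth signal.

    Runs the clean analytic ω through the standard segmentation and feature
    extraction; used as the recovery side-car for end-to-end tests.
    """
    from .cycles import segment
    from .features import extract_features
    from .frailty import compute_frailty_index, features_to_inputs

    truth, _ = generate_omega(params, rate=rate)
    cycles = segment(truth)
    feats = extract_features(truth, cycles)
    inputs = features_to_inputs(feats)
    return feats, inputs, compute_frailty_index(inputs)


def write_dataset(params: SyntheticParams, out_dir: str | Path) -> dict[str, Path]:
    """Write one synthetic subject to disk: keypoints (CSV + JSON), gyro CSV
    and a ground-truth side-car JSON with the programmed parameters, the
    noiseless feature values and the noiseless frailty index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "keypoints_csv": out_dir / "keypoints.csv",
        "keypoints_json": out_dir / "keypoints.json",
        "gyro_csv": out_dir / "gyro.csv",
        "truth_json": out_dir / "truth.json",
    }
    write_keypoints(generate_keypoints(params), paths["keypoints_csv"], format="csv")
    write_keypoints(generate_keypoints(params), paths["keypoints_json"], format="json")
    write_gyro(generate_gyro(params), paths["gyro_csv"])
    feats, inputs, result = ground_truth_features(params)
    doc = {
        "params": asdict(params),
        "features": feats.to_dict(),
        "frailty": result.to_json_dict(inputs),
    }
    paths["truth_json"].write_text(json.dumps(doc, indent=1, sort_keys=True))
    return paths


class MockPoseBackend(PoseBackend):
    """Scripted pose backend: replays a synthetic trajectory frame by frame.

    ``estimate`` ignores the pixel content of the image it is handed and
    returns the next frame of the scripted track, so a pipeline driven by
    this backend is exactly equivalent to reading the corresponding keypoint
    file.  An optional ``confidence_schedule`` (one value per frame) overrides
    the drawn wrist/elbow confidences.
    """

    def __init__(
        self,
        params: SyntheticParams | None = None,
        confidence_schedule: Sequence[float] | None = None,
    ):
        self.params = params or SyntheticParams()
        self._track = generate_keypoints(self.params)
        if confidence_schedule is not None:
            sched = np.asarray(confidence_schedule, dtype=float)
            if sched.size != self._track.n_frames:
                raise ConfigurationError(
                    f"confidence schedule has {sched.size} entries for "
                    f"{self._track.n_frames} frames"
                )
            for name in ("wrist", "elbow"):
                self._track.joints[name][:, 2] = sched
        self._cursor = 0

    @property
    def n_frames(self) -> int:
        return self._track.n_frames

    def estimate(self, frame_image) -> dict[str, tuple[float, float, float]]:
        if self._cursor >= self._track.n_frames:
            raise ConfigurationError("mock backend exhausted its scripted trajectory")
        k = self._cursor
        self._cursor += 1
        return {
            name: tuple(arr[k]) for name, arr in self._track.joints.items()
        }

    def track(self) -> KeypointTrack:
        """The full scripted track (identical to ``generate_keypoints(params)``)."""
        return self._track
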