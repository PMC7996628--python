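"""End-to-end composition: recording → ω → half-cycles → 20 features → index.

Both input paths funnel into the same feature extractor:

* video: keypoints → forearm angle → smoothed derivative (flexion-positive ω);
* sensor: tri-axial gyro → principal-axis projection → shared low-pass.

Each stage failure is re-raised with the stage name prefixed so callers (and
the CLI) can report where a recording fell over.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

from . import cycles as cyc
from . import features as feat
from . import frailty as fr
from . import io
from . import kinematics as kin
from .config import RunConfig
from .errors import FrailtyKitError


@contextmanager
def _stage(name: str):
    try:
        yield
    except FrailtyKitError as exc:
        raise type(exc)(f"[{name}] {exc}") from None


@dataclass
class PipelineResult:
    features: feat.PhenotypeFeatureSet
    inputs: fr.FrailtyInputs
    frailty: fr.FrailtyResult
    cycles: cyc.CycleSet
    omega: kin.AngularVelocitySeries
    angle: kin.AngleSeries | None = None


def _finish(omega, config: RunConfig, angle=None) -> PipelineResult:
    with _stage("segment"):
        omega = omega.crop(config.test_duration)
        cycles = cyc.segment(
            omega,
            min_peak=config.min_peak,
            min_duration=config.min_duration,
            hysteresis=config.hysteresis,
        )
    with _stage("features"):
        features = feat.extract_features(
            omega, cycles, split=config.window_split, angle=angle
        )
    with _stage("frailty"):
        inputs = fr.features_to_inputs(features)
        result = fr.compute_frailty_index(inputs)
    return PipelineResult(features, inputs, result, cycles, omega, angle)


def analyze_keypoint_track(track: io.KeypointTrack, config: RunConfig | None = None) -> PipelineResult:
    """Video path: keypoint track → features and frailty index."""
    config = config or RunConfig()
    with _stage("kinematics"):
        angle = kin.forearm_angle(track, shoulder_confidence_threshold=config.confidence_threshold)
        omega = kin.differentiate_and_smooth(angle, cutoff=config.smoothing_cutoff)
    return _finish(omega, config, angle=angle)


def analyze_gyro(rec: io.GyroRecording, config: RunConfig | None = None) -> PipelineResult:
    """Sensor path: gyro recording → features and frailty index."""
    config = config or RunConfig()
    with _stage("kinematics"):
        omega = kin.gyro_to_omega(rec, target_rate=config.gyro_rate)
        smoothed = kin.lowpass(omega.omega, omega.rate, config.smoothing_cutoff)
        omega = kin.AngularVelocitySeries(
            t=omega.t, omega=kin.normalize_sign(smoothed), source="sensor", rate=omega.rate
        )
    return _finish(omega, config)


def run_video(path: str | Path, config: RunConfig | None = None, format: str | None = None) -> PipelineResult:
    """Read a keypoint file and run the video path."""
    config = config or RunConfig()
    with _stage("read"):
        track = io.read_keypoints(
            path,
            format=format,
            confidence_threshold=config.confidence_threshold,
            max_gap_frames=config.max_gap_frames,
        )
    return analyze_keypoint_track(track, config)


def run_sensor(path: str | Path, config: RunConfig | None = None) -> PipelineResult:
    """Read a gyro CSV and run the sensor path."""
    config = config or RunConfig()
    with _stage("read"):
        rec = io.read_gyro(path, nominal_rate=config.gyro_rate)
    return analyze_gyro(rec, config)
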