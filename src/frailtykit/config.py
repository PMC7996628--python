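"""Run configuration: the protocol constants and algorithm thresholds.

Serialisable to a plain-text YAML mapping (``key: value``) so a comparison
study can pin one configuration and reproduce every run from it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    test_duration: float = 20.0  # s; recordings are cropped to this
    window_split: float = 10.0  # s; first/last window boundary for exhaustion
    smoothing_cutoff: float = 6.0  # Hz, zero-phase low-pass on both paths
    min_peak: float = 10.0  # deg/s, half-cycle acceptance threshold
    min_duration: float = 0.1  # s, half-cycle acceptance threshold
    hysteresis: float = 2.0  # deg/s, zero-crossing hysteresis band
    confidence_threshold: float = 0.1  # keypoint confidence below this = missing
    max_gap_frames: int = 5  # longest interpolatable keypoint gap
    gyro_rate: float = 100.0  # Hz, uniform grid for the sensor path
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from None
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config {path} must be a key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        return cls(**doc)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def replace(self, **overrides) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def hash(self) -> str:
        """Short digest of the full configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
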