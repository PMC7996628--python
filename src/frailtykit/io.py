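"""Readers and writers for keypoint tracks, gyroscope recordings and feature
tables, plus the pluggable pose-backend registry.

Coordinate convention: image coordinates are standard raster coordinates —
origin at the top-left corner, x to the right, y *downward*.  The kinematics
module converts to mathematical angles internally.

Keypoint CSV dialect::

    time,wrist_x,wrist_y,wrist_c,elbow_x,elbow_y,elbow_c[,shoulder_x,shoulder_y,shoulder_c]

Keypoint JSON dialect: an object with ``frame_rate`` (Hz), optional
``subject_side`` (``left``/``right``/``unknown``), a joint-index map (either a
named ``layout`` — ``body25`` or ``coco18`` — or an explicit ``joint_index``
object mapping joint name to triplet index), and ``frames``: a list of
``{"time": s, "keypoints": [x0, y0, c0, x1, y1, c1, ...]}`` records, one
(x, y, confidence) triplet per joint of the layout.

Gyro CSV dialect: ``time,gx,gy,gz`` with angular rates in deg/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, QualityError, ValidationError

#: triplet index of each joint in the common 2-D pose layouts, per body side.
#: Both the 25-joint and the 18-joint body layouts place the right arm at
#: indices 2-4 and the left arm at 5-7.
JOINT_INDEX_TABLES: dict[str, dict[str, dict[str, int]]] = {
    "body25": {
        "right": {"shoulder": 2, "elbow": 3, "wrist": 4},
        "left": {"shoulder": 5, "elbow": 6, "wrist": 7},
    },
    "coco18": {
        "right": {"shoulder": 2, "elbow": 3, "wrist": 4},
        "left": {"shoulder": 5, "elbow": 6, "wrist": 7},
    },
}

DEFAULT_CONFIDENCE_THRESHOLD = 0.1
DEFAULT_MAX_GAP_FRAMES = 5
MAX_MISSING_FRACTION = 0.2


@dataclass
class KeypointTrack:
    """Timestamped 2-D joint positions with confidences from a video.

    ``joints`` maps a joint name (``wrist``, ``elbow``, optionally
    ``shoulder``) to an ``(n, 3)`` array of ``x`` (px), ``y`` (px, downward)
    and confidence in ``[0, 1]``; confidence 0 marks a missing observation.
    """

    t: np.ndarray
    joints: dict[str, np.ndarray]
    frame_rate: float
    subject_side: str = "unknown"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.joints = {k: np.asarray(v, dtype=float) for k, v in self.joints.items()}
        self.validate()

    def validate(self) -> None:
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValidationError("keypoint track needs at least 2 frames")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("keypoint timestamps must be strictly increasing")
        for name in ("wrist", "elbow"):
            if name not in self.joints:
                raise ValidationError(f"keypoint track missing required joint {name!r}")
        for name, arr in self.joints.items():
            if arr.shape != (self.t.size, 3):
                raise ValidationError(
                    f"joint {name!r} has shape {arr.shape}, expected ({self.t.size}, 3)"
                )
            c = arr[:, 2]
            if np.any(~np.isfinite(c)) or c.min() < 0 or c.max() > 1:
                raise ValidationError(f"joint {name!r} confidences must lie in [0, 1]")
        if self.subject_side not in ("left", "right", "unknown"):
            raise ValidationError(f"unknown subject_side {self.subject_side!r}")

    @property
    def n_frames(self) -> int:
        return int(self.t.size)


@dataclass
class GyroRecording:
    """Tri-axial wrist gyroscope recording; channels in deg/s."""

    t: np.ndarray
    channels: np.ndarray  # (n, 3)
    nominal_rate: float = 100.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValidationError("gyro recording needs at least 2 samples")
        if self.channels.shape != (self.t.size, 3):
            raise ValidationError(
                f"gyro channels have shape {self.channels.shape}, expected ({self.t.size}, 3)"
            )
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("gyro timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.channels)):
            raise ValidationError("gyro channels contain non-finite values")


# ---------------------------------------------------------------------------
# keypoint reading


def _interpolate_missing(
    t: np.ndarray,
    arr: np.ndarray,
    threshold: float,
    max_gap: int,
    joint: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short internal runs of low-confidence frames by linear interpolation.

    Returns the filled ``(n, 3)`` array and the boolean mask of frames that
    remain unusable (edge gaps).  Interpolated frames get confidence equal to
    the threshold, marking them as filled rather than observed.  Interpolation
    only ever fills positions at existing timestamps.
    """
    arr = arr.copy()
    missing = arr[:, 2] < threshold
    if missing.mean() > MAX_MISSING_FRACTION:
        raise QualityError(
            f"{missing.mean():.0%} of {joint} frames below confidence "
            f"{threshold}; more than {MAX_MISSING_FRACTION:.0%} missing"
        )
    if not missing.any():
        return arr, missing
    valid = ~missing
    idx = np.flatnonzero(missing)
    # split missing indices into contiguous runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    still_missing = np.zeros(arr.shape[0], dtype=bool)
    for run in runs:
        internal = run[0] > 0 and run[-1] < arr.shape[0] - 1
        if internal and len(run) > max_gap:
            raise QualityError(
                f"{joint}: internal gap of {len(run)} low-confidence frames "
                f"starting at frame {run[0]} exceeds the maximum of {max_gap}"
            )
        if internal:
            for col in (0, 1):
                arr[run, col] = np.interp(t[run], t[valid], arr[valid, col])
            arr[run, 2] = threshold
        else:
            still_missing[run] = True
    return arr, still_missing


def _finalize_track(
    t: np.ndarray,
    joints: dict[str, np.ndarray],
    frame_rate: float,
    subject_side: str,
    confidence_threshold: float,
    max_gap_frames: int,
) -> KeypointTrack:
    edge_missing = np.zeros(t.size, dtype=bool)
    for name in ("wrist", "elbow"):
        joints[name], miss = _interpolate_missing(
            t, joints[name], confidence_threshold, max_gap_frames, name
        )
        edge_missing |= miss
    if edge_missing.any():
        # edge gaps cannot be interpolated; trim those frames from both ends
        keep = ~edge_missing
        first, last = np.flatnonzero(keep)[[0, -1]]
        t = t[first : last + 1]
        joints = {k: v[first : last + 1] for k, v in joints.items()}
    return KeypointTrack(t=t, joints=joints, frame_rate=frame_rate, subject_side=subject_side)


def read_keypoints(
    path: str | Path,
    format: str | None = None,
    *,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    frame_rate: float | None = None,
) -> KeypointTrack:
    """Read a keypoint track from CSV or JSON (see module docstring for dialects).

    Frames whose wrist/elbow confidence falls below ``confidence_threshold``
    are treated as missing; internal gaps up to ``max_gap_frames`` are linearly
    interpolated, longer gaps raise :class:`QualityError`.  ``frame_rate``
    overrides the value inferred from timestamps (CSV) or stated in the file
    (JSON).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        t, joints, side = _read_keypoints_csv(path)
    elif fmt == "json":
        t, joints, side, stated_rate = _read_keypoints_json(path)
        if frame_rate is None:
            frame_rate = stated_rate
    else:
        raise ConfigurationError(f"unknown keypoint format {fmt!r}")
    if not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValidationError(f"{path.name}: timestamps not strictly increasing at record {bad}")
    if frame_rate is None:
        frame_rate = float((t.size - 1) / (t[-1] - t[0]))
    return _finalize_track(t, joints, frame_rate, side, confidence_threshold, max_gap_frames)


_CSV_REQUIRED = ["time", "wrist_x", "wrist_y", "wrist_c", "elbow_x", "elbow_y", "elbow_c"]
_CSV_SHOULDER = ["shoulder_x", "shoulder_y", "shoulder_c"]


def _read_keypoints_csv(path: Path):
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises a zoo of parser errors
        raise ParseError(f"{path.name}: {exc}") from None
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: header missing columns {missing}")
    if len(df) == 0:
        raise ParseError(f"{path.name}: no data rows")
    cols = list(df.columns)
    for c in cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path.name}: non-numeric value in column {c!r} at line {row}")
    t = df["time"].to_numpy(float)
    joints = {
        "wrist": df[["wrist_x", "wrist_y", "wrist_c"]].to_numpy(float),
        "elbow": df[["elbow_x", "elbow_y", "elbow_c"]].to_numpy(float),
    }
    if all(c in df.columns for c in _CSV_SHOULDER):
        joints["shoulder"] = df[_CSV_SHOULDER].to_numpy(float)
    return t, joints, "unknown"


def _read_keypoints_json(path: Path):
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path.name}: invalid JSON ({exc})") from None
    if not isinstance(doc, dict) or "frames" not in doc:
        raise ParseError(f"{path.name}: expected an object with a 'frames' list")
    frames = doc["frames"]
    if not frames:
        raise ParseError(f"{path.name}: empty 'frames' list")
    side = doc.get("subject_side", "unknown")
    if "joint_index" in doc:
        index_map = {str(k): int(v) for k, v in doc["joint_index"].items()}
    else:
        layout = doc.get("layout")
        if layout not in JOINT_INDEX_TABLES:
            raise ParseError(
                f"{path.name}: need either 'joint_index' or a known 'layout' "
                f"(one of {sorted(JOINT_INDEX_TABLES)})"
            )
        table = JOINT_INDEX_TABLES[layout]
        if side in ("left", "right"):
            index_map = table[side]
        else:
            # side unknown: pick the side whose wrist is more confidently seen
            best, best_conf = "right", -1.0
            for cand in ("right", "left"):
                wi = table[cand]["wrist"]
                confs = [
                    f["keypoints"][3 * wi + 2]
                    for f in frames
                    if len(f.get("keypoints", [])) > 3 * wi + 2
                ]
                mc = float(np.mean(confs)) if confs else -1.0
                if mc > best_conf:
                    best, best_conf = cand, mc
            side, index_map = best, table[best]
    t = np.empty(len(frames))
    joints = {name: np.empty((len(frames), 3)) for name in index_map}
    for i, f in enumerate(frames):
        if "time" not in f or "keypoints" not in f:
            raise ParseError(f"{path.name}: frame record {i} lacks 'time'/'keypoints'")
        t[i] = float(f["time"])
        kp = f["keypoints"]
        for name, j in index_map.items():
            if len(kp) < 3 * j + 3:
                raise ParseError(
                    f"{path.name}: frame record {i} has {len(kp)} values, "
                    f"too few for joint {name!r} at index {j}"
                )
            joints[name][i] = kp[3 * j : 3 * j + 3]
    # a joint that is entirely absent (all-zero confidence) is simply dropped
    joints = {
        k: v for k, v in joints.items() if k in ("wrist", "elbow") or np.any(v[:, 2] > 0)
    }
    for req in ("wrist", "elbow"):
        if req not in joints:
            raise ParseError(f"{path.name}: joint-index map lacks required joint {req!r}")
    return t, joints, side, doc.get("frame_rate")


def write_keypoints(track: KeypointTrack, path: str | Path, format: str | None = None) -> None:
    """Write a keypoint track as CSV or JSON; the round trip is lossless."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    names = ["wrist", "elbow"] + (["shoulder"] if "shoulder" in track.joints else [])
    if fmt == "csv":
        data = {"time": track.t}
        for name in names:
            for k, suffix in enumerate(("x", "y", "c")):
                data[f"{name}_{suffix}"] = track.joints[name][:, k]
        pd.DataFrame(data).to_csv(path, index=False)
    elif fmt == "json":
        doc = {
            "frame_rate": track.frame_rate,
            "subject_side": track.subject_side,
            "joint_index": {name: i for i, name in enumerate(names)},
            "frames": [
                {
                    "time": float(track.t[i]),
                    "keypoints": [
                        float(v) for name in names for v in track.joints[name][i]
                    ],
                }
                for i in range(track.n_frames)
            ],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    else:
        raise ConfigurationError(f"unknown keypoint format {fmt!r}")


# ---------------------------------------------------------------------------
# gyro reading


def read_gyro(path: str | Path, nominal_rate: float = 100.0) -> GyroRecording:
    """Read a tri-axial gyro CSV (``time,gx,gy,gz``; deg/s)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path.name}: {exc}") from None
    required = ["time", "gx", "gy", "gz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: header missing columns {missing}")
    if len(df) < 2:
        raise ParseError(f"{path.name}: fewer than 2 data rows")
    for c in required:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path.name}: non-numeric value in column {c!r} at line {row}")
    t = df["time"].to_numpy(float)
    if not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise ValidationError(f"{path.name}: timestamps not strictly increasing at line {bad}")
    return GyroRecording(t=t, channels=df[["gx", "gy", "gz"]].to_numpy(float), nominal_rate=nominal_rate)


def write_gyro(rec: GyroRecording, path: str | Path) -> None:
    pd.DataFrame(
        {"time": rec.t, "gx": rec.channels[:, 0], "gy": rec.channels[:, 1], "gz": rec.channels[:, 2]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(
    rows: Mapping[str, Mapping[str, float | None]],
    path: str | Path,
    units: Mapping[str, str] | None = None,
) -> None:
    """Write a feature table: one row per recording, one column per feature.

    ``rows`` maps a record id to a feature-name → value mapping (``None`` for
    unavailable features, written as empty cells).  CSV columns carry the unit
    as a bracketed suffix (``speed [deg/s]``); a ``.json`` path writes the
    JSON mirror instead (plain feature names, units in a side field).
    """
    path = Path(path)
    units = dict(units or {})
    df = pd.DataFrame.from_dict({k: dict(v) for k, v in rows.items()}, orient="index")
    df.index.name = "record_id"
    if path.suffix.lower() == ".json":
        doc = {
            "units": {c: units.get(c, "") for c in df.columns},
            "records": {
                rid: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
                for rid, row in df.iterrows()
            },
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    else:
        out = df.rename(columns={c: f"{c} [{units[c]}]" if units.get(c) else c for c in df.columns})
        out.to_csv(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`.

    Returns a DataFrame indexed by record id with plain (unit-stripped)
    feature names as columns.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: invalid JSON ({exc})") from None
        if "records" not in doc:
            raise ParseError(f"{path.name}: missing 'records'")
        df = pd.DataFrame.from_dict(doc["records"], orient="index")
    else:
        try:
            df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        except Exception as exc:
            raise ParseError(f"{path.name}: {exc}") from None
        df.columns = [c.split(" [")[0] for c in df.columns]
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# pose-backend registry


class PoseBackend:
    """Contract for per-frame 2-D pose estimation.

    ``estimate`` takes a 2-D image array and returns a mapping from joint name
    to an ``(x, y, confidence)`` triple.  Backends are registered by name so a
    real estimator can be plugged in without touching the pipeline.
    """

    def estimate(self, frame_image) -> dict[str, tuple[float, float, float]]:
        raise NotImplementedError


_BACKENDS: dict[str, Callable[..., PoseBackend]] = {}


def register_backend(name: str, factory: Callable[..., PoseBackend]) -> None:
    _BACKENDS[name] = factory


def get_backend(name: str, **kwargs) -> PoseBackend:
    if name not in _BACKENDS:
        raise ConfigurationError(
            f"unknown pose backend {name!r}; registered: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[name](**kwargs)


def _mock_backend_factory(**kwargs) -> PoseBackend:
    from .synthetic import MockPoseBackend  # deferred: synthetic imports this module

    return MockPoseBackend(**kwargs)


register_backend("mock", _mock_backend_factory)
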