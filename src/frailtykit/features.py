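"""The 20 kinematic frailty-phenotype features ("digital biomarkers").

Phenotype groups and their features, with internal units (seconds, deg/s):

* slowness — ``speed`` (mean per-cycle ω range, deg/s), ``rise_time``,
  ``fall_time``, ``extension_time``, ``flexion_time``, ``cycle_time`` (s) and
  ``n_repetitions`` (full flexion–extension cycles per test);
* weakness — ``power`` (mean per-cycle product of the ω range and the angular-
  acceleration range, deg²/s³);
* rigidity — ``range_of_motion`` (mean per-half-cycle integrated angle, deg);
* exhaustion — ``delta_speed``, ``delta_power``, ``delta_cycle_time``,
  ``delta_rise_time`` (% change between the first and last half of the test,
  relative to the whole-test mean; negative = decline);
* unsteadiness — ``cv_speed``, ``cv_rise_time``, ``cv_flexion_time``,
  ``cv_extension_time``, ``cv_cycle_time``, ``cv_power``, ``cv_rigidity``
  (cycle-to-cycle coefficients of variation, %).

Features that cannot be computed (e.g. no movement cycles, a 10-s window with
no cycles) are *flagged unavailable with a reason* — never silently zeroed,
because zero is a meaningful value for most of these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cycles import FLEXION, CycleSet
from .errors import FeatureUnavailable
from .kinematics import AngleSeries, AngularVelocitySeries, CONVENTION_INTERIOR, half_cycle_rom

FEATURE_UNITS: dict[str, str] = {
    "speed": "deg/s",
    "rise_time": "s",
    "fall_time": "s",
    "extension_time": "s",
    "flexion_time": "s",
    "cycle_time": "s",
    "n_repetitions": "count",
    "power": "deg^2/s^3",
    "range_of_motion": "deg",
    "delta_speed": "%",
    "delta_power": "%",
    "delta_cycle_time": "%",
    "delta_rise_time": "%",
    "cv_speed": "%",
    "cv_rise_time": "%",
    "cv_flexion_time": "%",
    "cv_extension_time": "%",
    "cv_cycle_time": "%",
    "cv_power": "%",
    "cv_rigidity": "%",
}

FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_UNITS)
assert len(FEATURE_NAMES) == 20

PHENOTYPE_GROUPS: dict[str, tuple[str, ...]] = {
    "slowness": (
        "speed",
        "rise_time",
        "fall_time",
        "extension_time",
        "flexion_time",
        "cycle_time",
        "n_repetitions",
    ),
    "weakness": ("power",),
    "rigidity": ("range_of_motion",),
    "exhaustion": ("delta_speed", "delta_power", "delta_cycle_time", "delta_rise_time"),
    "unsteadiness": (
        "cv_speed",
        "cv_rise_time",
        "cv_flexion_time",
        "cv_extension_time",
        "cv_cycle_time",
        "cv_power",
        "cv_rigidity",
    ),
}


@dataclass
class PhenotypeFeatureSet:
    """The 20 digital biomarkers; ``None`` fields are listed in ``unavailable``."""

    speed: Optional[float] = None
    rise_time: Optional[float] = None
    fall_time: Optional[float] = None
    extension_time: Optional[float] = None
    flexion_time: Optional[float] = None
    cycle_time: Optional[float] = None
    n_repetitions: Optional[float] = None
    power: Optional[float] = None
    range_of_motion: Optional[float] = None
    delta_speed: Optional[float] = None
    delta_power: Optional[float] = None
    delta_cycle_time: Optional[float] = None
    delta_rise_time: Optional[float] = None
    cv_speed: Optional[float] = None
    cv_rise_time: Optional[float] = None
    cv_flexion_time: Optional[float] = None
    cv_extension_time: Optional[float] = None
    cv_cycle_time: Optional[float] = None
    cv_power: Optional[float] = None
    cv_rigidity: Optional[float] = None
    unavailable: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def require(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            reason = self.unavailable.get(name, "not computed")
            raise FeatureUnavailable(f"feature {name!r} unavailable: {reason}")
        return float(value)

    @classmethod
    def all_unavailable(cls, reason: str) -> "PhenotypeFeatureSet":
        return cls(unavailable={name: reason for name in FEATURE_NAMES})


@dataclass
class PerCycleValues:
    """Per-cycle primitives the aggregate features are built from.

    Full-cycle arrays are aligned with ``CycleSet.full_cycles()``; half-cycle
    arrays with ``CycleSet.half_cycles``.
    """

    cycle_midpoint: np.ndarray  # s, midpoint of each full cycle
    speed: np.ndarray  # deg/s, ω range per full cycle
    power: np.ndarray  # deg²/s³ per full cycle
    cycle_time: np.ndarray  # s per full cycle
    half_kind: list[str]
    half_midpoint: np.ndarray
    half_duration: np.ndarray
    half_rise: np.ndarray
    half_fall: np.ndarray
    half_rom: np.ndarray  # deg, |∫ω dt| per half-cycle

    @property
    def n_full_cycles(self) -> int:
        return int(self.speed.size)


_UPSAMPLE_RATE = 200.0  # Hz; common evaluation grid for per-cycle extrema


def _upsample(ts: np.ndarray, seg: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    if rate >= _UPSAMPLE_RATE or seg.size < 4:
        return ts, seg
    from scipy.interpolate import CubicSpline

    fine = np.linspace(ts[0], ts[-1], int(np.ceil((ts[-1] - ts[0]) * _UPSAMPLE_RATE)) + 1)
    return fine, CubicSpline(ts, seg)(fine)


def per_cycle_primitives(
    omega: AngularVelocitySeries, cycles: CycleSet, angle: AngleSeries | None = None
) -> PerCycleValues:
    """Compute the per-(half-)cycle primitive values.

    Angular acceleration is the finite difference of the (already smoothed) ω
    within each cycle — no second smoothing pass, which would bias amplitudes.
    When ``angle`` uses the elbow-interior convention, the per-half-cycle
    range of motion is read directly off θ instead of integrating ω.
    """
    t, w = omega.t, omega.omega
    dt = 1.0 / omega.rate
    mids, speeds, powers, durations = [], [], [], []
    for flex, ext in cycles.full_cycles():
        mask = (t >= flex.t_start - dt / 2) & (t <= ext.t_end + dt / 2)
        ts, seg = t[mask], w[mask]
        if seg.size < 3:
            continue
        # evaluate extrema and the derivative on a spline-upsampled copy so
        # the result does not depend on the recording rate (30 fps video vs
        # 100 Hz gyro must measure the same waveform)
        ts_f, seg_f = _upsample(ts, seg, omega.rate)
        speed = float(seg_f.max() - seg_f.min())
        accel = np.gradient(seg_f, ts_f)
        powers.append(speed * float(accel.max() - accel.min()))
        speeds.append(speed)
        durations.append(ext.t_end - flex.t_start)
        mids.append(0.5 * (flex.t_start + ext.t_end))
    use_theta_range = angle is not None and angle.convention == CONVENTION_INTERIOR
    half_rom = []
    for h in cycles:
        if use_theta_range:
            m = (angle.t >= h.t_start) & (angle.t <= h.t_end)
            half_rom.append(float(angle.theta[m].max() - angle.theta[m].min()) if m.any() else 0.0)
        else:
            half_rom.append(half_cycle_rom(omega, h.t_start, h.t_end))
    return PerCycleValues(
        cycle_midpoint=np.asarray(mids),
        speed=np.asarray(speeds),
        power=np.asarray(powers),
        cycle_time=np.asarray(durations),
        half_kind=[h.kind for h in cycles],
        half_midpoint=np.asarray([h.midpoint for h in cycles]),
        half_duration=np.asarray([h.duration for h in cycles]),
        half_rise=np.asarray([h.rise for h in cycles]),
        half_fall=np.asarray([h.fall for h in cycles]),
        half_rom=np.asarray(half_rom),
    )


def exhaustion_delta(values: np.ndarray, midpoints: np.ndarray, split: float) -> float:
    """Percent change between the first and last test windows.

    ``100 · (mean(last window) − mean(first window)) / mean(all)``, with each
    value assigned to a window by its cycle midpoint (half-open at ``split``).
    Negative = decline over the test.
    """
    values = np.asarray(values, dtype=float)
    midpoints = np.asarray(midpoints, dtype=float)
    first = values[midpoints < split]
    last = values[midpoints >= split]
    if first.size == 0 or last.size == 0:
        raise FeatureUnavailable("a test window contains no cycles")
    overall = float(values.mean())
    if overall == 0.0:
        raise FeatureUnavailable("whole-test mean is zero; percent change undefined")
    return float(100.0 * (last.mean() - first.mean()) / overall)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample CV in percent: ``100 · sd(n−1) / mean``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise FeatureUnavailable("need at least 2 cycles for a coefficient of variation")
    mean = float(values.mean())
    if mean == 0.0:
        raise FeatureUnavailable("mean is zero; coefficient of variation undefined")
    return float(100.0 * values.std(ddof=1) / mean)


def extract_features(
    omega: AngularVelocitySeries,
    cycles: CycleSet,
    split: float | None = None,
    angle: AngleSeries | None = None,
) -> PhenotypeFeatureSet:
    """Aggregate the per-cycle primitives into the 20-feature set.

    ``split`` is the first/last window boundary for the exhaustion deltas;
    it defaults to the temporal midpoint of the series (10 s for the standard
    20-s test).
    """
    if len(cycles) == 0:
        return PhenotypeFeatureSet.all_unavailable("no movement cycles detected")
    if split is None:
        split = 0.5 * float(omega.t[0] + omega.t[-1])
    v = per_cycle_primitives(omega, cycles, angle=angle)
    flex = np.asarray([k == FLEXION for k in v.half_kind])

    out = PhenotypeFeatureSet()

    def put(name: str, fn):
        try:
            setattr(out, name, float(fn()))
        except FeatureUnavailable as exc:
            out.unavailable[name] = exc.reason

    def mean_of(arr: np.ndarray):
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            raise FeatureUnavailable("no cycles of the required kind")
        return arr.mean()

    put("speed", lambda: mean_of(v.speed))
    put("rise_time", lambda: mean_of(v.half_rise[flex]))
    put("fall_time", lambda: mean_of(v.half_fall[flex]))
    put("extension_time", lambda: mean_of(v.half_duration[~flex]))
    put("flexion_time", lambda: mean_of(v.half_duration[flex]))
    put("cycle_time", lambda: mean_of(v.cycle_time))
    out.n_repetitions = float(cycles.n_full_cycles)
    put("power", lambda: mean_of(v.power))
    put("range_of_motion", lambda: mean_of(v.half_rom))

    put("delta_speed", lambda: exhaustion_delta(v.speed, v.cycle_midpoint, split))
    put("delta_power", lambda: exhaustion_delta(v.power, v.cycle_midpoint, split))
    put("delta_cycle_time", lambda: exhaustion_delta(v.cycle_time, v.cycle_midpoint, split))
    put(
        "delta_rise_time",
        lambda: exhaustion_delta(v.half_rise[flex], v.half_midpoint[flex], split),
    )

    put("cv_speed", lambda: coefficient_of_variation(v.speed))
    put("cv_rise_time", lambda: coefficient_of_variation(v.half_rise[flex]))
    put("cv_flexion_time", lambda: coefficient_of_variation(v.half_duration[flex]))
    put("cv_extension_time", lambda: coefficient_of_variation(v.half_duration[~flex]))
    put("cv_cycle_time", lambda: coefficient_of_variation(v.cycle_time))
    put("cv_power", lambda: coefficient_of_variation(v.power))
    put("cv_rigidity", lambda: coefficient_of_variation(v.half_rom))
    return out
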