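"""Zero-crossing / peak-detection segmentation of the angular-velocity signal
into alternating flexion and extension half-cycles.

A hysteresis band around zero (default ±2 deg/s) suppresses sign chatter from
residual noise; run boundaries are then refined to the interpolated zero
crossing, so on clean signals the result matches a plain sign-run scan to
within one sample.  Runs whose peak or duration falls below threshold are
absorbed into their neighbours (they are fragments of one half-cycle split by
a noise blip) or dropped when isolated.  Partial half-cycles touching the
recording edges are kept as long as they contain an interior peak and meet
the thresholds — the test starts and ends mid-movement, and dropping them
would bias the repetition count low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import AngularVelocitySeries

FLEXION = "flexion"
EXTENSION = "extension"

DEFAULT_MIN_PEAK = 10.0  # deg/s
DEFAULT_MIN_DURATION = 0.1  # s
DEFAULT_HYSTERESIS = 2.0  # deg/s


@dataclass
class HalfCycle:
    """One sign-consistent excursion of ω: flexion (ω>0) or extension (ω<0)."""

    kind: str
    t_start: float
    t_peak: float
    t_end: float
    peak_omega: float

    def __post_init__(self):
        assert self.t_start < self.t_peak < self.t_end, "peak must be interior"
        assert (self.kind == FLEXION) == (self.peak_omega > 0)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def rise(self) -> float:
        """Onset → peak (the acceleration phase)."""
        return self.t_peak - self.t_start

    @property
    def fall(self) -> float:
        """Peak → offset (the deceleration phase)."""
        return self.t_end - self.t_peak

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class CycleSet:
    """Time-ordered, strictly alternating half-cycles."""

    half_cycles: list[HalfCycle] = field(default_factory=list)

    def __post_init__(self):
        for a, b in zip(self.half_cycles, self.half_cycles[1:]):
            assert b.t_start >= a.t_end - 1e-9, "half-cycles overlap"
            assert b.kind != a.kind, "half-cycle kinds must alternate"

    def __len__(self) -> int:
        return len(self.half_cycles)

    def __iter__(self):
        return iter(self.half_cycles)

    @property
    def n_half_cycles(self) -> int:
        return len(self.half_cycles)

    @property
    def n_flexions(self) -> int:
        return sum(1 for h in self.half_cycles if h.kind == FLEXION)

    @property
    def n_extensions(self) -> int:
        return sum(1 for h in self.half_cycles if h.kind == EXTENSION)

    @property
    def n_full_cycles(self) -> int:
        """Number of flexion half-cycles immediately followed by an extension."""
        return sum(
            1
            for a, b in zip(self.half_cycles, self.half_cycles[1:])
            if a.kind == FLEXION and b.kind == EXTENSION
        )

    def full_cycles(self) -> list[tuple[HalfCycle, HalfCycle]]:
        return [
            (a, b)
            for a, b in zip(self.half_cycles, self.half_cycles[1:])
            if a.kind == FLEXION and b.kind == EXTENSION
        ]


class _Run:
    __slots__ = ("sign", "i0", "i1", "t_start", "t_end")

    def __init__(self, sign, i0, i1, t_start, t_end):
        self.sign, self.i0, self.i1 = sign, i0, i1
        self.t_start, self.t_end = t_start, t_end


def _hysteresis_states(w: np.ndarray, band: float) -> np.ndarray:
    """Per-sample sign state: flips only when ω exceeds the opposite band."""
    states = np.zeros(w.size, dtype=np.int8)
    state = 0
    for i, x in enumerate(w):
        if x > band:
            state = 1
        elif x < -band:
            state = -1
        states[i] = state
    # samples before the first band crossing belong to the first real run
    nz = np.flatnonzero(states)
    if nz.size:
        states[: nz[0]] = states[nz[0]]
    return states


def _zero_crossing(t: np.ndarray, w: np.ndarray, k: int) -> float:
    """Interpolated zero-crossing time between samples k and k+1."""
    w0, w1 = w[k], w[k + 1]
    if w0 == w1:
        return 0.5 * (t[k] + t[k + 1])
    return float(t[k] + (t[k + 1] - t[k]) * (0.0 - w0) / (w1 - w0))


def _initial_runs(t: np.ndarray, w: np.ndarray, band: float) -> list[_Run]:
    states = _hysteresis_states(w, band)
    if not states.any():
        return []
    change = np.flatnonzero(np.diff(states) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [w.size - 1]))
    runs = [_Run(int(states[i0]), int(i0), int(i1), t[i0], t[i1]) for i0, i1 in zip(starts, ends)]
    # reassign trailing samples whose actual sign already flipped (the state
    # machine only flips past the band) so every run is sign-pure, then set
    # shared boundaries at the interpolated zero crossing
    for prev, nxt in zip(runs, runs[1:]):
        k = prev.i1
        while k > prev.i0 and w[k] * nxt.sign > 0:
            k -= 1
        prev.i1, nxt.i0 = k, k + 1
        t_cross = _zero_crossing(t, w, k)
        prev.t_end = t_cross
        nxt.t_start = t_cross
    runs[0].t_start = float(t[runs[0].i0])
    runs[-1].t_end = float(t[runs[-1].i1])
    return runs


def segment(
    omega: AngularVelocitySeries,
    min_peak: float = DEFAULT_MIN_PEAK,
    min_duration: float = DEFAULT_MIN_DURATION,
    hysteresis: float = DEFAULT_HYSTERESIS,
) -> CycleSet:
    """Partition ω into alternating flexion/extension half-cycles.

    A sign-consistent run between zero crossings becomes a half-cycle when its
    extreme |ω| reaches ``min_peak`` and it lasts at least ``min_duration``.
    Sub-threshold runs are merged into same-signed neighbours or dropped when
    isolated; an empty :class:`CycleSet` is a valid result.
    """
    t, w = omega.t, omega.omega
    runs = _initial_runs(t, w, hysteresis)

    def peak_of(run: _Run) -> tuple[int, float]:
        seg = w[run.i0 : run.i1 + 1] * run.sign
        k = run.i0 + int(np.argmax(seg))
        return k, float(w[k])

    def acceptable(run: _Run) -> bool:
        k, pk = peak_of(run)
        if abs(pk) < min_peak or (run.t_end - run.t_start) < min_duration:
            return False
        # the peak must be interior: a monotone edge fragment has no peak
        return run.t_start < t[k] < run.t_end

    while runs:
        bad = [r for r in runs if not acceptable(r)]
        if not bad:
            break
        victim = min(bad, key=lambda r: abs(peak_of(r)[1]))
        j = runs.index(victim)
        runs.pop(j)
        left = runs[j - 1] if j - 1 >= 0 else None
        right = runs[j] if j < len(runs) else None
        if left is not None and right is not None and left.sign == right.sign:
            merged = _Run(left.sign, left.i0, right.i1, left.t_start, right.t_end)
            runs[j - 1 : j + 1] = [merged]

    half_cycles = []
    for run in runs:
        k, pk = peak_of(run)
        t_peak, peak = _refine_peak(t, w, k, run.i0, run.i1)
        t_peak = min(max(t_peak, run.t_start + 1e-12), run.t_end - 1e-12)
        half_cycles.append(
            HalfCycle(
                kind=FLEXION if run.sign > 0 else EXTENSION,
                t_start=run.t_start,
                t_peak=t_peak,
                t_end=run.t_end,
                peak_omega=peak if peak * run.sign > 0 else pk,
            )
        )
    return CycleSet(half_cycles)


def _refine_peak(
    t: np.ndarray, w: np.ndarray, k: int, i0: int, i1: int, shoulder: float = 0.75
) -> tuple[float, float]:
    """Sub-sample peak location from a least-squares parabola over the
    contiguous samples within ``shoulder`` of the extreme.

    Averaging over the whole peak shoulder (rather than a 3-point parabola)
    both removes the frame-rate quantisation of rise/fall times and damps
    measurement noise in the peak time.
    """
    if not (0 < k < w.size - 1):
        return float(t[k]), float(w[k])
    s = 1.0 if w[k] > 0 else -1.0
    lo = k
    while lo > i0 and w[lo - 1] * s >= shoulder * w[k] * s:
        lo -= 1
    hi = k
    while hi < i1 and w[hi + 1] * s >= shoulder * w[k] * s:
        hi += 1
    if hi - lo + 1 >= 4:
        tt = t[lo : hi + 1] - t[k]
        c2, c1, c0 = np.polyfit(tt, w[lo : hi + 1], 2)
        if c2 * s < 0:
            vertex = -c1 / (2.0 * c2)
            if tt[0] <= vertex <= tt[-1]:
                return float(t[k] + vertex), float(c0 - c1**2 / (4.0 * c2))
    y0, y1, y2 = w[k - 1], w[k], w[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(t[k]), float(w[k])
    delta = max(-0.5, min(0.5, 0.5 * (y0 - y2) / denom))
    dt = t[k + 1] - t[k]
    return float(t[k] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def assign_window(cycles: CycleSet, split: float = 10.0) -> tuple[CycleSet, CycleSet]:
    """Split half-cycles into first/last windows by temporal midpoint.

    Half-open convention: a midpoint strictly below ``split`` goes to the
    first window; a midpoint at exactly ``split`` goes to the last.
    """
    first = [h for h in cycles if h.midpoint < split]
    last = [h for h in cycles if h.midpoint >= split]
    return CycleSet(first), CycleSet(last)
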