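"""Head-speed and gaze compliance scoring for metronome-paced VORx1 exercises.

The pipeline is: time-aware smoothing -> extrema detection with a
prominence/zero-crossing filter and a minimum-height threshold -> conversion
of same-kind extrema intervals to beats-per-minute -> classification against
the prescribed tempo window -> percent-correct, gaze compliance and reward
coins.

Conventions
-----------
* One metronome beat = one head turn to one extreme, so a full oscillation
  (peak-to-peak) spans two beats and the ideal peak-to-peak interval is
  ``120 / goal_bpm`` seconds.
* All angles are degrees, all times seconds.
* The zero-crossing baseline is the whole-signal mean (camera angle traces
  carry a DC offset); it is subtracted before extrema detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "HeadAngleSeries",
    "Prescription",
    "Extremum",
    "ExtremaList",
    "Interval",
    "ComplianceReport",
    "GazeSeries",
    "smooth",
    "detect_extrema",
    "interval_bpm",
    "classify_intervals",
    "gaze_compliance",
    "compute_rewards",
    "analyze_series",
]

Plane = Literal["yaw", "pitch", "roll"]
Source = Literal["camera", "imu", "synthetic"]


@dataclass(frozen=True)
class HeadAngleSeries:
    """Timestamped head-angle samples in a single rotation plane.

    Parameters
    ----------
    times : array-like of float
        Sample times in seconds, strictly increasing, length >= 2.
    angles : array-like of float
        Head angle in degrees at each time.
    plane : {"yaw", "pitch", "roll"}
    source : {"camera", "imu", "synthetic"}
    """

    times: np.ndarray
    angles: np.ndarray
    plane: Plane = "yaw"
    source: Source = "synthetic"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "angles", angles)
        if times.ndim != 1 or angles.ndim != 1:
            raise ValueError("times and angles must be 1-D arrays")
        if len(times) != len(angles):
            raise ValueError(
                f"length mismatch: {len(times)} times vs {len(angles)} angles"
            )
        if len(times) < 2:
            raise ValueError("series must contain at least 2 samples")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(angles))):
            raise ValueError("times and angles must be finite")
        if np.any(np.diff(times) <= 0):
            i = int(np.argmax(np.diff(times) <= 0))
            raise ValueError(f"times must strictly increase (violation at index {i + 1})")
        if self.plane not in ("yaw", "pitch", "roll"):
            raise ValueError(f"plane must be yaw/pitch/roll, got {self.plane!r}")
        if self.source not in ("camera", "imu", "synthetic"):
            raise ValueError(f"source must be camera/imu/synthetic, got {self.source!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class Prescription:
    """Exercise prescription.

    ``direction`` maps onto the motion plane: horizontal -> yaw,
    vertical -> pitch.
    """

    goal_bpm: float
    duration_s: float = 30.0
    direction: Literal["horizontal", "vertical"] = "horizontal"
    compliance_delta_bpm: float = 15.0
    min_peak_height_deg: float = 4.0

    def __post_init__(self) -> None:
        if not self.goal_bpm > 0:
            raise ValueError(f"goal_bpm must be > 0, got {self.goal_bpm}")
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.compliance_delta_bpm < 0:
            raise ValueError("compliance_delta_bpm must be >= 0")
        if not self.goal_bpm > self.compliance_delta_bpm:
            raise ValueError("goal_bpm must exceed compliance_delta_bpm")
        if self.min_peak_height_deg < 0:
            raise ValueError("min_peak_height_deg must be >= 0")
        if self.direction not in ("horizontal", "vertical"):
            raise ValueError(f"direction must be horizontal/vertical, got {self.direction!r}")

    @property
    def plane(self) -> Plane:
        return "yaw" if self.direction == "horizontal" else "pitch"

    @property
    def ideal_interval_s(self) -> float:
        """Ideal same-kind (peak-to-peak) interval, 120/goal seconds."""
        return 120.0 / self.goal_bpm


@dataclass(frozen=True)
class Extremum:
    """A retained peak or valley.

    ``height`` is signed and measured relative to the detection baseline
    (negative for valleys); ``prominence`` is the standard topographic
    prominence of the extremum on the baseline-subtracted (and, for
    valleys, negated) signal.
    """

    time: float
    height: float
    prominence: float
    kind: Literal["peak", "valley"]


@dataclass(frozen=True)
class ExtremaList:
    """Time-ordered, strictly alternating peaks and valleys."""

    extrema: tuple[Extremum, ...]
    baseline_deg: float = 0.0

    def __post_init__(self) -> None:
        ts = [e.time for e in self.extrema]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("extrema times must strictly increase")
        kinds = [e.kind for e in self.extrema]
        if any(a == b for a, b in zip(kinds, kinds[1:])):
            raise ValueError("extrema kinds must strictly alternate")

    def __len__(self) -> int:
        return len(self.extrema)

    def __iter__(self):
        return iter(self.extrema)

    def of_kind(self, kind: Literal["peak", "valley"]) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == kind]

    @property
    def n_peaks(self) -> int:
        return sum(1 for e in self.extrema if e.kind == "peak")

    @property
    def n_valleys(self) -> int:
        return sum(1 for e in self.extrema if e.kind == "valley")


@dataclass(frozen=True)
class Interval:
    start_time: float
    end_time: float
    measured_bpm: float
    label: Literal["slow", "correct", "fast"]


@dataclass(frozen=True)
class ComplianceReport:
    """Per-interval tempo classification plus summary statistics.

    ``percent_correct`` is interval-count weighted and is ``None`` (flagged)
    when no interval could be formed.
    """

    intervals: tuple[Interval, ...]
    percent_correct: float | None
    mean_bpm: float | None
    n_peaks: int
    n_valleys: int
    goal_bpm: float
    compliance_delta_bpm: float

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def to_dict(self) -> dict:
        return {
            "goal_bpm": self.goal_bpm,
            "compliance_delta_bpm": self.compliance_delta_bpm,
            "n_peaks": self.n_peaks,
            "n_valleys": self.n_valleys,
            "n_intervals": self.n_intervals,
            "percent_correct": self.percent_correct,
            "mean_bpm": self.mean_bpm,
            "intervals": [
                {
                    "start_time": iv.start_time,
                    "end_time": iv.end_time,
                    "measured_bpm": iv.measured_bpm,
                    "label": iv.label,
                }
                for iv in self.intervals
            ],
        }


@dataclass(frozen=True)
class GazeSeries:
    """Binary on/off-target gaze labels per frame."""

    times: np.ndarray
    on_target: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        on = np.asarray(self.on_target, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "on_target", on)
        if len(times) != len(on):
            raise ValueError("times and on_target lengths must match")
        if len(times) == 0:
            raise ValueError("gaze series must contain at least 1 frame")
        if np.any(np.diff(times) < 0):
            raise ValueError("gaze times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)


def smooth(series: HeadAngleSeries, window_s: float) -> HeadAngleSeries:
    """Centered, time-aware moving average.

    Each output sample is the mean of all input samples whose timestamp lies
    within ``window_s / 2`` of the output timestamp; endpoints use truncated
    windows.  ``window_s == 0`` returns the input unchanged.  Time-based
    windowing keeps the filter well defined under frame-time jitter.
    """
    if window_s < 0:
        raise ValueError(f"window_s must be >= 0, got {window_s}")
    if window_s == 0:
        return series
    t = series.times
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(series.angles)))
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return HeadAngleSeries(t.copy(), out, plane=series.plane, source=series.source)


#: absolute tolerance (deg) for the prominence-vs-height comparison; guards
#: against float dust when a region boundary sits exactly on the baseline
PROMINENCE_TOL_DEG = 1e-9


def _one_sided_extrema(
    x: np.ndarray, t: np.ndarray, min_height: float, sign: float
) -> list[Extremum]:
    """Detect maxima of ``sign * x`` retained by the prominence/height filter."""
    y = sign * x
    idx, props = find_peaks(y, prominence=(0, None))
    out: list[Extremum] = []
    for i, prom in zip(idx, props["prominences"]):
        h = y[i]
        # prominence >= height-above-baseline <=> the peak is the single
        # greatest maximum in its region bounded by baseline crossings
        if prom >= h - PROMINENCE_TOL_DEG and h >= min_height:
            kind = "peak" if sign > 0 else "valley"
            out.append(Extremum(float(t[i]), float(sign * h), float(prom), kind))
    return out


def _enforce_alternation(extrema: list[Extremum]) -> list[Extremum]:
    """Drop same-kind runs, keeping the extremum of larger |height| (ties: earlier)."""
    kept: list[Extremum] = []
    for e in extrema:
        if kept and kept[-1].kind == e.kind:
            if abs(e.height) > abs(kept[-1].height):
                kept[-1] = e
        else:
            kept.append(e)
    return kept


def detect_extrema(series: HeadAngleSeries, min_peak_height_deg: float = 4.0) -> ExtremaList:
    """Extract peaks and valleys of a (pre-smoothed) head-angle signal.

    The whole-signal mean is subtracted as the zero-crossing baseline.  A
    local maximum is retained iff its topographic prominence is at least its
    height above baseline — i.e. it is the greatest maximum within its
    region bounded by a baseline crossing on each side — and its height is
    at least ``min_peak_height_deg``.  Valleys are obtained by the identical
    procedure on the negated signal.  The merged list strictly alternates;
    if thresholding leaves two same-kind neighbours, the one with larger
    absolute height wins (ties go to the earlier one).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 samples to detect extrema")
    if min_peak_height_deg < 0:
        raise ValueError("min_peak_height_deg must be >= 0")
    baseline = float(np.mean(series.angles))
    x = series.angles - baseline
    peaks = _one_sided_extrema(x, series.times, min_peak_height_deg, +1.0)
    valleys = _one_sided_extrema(x, series.times, min_peak_height_deg, -1.0)
    merged = sorted(peaks + valleys, key=lambda e: e.time)
    return ExtremaList(tuple(_enforce_alternation(merged)), baseline_deg=baseline)


def interval_bpm(dt_s: float, kind: str = "peak_to_peak") -> float:
    """Convert an extrema time interval to beats per minute.

    A full oscillation spans two metronome beats, so a same-kind
    (peak-to-peak or valley-to-valley) interval maps to ``120/dt`` bpm and
    an adjacent-extrema (half-cycle) interval to ``60/dt`` bpm.
    """
    if dt_s <= 0:
        raise ValueError(f"dt_s must be > 0, got {dt_s}")
    if kind == "peak_to_peak":
        return 120.0 / dt_s
    if kind == "adjacent_extrema":
        return 60.0 / dt_s
    raise ValueError(f"unknown interval kind {kind!r}")


def _label(measured: float, goal: float, delta: float) -> Literal["slow", "correct", "fast"]:
    if measured < goal - delta:
        return "slow"
    if measured > goal + delta:
        return "fast"
    return "correct"


def classify_intervals(extrema: ExtremaList, rx: Prescription) -> ComplianceReport:
    """Classify same-kind extrema intervals against the prescribed tempo.

    Consecutive peak->peak and valley->valley pairs each yield an interval
    with ``measured_bpm = 120/dt``; an interval is *correct* iff
    ``|measured - goal| <= compliance_delta_bpm``, otherwise *slow* or
    *fast*.  Fewer than 2 same-kind extrema yields a flagged empty report.
    """
    intervals: list[Interval] = []
    for kind in ("peak", "valley"):
        es = extrema.of_kind(kind)
        for a, b in zip(es, es[1:]):
            bpm = interval_bpm(b.time - a.time, "peak_to_peak")
            intervals.append(
                Interval(a.time, b.time, bpm, _label(bpm, rx.goal_bpm, rx.compliance_delta_bpm))
            )
    intervals.sort(key=lambda iv: (iv.start_time, iv.end_time))
    if intervals:
        n_correct = sum(1 for iv in intervals if iv.label == "correct")
        percent = 100.0 * n_correct / len(intervals)
        mean_bpm = float(np.mean([iv.measured_bpm for iv in intervals]))
    else:
        percent = None
        mean_bpm = None
    return ComplianceReport(
        intervals=tuple(intervals),
        percent_correct=percent,
        mean_bpm=mean_bpm,
        n_peaks=extrema.n_peaks,
        n_valleys=extrema.n_valleys,
        goal_bpm=rx.goal_bpm,
        compliance_delta_bpm=rx.compliance_delta_bpm,
    )


def gaze_compliance(gaze: GazeSeries) -> float:
    """Percentage of frames with on-target gaze, in [0, 100]."""
    return 100.0 * float(np.count_nonzero(gaze.on_target)) / len(gaze)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_rewards(completed: bool, head_percent: float, gaze_percent: float) -> int:
    """Reward coins: 5 for completion plus 0-5 per compliance percentage.

    Each compliance percentage maps to coins via ``round(5 * percent / 100)``
    with half-away-from-zero rounding; the total is in [0, 15].
    """
    for name, p in (("head_percent", head_percent), ("gaze_percent", gaze_percent)):
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"{name} must be in [0, 100], got {p}")
    coins = 5 if completed else 0
    coins += _round_half_away(5.0 * head_percent / 100.0)
    coins += _round_half_away(5.0 * gaze_percent / 100.0)
    return coins


def analyze_series(
    series: HeadAngleSeries, rx: Prescription, window_s: float = 0.15
) -> ComplianceReport:
    """Full pipeline: smooth, detect extrema, classify intervals."""
    smoothed = smooth(series, window_s)
    extrema = detect_extrema(smoothed, rx.min_peak_height_deg)
    return classify_intervals(extrema, rx)
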