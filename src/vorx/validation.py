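"""Camera-vs-reference (IMU) validation harness and classifier metrics.

Implements the paired-trial comparison used to certify the camera-based
head-angle pipeline against an IMU-derived reference: cross-correlation
temporal alignment with DC compensation, one-to-one peak matching with
dropped-peak handling, interpeak time errors, head-turn frequency errors
(including the analytic interval-error-to-bpm-error mapping), percent
correct comparison, plus accuracy/precision/recall/F1 from confusion
matrix counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _sig

from .compliance import (
    ComplianceReport,
    Extremum,
    ExtremaList,
    HeadAngleSeries,
    Prescription,
    analyze_series,
    classify_intervals,
    detect_extrema,
    smooth,
)

__all__ = [
    "AlignmentResult",
    "FrequencyErrorRecord",
    "ValidationReport",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "MatchResult",
    "align_series",
    "match_peaks",
    "interpeak_errors",
    "frequency_error",
    "trial_report",
    "classification_metrics",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of cross-correlation alignment of a reference onto a camera series.

    ``lag_s`` is positive when the camera signal is delayed relative to the
    reference; ``aligned`` is the reference shifted by the lag, resampled to
    the camera timestamps, with the camera-minus-reference mean offset
    (``dc_applied_deg``) added to compensate for the reference's missing DC
    component.
    """

    lag_s: float
    dc_applied_deg: float
    aligned: HeadAngleSeries
    grid_interval_s: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.aligned.angles)):
            raise ValueError("aligned series must be finite")


@dataclass(frozen=True)
class FrequencyErrorRecord:
    """Head-turn frequency error induced by a peak-to-peak interval error.

    For a goal tempo ``g`` (ideal interval 120/g seconds) and an interval
    measurement error ``e``, the induced bpm error is
    ``err_bpm = g * (-e / (120/g + e))`` — equivalently
    ``g + err_bpm = 120 / (120/g + e)``.
    """

    goal: float
    err_interval: float
    err_bpm: float

    def __post_init__(self) -> None:
        ideal = 120.0 / self.goal
        lhs = self.goal * (-self.err_interval / (ideal + self.err_interval))
        if abs(lhs - self.err_bpm) > 1e-9:
            raise ValueError("err_bpm inconsistent with goal and err_interval")


@dataclass(frozen=True)
class ValidationReport:
    """Paired-trial error metrics (camera vs reference)."""

    mean_abs_head_angle_error_deg: float
    head_angle_rmse_deg: float
    n_peaks_reference: int
    n_peaks_camera: int
    mean_matched_interpeak_time_error_s: float | None
    interpeak_time_rmse_s: float | None
    mean_abs_head_turn_frequency_error_bpm: float | None
    head_turn_frequency_rmse_bpm: float | None
    percent_correct_reference: float | None
    percent_correct_camera: float | None
    percent_correct_difference: float | None
    lag_s: float
    dc_applied_deg: float
    n_matched_pairs: int
    n_dropped_camera: int
    n_dropped_reference: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = on-target."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy/precision/recall/F1 rounded to 4 decimals.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None

    def astuple(self) -> tuple:
        return (self.accuracy, self.precision, self.recall, self.f1)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one nearest-in-time matching of same-kind extrema."""

    pairs: tuple[tuple[Extremum, Extremum], ...]
    n_dropped_a: int
    n_dropped_b: int


def _uniform_grid(camera: HeadAngleSeries, reference: HeadAngleSeries):
    t0 = max(camera.times[0], reference.times[0])
    t1 = min(camera.times[-1], reference.times[-1])
    if t1 - t0 < 5.0:
        raise ValueError(
            f"insufficient overlap: series share {max(t1 - t0, 0.0):.2f} s, need >= 5 s"
        )
    dt = float(np.median(np.diff(camera.times)))
    n = int(np.floor((t1 - t0) / dt)) + 1
    return t0 + np.arange(n) * dt, dt


def align_series(
    camera: HeadAngleSeries, reference: HeadAngleSeries, max_lag_s: float = 2.0
) -> AlignmentResult:
    """Temporally align a (zero-mean) reference series onto a camera series.

    Both series are linearly interpolated onto a uniform grid at the median
    camera frame interval; the lag maximizing the normalized
    cross-correlation of the mean-removed signals within ``±max_lag_s`` is
    taken as the camera delay.  The reference is shifted by that lag,
    resampled at the camera timestamps, and given the camera's mean as its
    DC component.
    """
    if max_lag_s < 0:
        raise ValueError("max_lag_s must be >= 0")
    grid, dt = _uniform_grid(camera, reference)
    cam_u = np.interp(grid, camera.times, camera.angles)
    ref_u = np.interp(grid, reference.times, reference.angles)
    cam_z = cam_u - cam_u.mean()
    ref_z = ref_u - ref_u.mean()
    corr = _sig.correlate(cam_z, ref_z, mode="full")
    lags = _sig.correlation_lags(len(cam_z), len(ref_z), mode="full")
    max_k = int(np.floor(max_lag_s / dt))
    window = np.abs(lags) <= max_k
    k = int(lags[window][np.argmax(corr[window])])
    lag_s = k * dt

    cam_mean = float(np.mean(camera.angles))
    ref_mean = float(np.mean(reference.angles))
    dc_applied = cam_mean - ref_mean
    aligned_angles = (
        np.interp(camera.times - lag_s, reference.times, reference.angles - ref_mean) + cam_mean
    )
    aligned = HeadAngleSeries(
        camera.times.copy(), aligned_angles, plane=camera.plane, source=reference.source
    )
    return AlignmentResult(
        lag_s=lag_s, dc_applied_deg=dc_applied, aligned=aligned, grid_interval_s=dt
    )


def match_peaks(a: ExtremaList, b: ExtremaList, tol_s: float) -> MatchResult:
    """Greedy nearest-in-time one-to-one matching of same-kind extrema.

    Candidate same-kind pairs within ``tol_s`` are taken in order of
    increasing time difference; extrema left unmatched (e.g. a peak missed
    by one system) are counted as dropped and excluded from interpeak
    statistics.
    """
    if tol_s < 0:
        raise ValueError("tol_s must be >= 0")
    ea, eb = list(a), list(b)
    candidates = [
        (abs(x.time - y.time), i, j)
        for i, x in enumerate(ea)
        for j, y in enumerate(eb)
        if x.kind == y.kind and abs(x.time - y.time) <= tol_s
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Extremum, Extremum]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((ea[i], eb[j]))
    pairs.sort(key=lambda p: p[0].time)
    return MatchResult(
        pairs=tuple(pairs),
        n_dropped_a=len(ea) - len(used_a),
        n_dropped_b=len(eb) - len(used_b),
    )


def _matched_interval_pairs(
    pairs: Sequence[tuple[Extremum, Extremum]],
) -> list[tuple[float, float]]:
    """(dt_a, dt_b) for consecutive matched pairs of the same kind."""
    out: list[tuple[float, float]] = []
    for kind in ("peak", "valley"):
        ps = [p for p in pairs if p[0].kind == kind]
        for (a0, b0), (a1, b1) in zip(ps, ps[1:]):
            out.append((a1.time - a0.time, b1.time - b0.time))
    return out


def interpeak_errors(
    pairs: Sequence[tuple[Extremum, Extremum]],
) -> tuple[float | None, float | None]:
    """Mean absolute and RMS difference of corresponding interpeak intervals.

    Intervals are formed between consecutive matched extrema of the same
    kind; fewer than 2 matched pairs yields ``(None, None)``.
    """
    ivs = _matched_interval_pairs(pairs)
    if not ivs:
        return None, None
    e = np.array([abs(da - db) for da, db in ivs])
    return float(np.mean(e)), float(np.sqrt(np.mean(e**2)))


def frequency_error(goal: float, err_interval: float) -> FrequencyErrorRecord:
    """Bpm error induced by a peak-to-peak interval measurement error."""
    if goal <= 0:
        raise ValueError(f"goal must be > 0, got {goal}")
    ideal = 120.0 / goal
    if ideal + err_interval <= 0:
        raise ValueError(
            f"non-physical interval: 120/goal + err_interval = {ideal + err_interval} <= 0"
        )
    err_bpm = goal * (-err_interval / (ideal + err_interval))
    return FrequencyErrorRecord(goal=goal, err_interval=err_interval, err_bpm=err_bpm)


def trial_report(
    camera: HeadAngleSeries,
    reference: HeadAngleSeries,
    rx: Prescription,
    smoothing_window_s: float = 0.15,
    max_lag_s: float = 2.0,
    match_tol_s: float | None = None,
) -> ValidationReport:
    """Full paired-trial comparison, one camera series vs one reference.

    Pipeline: cross-correlation alignment (with DC compensation) ->
    per-timestamp absolute head-angle errors; extrema detection on both
    smoothed signals -> peak counts; one-to-one peak matching (default
    tolerance = half a beat, 30/goal_bpm s) -> interpeak time errors and
    per-interval head-turn frequency errors (camera minus reference, via
    120/dt on matched consecutive same-kind intervals); interval
    classification on both -> percent-correct comparison (camera minus
    reference).
    """
    if match_tol_s is None:
        match_tol_s = 30.0 / rx.goal_bpm
    ar = align_series(camera, reference, max_lag_s=max_lag_s)
    abs_err = np.abs(camera.angles - ar.aligned.angles)
    mean_abs = float(np.mean(abs_err))
    rmse = float(np.sqrt(np.mean(abs_err**2)))

    cam_sm = smooth(camera, smoothing_window_s)
    ref_sm = smooth(ar.aligned, smoothing_window_s)
    cam_ex = detect_extrema(cam_sm, rx.min_peak_height_deg)
    ref_ex = detect_extrema(ref_sm, rx.min_peak_height_deg)
    match = match_peaks(cam_ex, ref_ex, match_tol_s)
    ip_mean, ip_rmse = interpeak_errors(match.pairs)

    ivs = _matched_interval_pairs(match.pairs)
    if ivs:
        bpm_err = np.array([120.0 / da - 120.0 / db for da, db in ivs])
        freq_mae = float(np.mean(np.abs(bpm_err)))
        freq_rmse = float(np.sqrt(np.mean(bpm_err**2)))
    else:
        freq_mae = freq_rmse = None

    cam_rep = classify_intervals(cam_ex, rx)
    ref_rep = classify_intervals(ref_ex, rx)
    pc_cam = cam_rep.percent_correct
    pc_ref = ref_rep.percent_correct
    pc_diff = pc_cam - pc_ref if (pc_cam is not None and pc_ref is not None) else None

    return ValidationReport(
        mean_abs_head_angle_error_deg=mean_abs,
        head_angle_rmse_deg=rmse,
        n_peaks_reference=ref_ex.n_peaks,
        n_peaks_camera=cam_ex.n_peaks,
        mean_matched_interpeak_time_error_s=ip_mean,
        interpeak_time_rmse_s=ip_rmse,
        mean_abs_head_turn_frequency_error_bpm=freq_mae,
        head_turn_frequency_rmse_bpm=freq_rmse,
        percent_correct_reference=pc_ref,
        percent_correct_camera=pc_cam,
        percent_correct_difference=pc_diff,
        lag_s=ar.lag_s,
        dc_applied_deg=ar.dc_applied_deg,
        n_matched_pairs=len(match.pairs),
        n_dropped_camera=match.n_dropped_a,
        n_dropped_reference=match.n_dropped_b,
    )


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Accuracy, precision, recall and F1 from confusion counts, to 4 decimals.

    Precision, recall or F1 with a zero denominator are reported as
    ``None`` (explicitly undefined), never coerced to 0.
    """
    total = cm.total
    accuracy = round((cm.tp + cm.tn) / total, 4)
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = round(2 * precision * recall / (precision + recall), 4)
    else:
        f1 = None
    return ClassificationMetrics(
        accuracy=accuracy,
        precision=None if precision is None else round(precision, 4),
        recall=None if recall is None else round(recall, 4),
        f1=f1,
    )
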