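"""Session records, file I/O and report rendering.

File conventions: head-angle series are CSV with header ``time_s,angle_deg``
(times in seconds, angles in degrees) plus an optional JSON sidecar with
metadata; reports are JSON validated against the schema shipped in
``vorx/schemas/session_report.schema.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

from .compliance import ComplianceReport, HeadAngleSeries, Prescription

__all__ = [
    "SymptomRecord",
    "DifficultyRating",
    "SessionRecord",
    "read_series",
    "write_series",
    "symptom_delta",
    "render_report",
    "load_report_schema",
    "validate_report",
]

SYMPTOMS = ("dizziness", "headache", "nausea", "fogginess")


@dataclass(frozen=True)
class SymptomRecord:
    """Symptom ratings on a continuous 0-10 scale, before or after exercise."""

    dizziness: float
    headache: float
    nausea: float
    fogginess: float
    phase: Literal["pre", "post"]

    def __post_init__(self) -> None:
        for name in SYMPTOMS:
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise ValueError(f"{name} rating must be in [0, 10], got {v}")
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be pre/post, got {self.phase!r}")


@dataclass(frozen=True)
class DifficultyRating:
    """Perceived difficulty on a discrete 0 (easiest) - 10 (hardest) scale."""

    value: int

    def __post_init__(self) -> None:
        if self.value != int(self.value) or not 0 <= self.value <= 10:
            raise ValueError(f"difficulty must be an integer in [0, 10], got {self.value!r}")


@dataclass(frozen=True)
class SessionRecord:
    """One completed (or aborted) exercise session."""

    prescription: Prescription
    pre_symptoms: SymptomRecord
    compliance: ComplianceReport
    gaze_percent: float
    coins: int
    started_at: str
    completed: bool
    post_symptoms: SymptomRecord | None = None
    difficulty: DifficultyRating | None = None

    def __post_init__(self) -> None:
        if self.pre_symptoms.phase != "pre":
            raise ValueError("pre_symptoms must have phase 'pre'")
        if self.post_symptoms is not None and self.post_symptoms.phase != "post":
            raise ValueError("post_symptoms must have phase 'post'")
        if self.post_symptoms is not None and not self.completed:
            raise ValueError("post-phase symptoms are recorded only for completed sessions")
        if not 0.0 <= self.gaze_percent <= 100.0:
            raise ValueError("gaze_percent must be in [0, 100]")


def read_series(path: str | Path) -> HeadAngleSeries:
    """Read a ``time_s,angle_deg`` CSV, reporting malformed rows by line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if header[:2] != ["time_s", "angle_deg"]:
        raise ValueError(f"{path}: line 1: expected header 'time_s,angle_deg', got {lines[0]!r}")
    times: list[float] = []
    angles: list[float] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 comma-separated values")
        try:
            t, a = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
        if times and t <= times[-1]:
            raise ValueError(
                f"{path}: line {lineno}: time {t!r} does not increase past {times[-1]!r}"
            )
        times.append(t)
        angles.append(a)

    plane, source = "yaw", "synthetic"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        plane = meta.get("plane", plane)
        source = meta.get("source", source)
    return HeadAngleSeries(np.array(times), np.array(angles), plane=plane, source=source)


def write_series(series: HeadAngleSeries, path: str | Path, metadata: dict | None = None) -> None:
    """Write a series as CSV at full precision, with a JSON metadata sidecar."""
    path = Path(path)
    rows = ["time_s,angle_deg"]
    rows += [f"{float(t)!r},{float(a)!r}" for t, a in zip(series.times, series.angles)]
    path.write_text("\n".join(rows) + "\n")
    meta = {"plane": series.plane, "source": series.source}
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def symptom_delta(pre: SymptomRecord, post: SymptomRecord) -> dict[str, float]:
    """Post minus pre rating per symptom; positive values mean worsening."""
    if pre.phase != "pre" or post.phase != "post":
        raise ValueError(
            f"phase mismatch: expected (pre, post), got ({pre.phase!r}, {post.phase!r})"
        )
    return {s: getattr(post, s) - getattr(pre, s) for s in SYMPTOMS}


def _fmt(x: float | None) -> float | None:
    return None if x is None else round(float(x), 2)


def render_report(session: SessionRecord) -> tuple[str, dict]:
    """Deterministic human-readable text + JSON-serializable session summary."""
    comp = session.compliance
    deltas = (
        symptom_delta(session.pre_symptoms, session.post_symptoms)
        if session.post_symptoms is not None
        else None
    )
    doc = {
        "schema": "vorx-session-report/1",
        "started_at": session.started_at,
        "completed": session.completed,
        "prescription": {
            "direction": session.prescription.direction,
            "goal_bpm": session.prescription.goal_bpm,
            "duration_s": session.prescription.duration_s,
            "compliance_delta_bpm": session.prescription.compliance_delta_bpm,
            "min_peak_height_deg": session.prescription.min_peak_height_deg,
        },
        "head_speed": {
            "percent_correct": _fmt(comp.percent_correct),
            "mean_bpm": _fmt(comp.mean_bpm),
            "n_peaks": comp.n_peaks,
            "n_valleys": comp.n_valleys,
            "n_intervals": comp.n_intervals,
        },
        "gaze_percent": _fmt(session.gaze_percent),
        "coins": session.coins,
        "difficulty": None if session.difficulty is None else session.difficulty.value,
        "pre_symptoms": {s: _fmt(getattr(session.pre_symptoms, s)) for s in SYMPTOMS},
        "post_symptoms": (
            None
            if session.post_symptoms is None
            else {s: _fmt(getattr(session.post_symptoms, s)) for s in SYMPTOMS}
        ),
        "symptom_delta": None if deltas is None else {s: _fmt(v) for s, v in deltas.items()},
    }

    lines = [
        f"Session report ({session.started_at})",
        f"  exercise: {session.prescription.direction} VORx1 at "
        f"{session.prescription.goal_bpm:g} bpm for {session.prescription.duration_s:g} s",
        f"  completed: {'yes' if session.completed else 'NO (incomplete session)'}",
        f"  head-speed compliance: "
        + (
            f"{doc['head_speed']['percent_correct']:.2f}%"
            if doc["head_speed"]["percent_correct"] is not None
            else "undefined (no intervals)"
        ),
        f"  gaze compliance: {doc['gaze_percent']:.2f}%",
        f"  coins earned: {session.coins}",
    ]
    if deltas is not None:
        worst = ", ".join(f"{s} {deltas[s]:+.2f}" for s in SYMPTOMS)
        lines.append(f"  symptom change (post - pre): {worst}")
    else:
        lines.append("  symptom change: unavailable (exercise incomplete)")
    return "\n".join(lines) + "\n", doc


def load_report_schema() -> dict:
    """The JSON schema shipped with the package for session reports."""
    ref = resources.files("vorx").joinpath("schemas/session_report.schema.json")
    return json.loads(ref.read_text())


def _check_node(value, schema, path: str, errors: list[str]) -> None:
    t = schema.get("type")
    types = t if isinstance(t, list) else [t] if t else []
    type_map = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool, "null": type(None),
    }
    if types:
        allowed = tuple(
            c for name in types for c in (
                type_map[name] if isinstance(type_map[name], tuple) else (type_map[name],)
            )
        )
        if isinstance(value, bool) and bool not in allowed:
            errors.append(f"{path}: expected {t}, got boolean")
            return
        if not isinstance(value, allowed):
            errors.append(f"{path}: expected {t}, got {type(value).__name__}")
            return
    if "enum" in schema and value not in schema["enum"]:
        errors.append(f"{path}: {value!r} not in {schema['enum']}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check_node(value[key], sub, f"{path}.{key}", errors)


def validate_report(doc: dict) -> list[str]:
    """Structurally validate a report dict against the shipped schema.

    Returns a list of violation messages (empty when valid).  Covers the
    subset of JSON Schema the shipped schema uses: type, enum, required,
    properties.
    """
    errors: list[str] = []
    _check_node(doc, load_report_schema(), "$", errors)
    return errors
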