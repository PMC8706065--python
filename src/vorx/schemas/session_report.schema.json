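{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/vorx/session_report.schema.json",
  "title": "vorx session report",
  "type": "object",
  "required": [
    "schema",
    "started_at",
    "completed",
    "prescription",
    "head_speed",
    "gaze_percent",
    "coins"
  ],
  "properties": {
    "schema": {"type": "string", "enum": ["vorx-session-report/1"]},
    "started_at": {"type": "string"},
    "completed": {"type": "boolean"},
    "prescription": {
      "type": "object",
      "required": ["direction", "goal_bpm", "duration_s", "compliance_delta_bpm", "min_peak_height_deg"],
      "properties": {
        "direction": {"type": "string", "enum": ["horizontal", "vertical"]},
        "goal_bpm": {"type": "number"},
        "duration_s": {"type": "number"},
        "compliance_delta_bpm": {"type": "number"},
        "min_peak_height_deg": {"type": "number"}
      }
    },
    "head_speed": {
      "type": "object",
      "required": ["percent_correct", "mean_bpm", "n_peaks", "n_valleys", "n_intervals"],
      "properties": {
        "percent_correct": {"type": ["number", "null"]},
        "mean_bpm": {"type": ["number", "null"]},
        "n_peaks": {"type": "integer"},
        "n_valleys": {"type": "integer"},
        "n_intervals": {"type": "integer"}
      }
    },
    "gaze_percent": {"type": "number"},
    "coins": {"type": "integer"},
    "difficulty": {"type": ["integer", "null"]},
    "pre_symptoms": {"type": "object"},
    "post_symptoms": {"type": ["object", "null"]},
    "symptom_delta": {"type": ["object", "null"]}
  }
}
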