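{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Trial table CSV dialect (informational)",
  "description": "One row per task trial. Sign conventions: x in pixels, 0 at the left screen edge; performance error = true_stop_x_px - target_x_px; estimation error = estimate_x_px - true_stop_x_px; direction +1 rightward / -1 leftward.",
  "type": "object",
  "required": [
    "participant_id", "condition", "phase", "block_index", "direction",
    "feedback_level", "target_x_px", "true_stop_x_px", "estimate_x_px",
    "sweeps", "reaction_time_s", "estimation_time_s", "excluded", "excluded_reason"
  ],
  "properties": {
    "participant_id": {"type": "string"},
    "condition": {"enum": ["self", "agent"]},
    "phase": {"enum": ["before", "during", "after"]},
    "block_index": {"type": "integer", "minimum": 0},
    "direction": {"enum": [1, -1]},
    "feedback_level": {"enum": ["low", "medium", "high", "none"]},
    "target_x_px": {"type": ["number", "null"]},
    "true_stop_x_px": {"type": "number"},
    "estimate_x_px": {"type": "number"},
    "sweeps": {"type": "integer", "minimum": 1},
    "reaction_time_s": {"type": ["number", "null"]},
    "estimation_time_s": {"type": "number", "exclusiveMinimum": 0},
    "excluded": {"type": "boolean"},
    "excluded_reason": {"type": "string"}
  }
}
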