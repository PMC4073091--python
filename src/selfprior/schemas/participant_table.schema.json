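{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Participant table CSV dialect (informational)",
  "type": "object",
  "required": [
    "participant_id", "performance_sd_px", "self_prior_sd_px",
    "agent_prior_sd_px", "agent_prior_flat", "optimism_score"
  ],
  "properties": {
    "participant_id": {"type": "string"},
    "performance_sd_px": {"type": "number", "exclusiveMinimum": 0},
    "self_prior_sd_px": {"type": "number", "exclusiveMinimum": 0},
    "agent_prior_sd_px": {"type": ["number", "null"], "description": "null when the agent prior is flat"},
    "agent_prior_flat": {"type": "boolean"},
    "optimism_score": {"type": "integer", "minimum": 0, "maximum": 24}
  }
}
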