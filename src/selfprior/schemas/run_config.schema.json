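{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "RunConfig JSON (informational)",
  "type": "object",
  "required": ["experiment", "seed"],
  "properties": {
    "experiment": {"enum": ["exp1", "exp2", "exp3"]},
    "seed": {"type": "integer"},
    "cohort": {
      "type": "object",
      "properties": {
        "n_participants": {"type": "integer", "minimum": 2},
        "performance_sd_dist": {"$ref": "#/$defs/dist"},
        "self_exaggeration_dist": {"$ref": "#/$defs/dist"},
        "agent_prior_mode": {
          "type": "object",
          "properties": {
            "kind": {"enum": ["matched", "flat_with_prob"]},
            "flat_prob": {"type": "number", "minimum": 0, "maximum": 1},
            "matched_ratio": {"$ref": "#/$defs/dist"}
          }
        },
        "optimism_partial_rho": {"type": "number", "minimum": -1, "maximum": 1},
        "feedback_perf_sd_factor": {"type": "number", "exclusiveMinimum": 0},
        "feedback_evid_sd_factor": {"type": "number", "exclusiveMinimum": 0},
        "evidence_sd_dist": {"$ref": "#/$defs/dist"},
        "evidence_self_ratio": {"type": "number", "exclusiveMinimum": 0},
        "momentum_shift_dist": {"$ref": "#/$defs/dist"},
        "momentum_self_ratio": {"type": "number", "exclusiveMinimum": 0},
        "seed": {"type": "integer"}
      }
    },
    "bootstrap_b": {"type": "integer", "minimum": 0},
    "bootstrap_alpha": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
    "n_restarts": {"type": "integer", "minimum": 1},
    "blocks_per_phase": {"type": "integer", "minimum": 1},
    "exp2_release_blocks": {"type": "integer", "minimum": 1},
    "exp2_stop_blocks": {"type": "integer", "minimum": 1},
    "exp2_no_target_blocks": {"type": "integer", "minimum": 1},
    "exp3_blocks_per_target": {"type": "integer", "minimum": 1}
  },
  "$defs": {
    "dist": {
      "type": "object",
      "required": ["mean", "sd"],
      "properties": {"mean": {"type": "number"}, "sd": {"type": "number", "minimum": 0}}
    }
  }
}
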