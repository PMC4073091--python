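{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "RunReport JSON (informational)",
  "type": "object",
  "required": ["experiment", "provenance", "checklist"],
  "properties": {
    "experiment": {"enum": ["exp1", "exp2", "exp3"]},
    "provenance": {
      "type": "object",
      "required": ["config_hash", "seed", "software_version"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "software_version": {"type": "string"}
      }
    },
    "checklist": {
      "type": "object",
      "additionalProperties": {"type": "boolean"},
      "required": ["all_patterns_reproduced"]
    },
    "group_stats": {"type": "object"},
    "model_selection": {"type": "object"},
    "group_table": {"type": "array"}
  }
}
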