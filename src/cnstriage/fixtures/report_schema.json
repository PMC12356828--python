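{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CandidateReport",
  "type": "object",
  "required": ["policy", "candidates", "exclusions"],
  "properties": {
    "policy": {
      "type": "object",
      "required": ["require_permeable", "exclude_pgp", "require_safety_window", "sort_keys"],
      "properties": {
        "require_permeable": {"type": "boolean"},
        "exclude_pgp": {"type": "boolean"},
        "require_safety_window": {"type": "boolean"},
        "sort_keys": {"type": "array", "items": {"type": "string"}, "minItems": 1}
      }
    },
    "candidates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["complex", "drug", "target", "rank"],
        "properties": {
          "complex": {"type": "string"},
          "drug": {"type": "string"},
          "target": {"type": "string"},
          "rank": {"type": "integer", "minimum": 1}
        }
      }
    },
    "exclusions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["complex", "drug", "reasons"],
        "properties": {
          "complex": {"type": "string"},
          "drug": {"type": "string"},
          "reasons": {"type": "array", "items": {"type": "string"}, "minItems": 1}
        }
      }
    }
  }
}
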