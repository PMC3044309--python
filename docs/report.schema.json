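{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tmarq hypothesis-test report",
  "type": "object",
  "required": ["hypothesis", "shared", "classifier", "dependent", "table",
               "p_value", "test", "alpha", "decision", "provenance"],
  "properties": {
    "hypothesis": {"type": "string"},
    "shared": {
      "type": "object",
      "required": ["attribute", "value"],
      "properties": {"attribute": {"type": "string"}, "value": {"type": "string"}}
    },
    "classifier": {"$ref": "#/$defs/factor"},
    "dependent": {"$ref": "#/$defs/factor"},
    "table": {
      "type": "object",
      "required": ["n11", "n12", "n21", "n22"],
      "additionalProperties": false,
      "properties": {
        "n11": {"type": "integer", "minimum": 0},
        "n12": {"type": "integer", "minimum": 0},
        "n21": {"type": "integer", "minimum": 0},
        "n22": {"type": "integer", "minimum": 0}
      }
    },
    "p_value": {"type": "number", "minimum": 0, "maximum": 1},
    "test": {"type": "string"},
    "alpha": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
    "decision": {"enum": ["supported", "rejected"]},
    "provenance": {
      "type": "object",
      "required": ["cores", "slides", "experiments"],
      "properties": {
        "cores": {"type": "integer", "minimum": 0},
        "slides": {"type": "integer", "minimum": 0},
        "experiments": {"type": "integer", "minimum": 0}
      }
    }
  },
  "$defs": {
    "factor": {
      "type": "object",
      "required": ["attribute", "hypothesis_values", "complement_values"],
      "properties": {
        "attribute": {"type": "string"},
        "hypothesis_values": {"type": "array", "items": {"type": "string"}, "minItems": 1},
        "complement_values": {"type": "array", "items": {"type": "string"}, "minItems": 1}
      }
    }
  }
}
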