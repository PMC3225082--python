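{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Ranked compound-disease evidence clusters",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["disease", "score", "metric", "rank", "paths"],
    "additionalProperties": false,
    "properties": {
      "disease": {"type": "string"},
      "score": {"type": "number", "minimum": 0},
      "metric": {"enum": ["path_count", "property_count"]},
      "rank": {"type": "integer", "minimum": 1},
      "paths": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["rule", "similar_compound", "similarity", "provenance"],
          "additionalProperties": false,
          "properties": {
            "rule": {"type": "string"},
            "similar_compound": {"type": "string"},
            "similarity": {"type": ["number", "null"]},
            "gene": {"type": "string"},
            "bioassay": {"type": "string"},
            "article": {"type": "string"},
            "provenance": {"type": "array", "items": {"type": "string"}}
          }
        }
      }
    }
  }
}
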