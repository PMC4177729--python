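{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ragmm combined report",
  "type": "object",
  "required": ["sample_id", "kb_version", "score", "band", "matches", "iss_stage", "adverse_count", "ultrahigh"],
  "properties": {
    "sample_id": {"type": "string", "minLength": 1},
    "kb_version": {"type": "string"},
    "score": {"type": ["number", "null"], "minimum": 1.0, "maximum": 3.0},
    "band": {"enum": ["low", "low_intermediate", "high_intermediate", "high", "unscorable"]},
    "matches": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["category", "group", "weight", "supporting"],
        "properties": {
          "category": {"type": "string"},
          "group": {"enum": ["red", "amber", "green"]},
          "weight": {"enum": [3.0, 2.0, 1.0]},
          "supporting": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["kind", "method"],
              "properties": {
                "kind": {"enum": ["translocation", "trisomy", "deletion", "gain", "mutation"]},
                "descriptor": {"type": ["string", "null"]},
                "gene": {"type": ["string", "null"]},
                "method": {"enum": ["FISH", "karyotype", "GEP", "sequencing"]},
                "consequence": {"enum": ["nonsynonymous", "synonymous", "other", null]}
              }
            }
          }
        }
      }
    },
    "iss_stage": {"enum": ["I", "II", "III", null]},
    "adverse_count": {"type": "integer", "minimum": 0},
    "ultrahigh": {"type": "boolean"}
  }
}
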