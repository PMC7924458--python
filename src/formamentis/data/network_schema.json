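{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Forma mentis network report",
  "type": "object",
  "required": ["nodes", "edges"],
  "properties": {
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "valence"],
        "properties": {
          "id": {"type": "string"},
          "valence": {"enum": ["positive", "neutral", "negative", "unknown"]}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "layer"],
        "properties": {
          "source": {"type": "string"},
          "target": {"type": "string"},
          "layer": {"enum": ["syntactic", "synonym"]}
        }
      }
    }
  }
}
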