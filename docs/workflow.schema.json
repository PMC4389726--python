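{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rivulet workflow",
  "description": "Declarative dataflow graph: typed nodes, ordered positional edges, nested groups. YAML workflow files are JSON-compatible instances of this schema.",
  "type": "object",
  "properties": {
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "category", "operator"],
        "properties": {
          "id": {"type": "string"},
          "category": {
            "enum": ["source", "combinator", "transform", "condition",
                     "sink", "property", "nested"]
          },
          "operator": {
            "type": "string",
            "description": "registered operator name; 'group' / 'select_many' for nested nodes, 'group_input' / 'group_output' for the placeholders inside a group, 'property' for property nodes"
          },
          "params": {"type": "object"},
          "exposed_properties": {
            "type": "array",
            "items": {"type": "string"},
            "description": "parameter names that property nodes may bind at runtime"
          }
        },
        "additionalProperties": false
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [
          {"type": "string", "description": "from node id"},
          {"type": "string", "description": "to node id"},
          {"type": "integer", "minimum": 0, "description": "input slot (default 0)"}
        ],
        "minItems": 2,
        "maxItems": 3
      },
      "description": "positional: the k-th inbound edge feeds input slot k"
    },
    "groups": {
      "type": "object",
      "additionalProperties": {"$ref": "#"},
      "description": "nested graph per NESTED node id; must contain one group_input source per external input (slot-numbered) and exactly one group_output sink"
    }
  },
  "required": ["nodes"],
  "additionalProperties": false
}
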