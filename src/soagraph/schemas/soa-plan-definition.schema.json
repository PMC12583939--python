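{
  "$comment": "SYNTHETIC structural reconstruction of the soaPlanDefinition profile at JSON-schema level, authored for this package from the published description of the soaTimePoint/soaTransition extension scheme; it is not the normative StructureDefinition.",
  "type": "object",
  "required": ["resourceType", "id", "title", "status", "action"],
  "properties": {
    "resourceType": {"const": "PlanDefinition"},
    "id": {"type": "string"},
    "title": {"type": "string"},
    "status": {"enum": ["draft", "active", "retired", "unknown"]},
    "action": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "extension", "groupingBehavior",
                     "selectionBehavior"],
        "properties": {
          "id": {"type": "string"},
          "title": {"type": "string"},
          "description": {"type": "string"},
          "groupingBehavior": {"const": "logical-group"},
          "selectionBehavior": {"const": "exactly-one"},
          "extension": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["url", "extension"],
              "properties": {
                "url": {"type": "string"},
                "extension": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["url"],
                    "properties": {"url": {"type": "string"}}
                  }
                }
              }
            }
          },
          "action": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["id", "extension"],
              "properties": {
                "id": {"type": "string"},
                "condition": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["kind", "expression"],
                    "properties": {
                      "kind": {"const": "applicability"},
                      "expression": {
                        "type": "object",
                        "required": ["language", "expression"],
                        "properties": {
                          "language": {"type": "string"},
                          "expression": {"type": "string"}
                        }
                      }
                    }
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
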