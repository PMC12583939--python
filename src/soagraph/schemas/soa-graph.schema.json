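{
  "$comment": "Structural schema for the native SoA graph JSON document.",
  "type": "object",
  "required": ["graphID", "title", "nodes", "edges"],
  "properties": {
    "graphID": {"type": "string"},
    "title": {"type": "string"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["nodeID", "alias", "type", "name", "role"],
        "properties": {
          "nodeID": {"type": "string"},
          "alias": {"type": "string"},
          "type": {"enum": ["interaction", "activity"]},
          "subtype": {"type": "string"},
          "name": {"type": "string"},
          "description": {"type": "string"},
          "plannedTiming": {"type": "integer"},
          "referenceTimepoint": {"type": "boolean"},
          "plannedWindow": {"type": "array", "items": {"type": "integer"}},
          "plannedDuration": {"type": "integer"},
          "role": {"enum": ["regular", "instantiation_start",
                            "instantiation_finish", "activity_start",
                            "activity_finish", "cycle_start",
                            "cycle_finish", "unscheduled"]},
          "extra": {"type": "object"}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["edgeID", "source", "target", "transitionType",
                     "origin"],
        "properties": {
          "edgeID": {"type": "string"},
          "source": {"type": "string"},
          "target": {"type": "string"},
          "transitionDelay": {"type": "integer"},
          "transitionWindow": {"type": "array",
                               "items": {"type": "integer"}},
          "transitionType": {"enum": ["start_to_start", "start_to_finish",
                                      "finish_to_start",
                                      "finish_to_finish"]},
          "transitionRule": {"type": "string"},
          "primaryPath": {"type": "boolean"},
          "origin": {"enum": ["explicit", "implied"]},
          "priority": {"type": "integer"},
          "extra": {"type": "object"}
        }
      }
    },
    "activitySubgraphs": {"type": "object"},
    "metadata": {"type": "object"}
  }
}
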