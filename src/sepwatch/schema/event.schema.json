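{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "sepwatch clinical event",
  "description": "One JSON-lines record: a time-stamped fact about an ED encounter.",
  "type": "object",
  "required": ["encounter_id", "time", "kind"],
  "properties": {
    "encounter_id": {"type": "string"},
    "time": {"type": "string", "format": "date-time"},
    "kind": {
      "enum": [
        "ed_arrival", "bpa_accepted", "blood_culture_ordered",
        "lactate_resulted", "antibiotic_administered", "provider_assigned",
        "provider_unassigned", "shift_start", "shift_end", "transfer",
        "ed_departure"
      ]
    },
    "payload": {
      "type": "object",
      "properties": {
        "value": {"type": "number", "exclusiveMinimum": 0,
                  "description": "lactate in mmol/L (lactate_resulted)"},
        "draw_index": {"type": "integer", "minimum": 1},
        "provider_id": {"type": "string"},
        "role": {"enum": ["attending", "resident", "np", "pa"]},
        "patient_id": {"type": "string"},
        "age": {"type": "integer", "minimum": 18},
        "sex": {"enum": ["female", "male"]}
      }
    }
  }
}
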