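{
  "episodes.csv": {
    "description": "One care episode per row. UTF-8, comma-delimited, ISO-8601 dates. Intervals are closed on calendar dates at the file level.",
    "columns": {
      "patient_id": {"type": "string", "required": true},
      "episode_id": {"type": "string", "required": true, "unique": true},
      "kind": {"type": "enum", "values": ["ED", "HOSPITALIZATION", "DAY_HOSPITAL", "OUTPATIENT"]},
      "start_date": {"type": "date", "format": "YYYY-MM-DD"},
      "end_date": {"type": "date", "format": "YYYY-MM-DD", "constraint": "end_date >= start_date; equals start_date for DAY_HOSPITAL and OUTPATIENT"},
      "department": {"type": "string", "examples": ["cardiology", "internal medicine", "ICU", "emergency", "other"]},
      "disposition": {"type": "enum", "values": ["HOME", "ADMITTED", "DIED", "OTHER"]},
      "diagnoses": {
        "type": "packed list",
        "item_format": "system:code:position:poa",
        "item_separator": "|",
        "system": ["ICD10CM", "ICPC2"],
        "position": "1-based integer rank, empty if undefined (1 = principal diagnosis)",
        "poa": "Y/N present-on-admission flag for hospitalization diagnoses, empty otherwise",
        "constraint": "ICPC2 codes only on ED episodes; positions unique within an episode",
        "example": "ICD10CM:J18.9:1:Y|ICD10CM:I50.9:2:Y"
      }
    }
  },
  "vitals.csv": {
    "description": "One row per patient; at most one record per patient.",
    "columns": {
      "patient_id": {"type": "string", "required": true, "unique": true},
      "death_date": {"type": "date", "format": "YYYY-MM-DD", "nullable": "empty string when alive"}
    }
  },
  "costs.csv": {
    "description": "One cost line item per row, attached to an episode. Amounts in euros at cent precision.",
    "columns": {
      "episode_id": {"type": "string", "required": true},
      "category": {"type": "enum", "values": ["DIRECT", "CATALOG", "RESIDUAL"]},
      "description": {"type": "string"},
      "quantity": {"type": "number", "nullable": "CATALOG items only"},
      "unit_cost": {"type": "number", "nullable": "CATALOG items only"},
      "amount": {"type": "number", "constraint": "amount >= 0; for CATALOG, amount = quantity * unit_cost"}
    }
  },
  "note": "This export format is an invented, minimum-basic-dataset-style schema; it is the package's own contract, not a registry standard."
}
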