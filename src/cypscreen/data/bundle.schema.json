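{
  "description": "All five panel datasets for one rule over one period (JSON-stable).",
  "properties": {
    "age_band_counts": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Age Band Counts",
      "type": "object"
    },
    "cytochrome": {
      "title": "Cytochrome",
      "type": "string"
    },
    "dosage_by_status": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Dosage By Status",
      "type": "object"
    },
    "dosage_coverage": {
      "anyOf": [
        {
          "maximum": 1.0,
          "minimum": 0.0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Dosage Coverage"
    },
    "n_patients": {
      "minimum": 0,
      "title": "N Patients",
      "type": "integer"
    },
    "period": {
      "title": "Period",
      "type": "string"
    },
    "perpetrator": {
      "title": "Perpetrator",
      "type": "string"
    },
    "relation": {
      "title": "Relation",
      "type": "string"
    },
    "rule_id": {
      "title": "Rule Id",
      "type": "string"
    },
    "sex_counts": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Sex Counts",
      "type": "object"
    },
    "substrate": {
      "title": "Substrate",
      "type": "string"
    },
    "time_series": {
      "items": {
        "maxItems": 2,
        "minItems": 2,
        "prefixItems": [
          {
            "type": "string"
          },
          {
            "type": "integer"
          }
        ],
        "type": "array"
      },
      "title": "Time Series",
      "type": "array"
    },
    "unit_breakdown": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Unit Breakdown",
      "type": "object"
    }
  },
  "required": [
    "rule_id",
    "cytochrome",
    "substrate",
    "relation",
    "perpetrator",
    "period",
    "n_patients",
    "time_series",
    "sex_counts",
    "age_band_counts",
    "unit_breakdown",
    "dosage_by_status"
  ],
  "title": "DashboardBundle",
  "type": "object"
}
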