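{
  "$defs": {
    "MetricRow": {
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "note": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Note"
        },
        "scaled": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Scaled"
        },
        "value": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Value"
        }
      },
      "required": [
        "name"
      ],
      "title": "MetricRow",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "inputs": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Inputs",
          "type": "object"
        },
        "package": {
          "default": "quartet-qc",
          "title": "Package",
          "type": "string"
        },
        "package_version": {
          "default": "0.1.0",
          "title": "Package Version",
          "type": "string"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        },
        "timestamp": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Timestamp"
        }
      },
      "title": "Provenance",
      "type": "object"
    }
  },
  "properties": {
    "category": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Category"
    },
    "metrics": {
      "items": {
        "$ref": "#/$defs/MetricRow"
      },
      "title": "Metrics",
      "type": "array"
    },
    "omics": {
      "title": "Omics",
      "type": "string"
    },
    "percentile": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Percentile"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    },
    "scorecard": {
      "additionalProperties": true,
      "title": "Scorecard",
      "type": "object"
    },
    "total_score": {
      "title": "Total Score",
      "type": "number"
    },
    "warnings": {
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    }
  },
  "required": [
    "omics",
    "scorecard",
    "total_score"
  ],
  "title": "QCReport",
  "type": "object"
}
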