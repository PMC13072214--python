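{
  "$defs": {
    "StageRecord": {
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "status": {
          "default": "ok",
          "title": "Status",
          "type": "string"
        },
        "n_records": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "N Records",
          "type": "object"
        },
        "warnings": {
          "items": {
            "type": "string"
          },
          "title": "Warnings",
          "type": "array"
        },
        "outputs": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Outputs",
          "type": "object"
        },
        "wall_time_s": {
          "default": 0.0,
          "title": "Wall Time S",
          "type": "number"
        },
        "error": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Error"
        }
      },
      "required": [
        "name"
      ],
      "title": "StageRecord",
      "type": "object"
    }
  },
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "stages": {
      "items": {
        "$ref": "#/$defs/StageRecord"
      },
      "title": "Stages",
      "type": "array"
    }
  },
  "required": [
    "seed"
  ],
  "title": "RunReport",
  "type": "object"
}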