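{
  "description": "Schema of ``report.json`` (also shipped as data/report.schema.json).",
  "properties": {
    "bait": {
      "additionalProperties": true,
      "title": "Bait",
      "type": "object"
    },
    "enrichment": {
      "additionalProperties": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Enrichment",
      "type": "object"
    },
    "input_checksums": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Input Checksums",
      "type": "object"
    },
    "overlap_percent": {
      "title": "Overlap Percent",
      "type": "number"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "set_sizes": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Set Sizes",
      "type": "object"
    },
    "tool": {
      "title": "Tool",
      "type": "string"
    },
    "version": {
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "tool",
    "version",
    "parameters",
    "input_checksums",
    "set_sizes",
    "overlap_percent",
    "bait",
    "enrichment"
  ],
  "title": "RunReport",
  "type": "object"
}
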