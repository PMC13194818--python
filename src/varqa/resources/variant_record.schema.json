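{
  "$defs": {
    "ClinicalSignificance": {
      "additionalProperties": false,
      "description": "One curated condition with its interpretation terms.",
      "properties": {
        "condition": {
          "title": "Condition",
          "type": "string"
        },
        "interpretations": {
          "items": {
            "type": "string"
          },
          "title": "Interpretations",
          "type": "array"
        }
      },
      "required": [
        "condition"
      ],
      "title": "ClinicalSignificance",
      "type": "object"
    },
    "Consequence": {
      "additionalProperties": false,
      "description": "Most severe consequence as a Sequence Ontology accession + label.",
      "properties": {
        "accession": {
          "title": "Accession",
          "type": "string"
        },
        "label": {
          "title": "Label",
          "type": "string"
        }
      },
      "required": [
        "accession",
        "label"
      ],
      "title": "Consequence",
      "type": "object"
    },
    "Prediction": {
      "additionalProperties": false,
      "description": "A pathogenicity prediction score with its qualitative label.",
      "properties": {
        "score": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Score",
          "type": "number"
        },
        "label": {
          "title": "Label",
          "type": "string"
        }
      },
      "required": [
        "score",
        "label"
      ],
      "title": "Prediction",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "togovar_id": {
      "minLength": 1,
      "title": "Togovar Id",
      "type": "string"
    },
    "rs_id": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Rs Id"
    },
    "chromosome": {
      "title": "Chromosome",
      "type": "string"
    },
    "position": {
      "minimum": 1,
      "title": "Position",
      "type": "integer"
    },
    "ref": {
      "minLength": 1,
      "title": "Ref",
      "type": "string"
    },
    "alt": {
      "minLength": 1,
      "title": "Alt",
      "type": "string"
    },
    "gene_symbol": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Gene Symbol"
    },
    "clinical_significance": {
      "items": {
        "$ref": "#/$defs/ClinicalSignificance"
      },
      "title": "Clinical Significance",
      "type": "array"
    },
    "most_severe_consequence": {
      "anyOf": [
        {
          "$ref": "#/$defs/Consequence"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "hgvs": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Hgvs",
      "type": "object"
    },
    "predictions": {
      "additionalProperties": {
        "$ref": "#/$defs/Prediction"
      },
      "title": "Predictions",
      "type": "object"
    },
    "allele_frequencies": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Allele Frequencies",
      "type": "object"
    },
    "external_links": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "External Links",
      "type": "object"
    }
  },
  "required": [
    "togovar_id",
    "chromosome",
    "position",
    "ref",
    "alt"
  ],
  "title": "VariantRecord",
  "type": "object"
}
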