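{
  "$defs": {
    "GeneVariantCall": {
      "description": "A patient's star-allele diplotype for one pharmacogene.",
      "properties": {
        "gene": {
          "title": "Gene",
          "type": "string"
        },
        "diplotype": {
          "title": "Diplotype",
          "type": "string"
        },
        "activity_score": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Activity Score"
        }
      },
      "required": [
        "gene",
        "diplotype"
      ],
      "title": "GeneVariantCall",
      "type": "object"
    },
    "Guideline": {
      "description": "One evidence-based drug\u2013gene-variant dosing recommendation.\n\n``metabolizer_status`` is per drug\u2013gene pair (the same diplotype can\nimply different phenotypes for different substrates). ``dose_percent``\nis derived from ``recommendation_text`` at parse time when the text\nquantifies the adjustment as a percentage.",
      "properties": {
        "guideline_id": {
          "default": "",
          "title": "Guideline Id",
          "type": "string"
        },
        "gene": {
          "title": "Gene",
          "type": "string"
        },
        "diplotype": {
          "default": "",
          "title": "Diplotype",
          "type": "string"
        },
        "metabolizer_status": {
          "default": "UNKNOWN",
          "title": "Metabolizer Status",
          "type": "string"
        },
        "drug_name": {
          "default": "",
          "title": "Drug Name",
          "type": "string"
        },
        "drug_cas": {
          "default": "",
          "title": "Drug Cas",
          "type": "string"
        },
        "recommendation_text": {
          "default": "",
          "title": "Recommendation Text",
          "type": "string"
        },
        "recommendation_category": {
          "default": "standard",
          "title": "Recommendation Category",
          "type": "string"
        },
        "severity": {
          "default": 1,
          "title": "Severity",
          "type": "integer"
        },
        "evidence_level": {
          "default": "NONE",
          "title": "Evidence Level",
          "type": "string"
        },
        "source_url": {
          "default": "",
          "title": "Source Url",
          "type": "string"
        },
        "effect_text": {
          "default": "",
          "title": "Effect Text",
          "type": "string"
        },
        "dose_percent": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Dose Percent"
        }
      },
      "required": [
        "gene"
      ],
      "title": "Guideline",
      "type": "object"
    },
    "Prescription": {
      "description": "A prescribed drug, optionally under a brand name.",
      "properties": {
        "drug_name": {
          "title": "Drug Name",
          "type": "string"
        },
        "drug_cas": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Drug Cas"
        },
        "brand_name": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Brand Name"
        }
      },
      "required": [
        "drug_name"
      ],
      "title": "Prescription",
      "type": "object"
    }
  },
  "description": "Patient PGx report interchange document: demographics, prescriptions, gene-variant calls and dosing guidelines.",
  "properties": {
    "name": {
      "default": "",
      "title": "Name",
      "type": "string"
    },
    "age": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Age"
    },
    "sex": {
      "default": "",
      "title": "Sex",
      "type": "string"
    },
    "bmi": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Bmi"
    },
    "diagnoses": {
      "items": {
        "type": "string"
      },
      "title": "Diagnoses",
      "type": "array"
    },
    "prescriptions": {
      "items": {
        "$ref": "#/$defs/Prescription"
      },
      "title": "Prescriptions",
      "type": "array"
    },
    "variants": {
      "items": {
        "$ref": "#/$defs/GeneVariantCall"
      },
      "title": "Variants",
      "type": "array"
    },
    "guidelines": {
      "items": {
        "$ref": "#/$defs/Guideline"
      },
      "title": "Guidelines",
      "type": "array"
    }
  },
  "title": "PatientRecord",
  "type": "object"
}
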