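{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "famvar full-study report",
  "type": "object",
  "required": [
    "provenance",
    "subjects",
    "cascade",
    "segregation",
    "cohort_screen",
    "panel_aggregate",
    "group_comparisons"
  ],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package_version", "seed", "config_sha256"],
      "properties": {
        "package_version": {"type": "string"},
        "seed": {"type": "integer"},
        "config_sha256": {"type": "string"}
      }
    },
    "subjects": {
      "type": "object",
      "required": ["wes_cases", "wes_controls"],
      "properties": {
        "wes_cases": {"type": "array", "items": {"type": "string"}},
        "wes_controls": {"type": "array", "items": {"type": "string"}}
      }
    },
    "cascade": {
      "type": "object",
      "required": ["stages", "final_candidates"],
      "properties": {
        "stages": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name", "input_count", "output_count", "survivor_ids"],
            "properties": {
              "name": {"type": "string"},
              "input_count": {"type": "integer"},
              "output_count": {"type": "integer"},
              "survivor_ids": {"type": "array", "items": {"type": "string"}}
            }
          }
        },
        "final_candidates": {"type": "array", "items": {"type": "string"}}
      }
    },
    "segregation": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "variant_id",
          "case_carriers",
          "case_total",
          "control_carriers",
          "control_total",
          "cosegregates",
          "discordant_ids"
        ],
        "properties": {
          "variant_id": {"type": "string"},
          "case_carriers": {"type": "integer"},
          "case_total": {"type": "integer"},
          "control_carriers": {"type": "integer"},
          "control_total": {"type": "integer"},
          "cosegregates": {"type": "boolean"},
          "discordant_ids": {"type": "array", "items": {"type": "string"}},
          "missing_ids": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "cohort_screen": {
      "type": "object",
      "required": ["cohort_name", "n_cases", "n_controls", "case_carriers", "control_carriers"],
      "properties": {
        "cohort_name": {"type": "string"},
        "n_cases": {"type": "integer"},
        "n_controls": {"type": "integer"},
        "case_carriers": {"type": "integer"},
        "control_carriers": {"type": "integer"},
        "n_missing": {"type": "integer"}
      }
    },
    "panel_aggregate": {
      "type": "object",
      "required": ["panels", "total_individuals", "total_alt_alleles", "allele_frequency"],
      "properties": {
        "panels": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name", "n_individuals", "alt_allele_count"],
            "properties": {
              "name": {"type": "string"},
              "n_individuals": {"type": "integer"},
              "alt_allele_count": {"type": "integer"}
            }
          }
        },
        "total_individuals": {"type": "integer"},
        "total_alt_alleles": {"type": "integer"},
        "allele_frequency": {"type": "number"}
      }
    },
    "group_comparisons": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["parameter", "case", "control", "method"],
        "properties": {
          "parameter": {"type": "string"},
          "units": {"type": "string"},
          "case": {
            "type": "object",
            "required": ["n", "mean"],
            "properties": {
              "n": {"type": "integer"},
              "mean": {"type": "number"},
              "sd": {"type": ["number", "null"]},
              "sem": {"type": ["number", "null"]}
            }
          },
          "control": {
            "type": "object",
            "required": ["n", "mean"],
            "properties": {
              "n": {"type": "integer"},
              "mean": {"type": "number"},
              "sd": {"type": ["number", "null"]},
              "sem": {"type": ["number", "null"]}
            }
          },
          "U": {"type": ["number", "null"]},
          "p_two_sided": {"type": ["number", "null"]},
          "method": {"type": "string"}
        }
      }
    },
    "simulation": {
      "type": "object",
      "properties": {
        "causal_id": {"type": "string"},
        "causal_in_final_candidates": {"type": "boolean"},
        "causal_cosegregates": {"type": "boolean"}
      }
    }
  }
}
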