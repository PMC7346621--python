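{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "medcomplex knowledge base",
  "description": "Structure of knowledge_base.yaml. Shipped as format documentation; runtime validation is performed by medcomplex.knowledge_base.validate_kb, which additionally enforces the cross-record invariants (61 factors, 8 distinct questions, 5 algorithms, reference integrity).",
  "type": "object",
  "required": ["version", "language", "factors", "questions", "measures"],
  "properties": {
    "version": {"type": "integer"},
    "language": {"type": "string"},
    "factors": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "label", "category", "automated", "in_tool"],
        "properties": {
          "id": {"type": "string"},
          "label": {"type": "string"},
          "category": {
            "enum": ["dosage_form", "dosage_scheme", "additional_instructions", "patient", "product", "process"]
          },
          "automated": {"type": "boolean"},
          "in_tool": {"type": "boolean"},
          "mechanism": {
            "enum": ["pzn", "dosage_scheme", "schedule_lines", "keywords", "pzn_and_keywords"]
          },
          "device_subtypes": {"type": "array", "items": {"type": "string"}},
          "questions": {"type": "array", "items": {"type": "string"}},
          "measures": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "questions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind", "parts"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["key", "distinct", "open"]},
          "device_subtypes": {"type": "array", "items": {"type": "string"}},
          "parts": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["text", "answer_type", "predicate"],
              "properties": {
                "text": {"type": "string"},
                "answer_type": {"enum": ["yes_no", "numeric", "free_text"]},
                "predicate": {
                  "type": "object",
                  "required": ["name"],
                  "properties": {
                    "name": {
                      "enum": ["yes_is_problem", "no_is_problem", "numeric_below", "numeric_above", "informational", "note_only"]
                    },
                    "threshold": {"type": "number"}
                  }
                }
              }
            }
          }
        }
      }
    },
    "measures": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "type"],
        "properties": {
          "id": {"type": "string"},
          "type": {"enum": ["recommendation_for_action", "training_material", "algorithm"]},
          "title": {"type": "string"},
          "topic": {"enum": ["aid_suggestion", "explain_administration", "review_regimen"]},
          "resource_ref": {"type": "string"},
          "algorithm_ref": {"type": "string"}
        }
      }
    }
  }
}
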