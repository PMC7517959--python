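{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "trialscape registry dialect",
 "description": "Minimal JSON dialect for curated trial-registry snapshots: one object per study with the extracted analysis fields only.",
 "version": "1.0",
 "type": "object",
 "required": ["schema_version", "trials"],
 "properties": {
  "schema_version": {"const": "1.0"},
  "trials": {
   "type": "array",
   "items": {
    "type": "object",
    "required": [
     "registry_id", "title", "study_type", "phase", "recruitment_status",
     "is_net", "is_therapeutic", "disease_stage", "line_of_therapy",
     "endpoint_class", "interventions"
    ],
    "additionalProperties": false,
    "properties": {
     "registry_id": {"type": "string", "pattern": "^NCT[0-9]{8}$"},
     "title": {"type": "string"},
     "study_type": {"enum": ["interventional", "observational"]},
     "phase": {"enum": ["I", "I_II", "II", "II_III", "III"]},
     "recruitment_status": {
      "enum": ["recruiting", "active_not_recruiting", "enrolling_by_invitation",
               "completed", "terminated", "suspended", "withdrawn", "unknown"]
     },
     "is_net": {"type": "boolean"},
     "is_therapeutic": {"type": "boolean"},
     "disease_stage": {
      "enum": ["advanced_metastatic", "localized_resectable", "localized_borderline",
               "localized_unresectable", "localized_any", "unspecified"]
     },
     "line_of_therapy": {"enum": ["first", "second_or_later", "unspecified"]},
     "endpoint_class": {
      "enum": ["survival", "quality_of_life", "pain", "complication", "sequelae", "infection"]
     },
     "novelty_group": {
      "enum": ["novel_intervention", "conventional_manipulation",
               "technical_procedure", "pain_management"]
     },
     "novelty_subgroup": {
      "enum": ["efficacy_other_cancer", "repurposed_non_cancer", "novel_to_all"]
     },
     "interventions": {
      "type": "array",
      "minItems": 1,
      "items": {
       "type": "object",
       "required": ["name", "category_code"],
       "additionalProperties": false,
       "properties": {
        "name": {"type": "string"},
        "category_code": {"type": "string"},
        "mechanism_code": {"type": "string"}
       }
      }
     }
    }
   }
  }
 }
}
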