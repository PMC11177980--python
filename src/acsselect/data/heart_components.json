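{
  "description": "Editable covariate-to-component mapping for the HEAR/HEART chest-pain scores. Each component scores 0-2 points. The mapping is a proxy built from the covariates available in the prehospital schema; align the cut points and covariate lists with your institution's HEART conventions before clinical interpretation.",
  "age_cutpoints": {"one_point_at": 45, "two_points_at": 65},
  "risk_factors": [
    "hypercholesterolemia",
    "hypertension",
    "current_smoker",
    "diabetes",
    "family_history_cv"
  ],
  "atherosclerotic_history": ["prior_mi", "prior_pci", "prior_cabg", "cad"],
  "risk_counts": {"one_point_at": 1, "two_points_at": 3},
  "history_primary_symptom": "sym_chest_pain",
  "history_supporting_symptoms": ["sym_diaphoresis", "sym_nausea_vomiting"]
}
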