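{
  "description": "Covariate schema for the prehospital chest-pain cohort: 23 covariates (2 baseline, 10 medical-history binaries, 8 symptom binaries, 3 per-lead ECG interpretation vectors). ECG vectors expand to 11 CSV columns each, suffixed _L01.._L11.",
  "ecg_vector_length": 11,
  "entries": [
    {"name": "age", "group": "baseline", "kind": "numeric"},
    {"name": "gender_male", "group": "baseline", "kind": "binary"},
    {"name": "hypercholesterolemia", "group": "history", "kind": "binary"},
    {"name": "hypertension", "group": "history", "kind": "binary"},
    {"name": "current_smoker", "group": "history", "kind": "binary"},
    {"name": "diabetes", "group": "history", "kind": "binary"},
    {"name": "prior_mi", "group": "history", "kind": "binary"},
    {"name": "angina", "group": "history", "kind": "binary"},
    {"name": "prior_cabg", "group": "history", "kind": "binary"},
    {"name": "prior_pci", "group": "history", "kind": "binary"},
    {"name": "cad", "group": "history", "kind": "binary"},
    {"name": "family_history_cv", "group": "history", "kind": "binary"},
    {"name": "sym_other", "group": "symptom", "kind": "binary"},
    {"name": "sym_chest_pain", "group": "symptom", "kind": "binary"},
    {"name": "sym_syncope", "group": "symptom", "kind": "binary"},
    {"name": "sym_shortness_of_breath", "group": "symptom", "kind": "binary"},
    {"name": "sym_diaphoresis", "group": "symptom", "kind": "binary"},
    {"name": "sym_nausea_vomiting", "group": "symptom", "kind": "binary"},
    {"name": "sym_palpitations", "group": "symptom", "kind": "binary"},
    {"name": "sym_other_symptoms", "group": "symptom", "kind": "binary"},
    {"name": "ecg_st_elevation", "group": "ecg", "kind": "binary_vector_11"},
    {"name": "ecg_st_depression", "group": "ecg", "kind": "binary_vector_11"},
    {"name": "ecg_t_wave_inversion", "group": "ecg", "kind": "binary_vector_11"}
  ]
}
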