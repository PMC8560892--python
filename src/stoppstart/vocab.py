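"""Controlled vocabularies: diagnosis labels, qualifier flags, Charlson weights.

Diagnoses are coded with a closed label set rather than raw ICD-9-CM codes,
because long-term-care records routinely carry diagnoses outside the coded
discharge list.  Every label a screening rule or covariate refers to is
declared here; unknown labels are rejected at the boundary.
"""

from __future__ import annotations

# Diagnosis labels.  "atrial_fibrillation" stands for the combined
# arrhythmia / chronic atrial fibrillation category; "coronary_artery_disease"
# covers angina and documented coronary disease.
CONDITIONS: frozenset[str] = frozenset(
    {
        "hypertension",
        "cerebrovascular_disease",
        "depression",
        "diabetes_mellitus",
        "constipation",
        "dementia",
        "urinary_incontinence",
        "rheumatic_disease",
        "congestive_heart_failure",
        "atrial_fibrillation",
        "benign_prostatic_hypertrophy",
        "renal_disease",
        "copd_asthma",
        "non_metastatic_solid_tumor",
        "hemiplegia",
        "parkinsons_disease",
        "metastatic_solid_tumor",
        "coronary_artery_disease",
        "peripheral_vascular_disease",
        "osteoporosis",
        "osteopenia",
        "glaucoma_narrow_angle",
        "peptic_ulcer",
        "delirium",
        "respiratory_failure",
        "prostatism_urinary_retention",
        "cardiac_conduction_abnormality",
        "bradycardia",
        "psychosis",
        "major_depressive_symptoms",
        "proteinuric_diabetic_renal_disease",
    }
)

# Patient-level judgement/qualifier flags consumed by screening rules.
# A missing flag is read as False: a rule that needs clinical judgement does
# not fire without an explicit record (conservative screening).
QUALIFIERS: frozenset[str] = frozenset(
    {
        "drug_without_indication",
        "tca_first_line",
        "behavioural_symptoms_mild",
        "ppi_full_dose",
        "serum_potassium_not_monitored",
        "end_of_life",
        "prostatectomy_considered_necessary",
    }
)

# Comorbidity list used for the comorbid-disease count (the most common /
# clinically significant comorbidities tabulated for this population).
COMORBIDITY_LIST: tuple[str, ...] = (
    "hypertension",
    "cerebrovascular_disease",
    "depression",
    "diabetes_mellitus",
    "constipation",
    "dementia",
    "urinary_incontinence",
    "rheumatic_disease",
    "congestive_heart_failure",
    "atrial_fibrillation",
    "benign_prostatic_hypertrophy",
    "renal_disease",
    "copd_asthma",
    "non_metastatic_solid_tumor",
    "hemiplegia",
    "parkinsons_disease",
    "metastatic_solid_tumor",
    "coronary_artery_disease",
    "osteoporosis",
    "glaucoma_narrow_angle",
)

# Charlson comorbidity weights for the conditions representable in this
# vocabulary (classic 1987 weighting).  Conditions absent from the map score 0.
CHARLSON_WEIGHTS: dict[str, int] = {
    "congestive_heart_failure": 1,
    "cerebrovascular_disease": 1,
    "peripheral_vascular_disease": 1,
    "dementia": 1,
    "copd_asthma": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer": 1,
    "diabetes_mellitus": 1,
    "hemiplegia": 2,
    "renal_disease": 2,
    "proteinuric_diabetic_renal_disease": 2,  # diabetes with end-organ damage
    "non_metastatic_solid_tumor": 2,
    "metastatic_solid_tumor": 6,
}
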