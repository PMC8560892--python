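"""Synthetic post-acute / long-term-care cohort generator.

The study population this emulates is a frail geriatric inpatient cohort:
median age around 82, two-thirds female, a median of 9 regular drugs per day,
heavy comorbidity (median Charlson index 6) and high rates of dependency and
fall risk.  Covariate marginals default to the prevalences observed in that
population; medications are drawn conditionally on diagnoses so that every
screening rule in the default catalog is exercisable.

Comorbidities are sampled independently except for explicitly conditional
pairs (e.g. major depressive symptoms only arise within depression, diabetic
renal disease within diabetes, prostatic conditions only in men); no joint
correlation structure beyond that is modelled.

All randomness flows from one root seed; each patient consumes an independent
substream derived from (seed, patient index), so records are reproducible and
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    DiagnosisEntry,
    MedicationEntry,
    PatientRecord,
    covariate_frame,
)

__all__ = ["CohortConfig", "generate", "plant_outcome"]


class ConfigError(ValueError):
    """Raised for an infeasible or inconsistent generator configuration."""


# Prevalence targets for directly sampled covariates (fractions of the
# cohort; *_male entries are conditional on male gender, with_* entries are
# conditional on the named parent condition).
DEFAULT_MARGINALS: dict[str, float] = {
    "female": 0.640,
    "enteral_nutrition": 0.130,
    "dependency_adl": 0.888,
    "fall_risk_medium_high": 0.814,
    "malnutrition": 0.043,
    "obesity": 0.137,
    "pressure_ulcers": 0.168,
    "recent_fracture": 0.286,
    "housebound_or_falls": 0.55,
    "polypharmacy": 0.913,  # emergent target; used for feasibility checks
    # comorbidities
    "hypertension": 0.683,
    "cerebrovascular_disease": 0.348,
    "depression": 0.342,
    "diabetes_mellitus": 0.335,
    "constipation": 0.335,
    "dementia": 0.292,
    "urinary_incontinence": 0.280,
    "rheumatic_disease": 0.236,
    "congestive_heart_failure": 0.224,
    "atrial_fibrillation": 0.180,
    "renal_disease": 0.143,
    "copd_asthma": 0.124,
    "non_metastatic_solid_tumor": 0.124,
    "hemiplegia": 0.093,
    "parkinsons_disease": 0.037,
    "metastatic_solid_tumor": 0.031,
    "coronary_artery_disease": 0.050,
    "peripheral_vascular_disease": 0.040,
    "osteoporosis": 0.019,
    "glaucoma_narrow_angle": 0.019,
    "peptic_ulcer": 0.100,
    "delirium": 0.050,
    "respiratory_failure": 0.120,
    "cardiac_conduction_abnormality": 0.050,
    "bradycardia": 0.040,
    "psychosis": 0.050,
    "osteopenia": 0.150,
    # male-only conditions
    "benign_prostatic_hypertrophy_male": 0.483,
    "prostatism_urinary_retention_male": 0.400,
    # conditional conditions
    "major_depressive_with_depression": 0.45,
    "proteinuric_with_diabetes": 0.20,
    # judgement qualifiers
    "drug_without_indication": 0.093,
    "end_of_life": 0.10,
    "serum_potassium_not_monitored": 0.50,
    "behavioural_mild_with_dementia": 0.30,
    "prostatectomy_necessary_with_prostatism": 0.10,
}

PROVENIENCE_PROBS = {
    "hospital": 0.509,
    "residence": 0.435,
    "nursing_home": 0.031,
    "primary_care": 0.013,
    "other": 0.012,
}
DISCHARGE_PROBS = {
    "residence": 0.379,
    "death": 0.174,
    "rncci": 0.174,
    "social": 0.124,
    "nursing_home": 0.106,
    "other": 0.037,
    "emergency": 0.006,
}

# Neutral filler drugs used to pad the list up to the drawn medication count.
# None of these codes matches any drug class of the default catalog.
FILLER_CODES = (
    "N02BE01",  # paracetamol
    "H03AA01",  # levothyroxine
    "A10BA02",  # metformin
    "M04AA01",  # allopurinol
    "B03BA01",  # cyanocobalamin
    "A11DA01",  # thiamine
    "A02AA04",  # magnesium antacid
    "S01XA20",  # artificial tears
    "D01BA02",  # terbinafine
    "M02AA15",  # topical diclofenac
    "N07CA01",  # betahistine
    "C04AD03",  # pentoxifylline
    "A05AA02",  # ursodeoxycholic acid
    "R05CB01",  # acetylcysteine
    "C05CA05",  # hidrosmin
    "A12CB01",  # zinc sulfate
    "A11GA01",  # ascorbic acid
    "N06BX03",  # piracetam
    "C01EB10",  # adenosine-type cardiac
    "V03AB15",  # naloxone-type antidote
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    ``marginals`` are prevalence targets of directly sampled covariates;
    ``med_count_*`` parameterize the negative-binomial regular-medication
    count (mean 8.84, sd ~3.3, truncated to [0, 25], median 9); the age model
    is normal (mean 81.6, sd 7.4) truncated at 65.
    """

    n: int = 161
    seed: int = 0
    marginals: dict[str, float] = field(default_factory=dict)
    age_mean: float = 81.6
    age_sd: float = 7.4
    age_min: int = 65
    med_count_mean: float = 8.84
    med_count_sd: float = 3.32
    med_count_max: int = 25
    los_median: float = 93.0
    los_sigma: float = 0.95  # log-scale spread of length of stay

    def resolved_marginals(self) -> dict[str, float]:
        merged = dict(DEFAULT_MARGINALS)
        unknown = set(self.marginals) - set(merged)
        if unknown:
            raise ConfigError(f"unknown marginal(s): {sorted(unknown)}")
        merged.update(self.marginals)
        return merged

    def validate(self) -> dict[str, float]:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        marg = self.resolved_marginals()
        for name, p in marg.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"marginal {name!r} = {p} outside [0, 1]")
        if marg["polypharmacy"] > 0 and self.med_count_max < 5:
            raise ConfigError(
                "infeasible config: nonzero polypharmacy target with "
                f"med_count_max = {self.med_count_max} (< 5 drugs)"
            )
        if self.med_count_sd**2 <= self.med_count_mean:
            raise ConfigError("medication count model needs variance > mean")
        return marg


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(0, index)))
    )


def _categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    names = list(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    return names[int(rng.choice(len(names), p=p / p.sum()))]


def _nbinom_count(rng: np.random.Generator, cfg: CohortConfig) -> int:
    mu, var = cfg.med_count_mean, cfg.med_count_sd**2
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    while True:
        k = int(rng.negative_binomial(r, p))
        if k <= cfg.med_count_max:
            return k


def _chronic_duration(rng: np.random.Generator) -> int:
    return int(rng.integers(30, 366))


def _doses(rng: np.random.Generator) -> int:
    return int(rng.choice([1, 2, 3], p=[0.85, 0.12, 0.03]))


def _generate_patient(index: int, cfg: CohortConfig, marg: dict[str, float]) -> PatientRecord:
    rng = _patient_rng(cfg.seed, index)
    bern = lambda p: bool(rng.random() < p)

    female = bern(marg["female"])
    age = cfg.age_min - 1
    while age < cfg.age_min:
        age = int(round(rng.normal(cfg.age_mean, cfg.age_sd)))
    provenience = _categorical(rng, PROVENIENCE_PROBS)
    discharge = _categorical(rng, DISCHARGE_PROBS)
    los = max(1, int(round(cfg.los_median * np.exp(rng.normal(0.0, cfg.los_sigma)))))

    # ---- diagnoses -------------------------------------------------------
    simple_conditions = [
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
        "renal_disease",
        "copd_asthma",
        "non_metastatic_solid_tumor",
        "hemiplegia",
        "parkinsons_disease",
        "metastatic_solid_tumor",
        "coronary_artery_disease",
        "peripheral_vascular_disease",
        "osteoporosis",
        "glaucoma_narrow_angle",
        "peptic_ulcer",
        "delirium",
        "respiratory_failure",
        "cardiac_conduction_abnormality",
        "bradycardia",
        "psychosis",
        "osteopenia",
    ]
    conditions = {c for c in simple_conditions if bern(marg[c])}
    if not female:
        if bern(marg["benign_prostatic_hypertrophy_male"]):
            conditions.add("benign_prostatic_hypertrophy")
        if bern(marg["prostatism_urinary_retention_male"]):
            conditions.add("prostatism_urinary_retention")
    if "depression" in conditions and bern(marg["major_depressive_with_depression"]):
        conditions.add("major_depressive_symptoms")
    if "diabetes_mellitus" in conditions and bern(marg["proteinuric_with_diabetes"]):
        conditions.add("proteinuric_diabetic_renal_disease")

    # ---- qualifier flags -------------------------------------------------
    qualifiers: set[str] = set()
    if bern(marg["drug_without_indication"]):
        qualifiers.add("drug_without_indication")
    if bern(marg["end_of_life"]):
        qualifiers.add("end_of_life")
    if bern(marg["serum_potassium_not_monitored"]):
        qualifiers.add("serum_potassium_not_monitored")
    if "dementia" in conditions and bern(marg["behavioural_mild_with_dementia"]):
        qualifiers.add("behavioural_symptoms_mild")
    if "prostatism_urinary_retention" in conditions and bern(
        marg["prostatectomy_necessary_with_prostatism"]
    ):
        qualifiers.add("prostatectomy_considered_necessary")

    # ---- medications -----------------------------------------------------
    has = lambda c: c in conditions
    meds: list[MedicationEntry] = []

    def add(code: str, duration: int | None = None, combo: bool = False) -> None:
        meds.append(
            MedicationEntry(
                drug_code=code,
                is_regular=True,
                duration_days=_chronic_duration(rng) if duration is None else duration,
                daily_doses=_doses(rng),
                is_fixed_combination=combo,
            )
        )

    took_benzo = bern(0.55)
    if took_benzo:
        dur = int(rng.integers(28, 366)) if bern(0.95) else int(rng.integers(7, 28))
        add("N05BA06" if bern(0.5) else "N05CD06", duration=dur)
        if bern(0.15):  # duplicate class prescription
            add("N05BA01", duration=int(rng.integers(28, 366)))
    if bern(0.06):
        add("N05CF02")
    p_neuro = min(0.95, 0.12 + 0.35 * has("dementia") + 0.40 * has("psychosis"))
    if bern(p_neuro):
        add("N05AH04" if bern(0.6) else "N05AX08")
    took_tca = bern(0.06 + 0.22 * has("depression"))
    if took_tca:
        add("N06AA09")
        if bern(0.5):
            qualifiers.add("tca_first_line")
    if bern(0.55 if has("depression") else 0.05):
        add("N06AB05" if bern(0.5) else "N06AX11")
    if has("dementia") and bern(0.30):
        add("N06DA02")
    vascular = has("coronary_artery_disease") or has("cerebrovascular_disease") or has(
        "peripheral_vascular_disease"
    )
    if bern(0.65 if vascular else 0.15):
        add("B01AC06" if bern(0.8) else "B01AC04")
    if bern(0.85 if has("atrial_fibrillation") else 0.02):
        add("B01AA03" if bern(0.5) else "B01AF01")
    if bern(0.50 if vascular else 0.20):
        add("C10AA01" if bern(0.5) else "C10AA05")
    if bern(0.35 * has("congestive_heart_failure") + 0.40 * has("hypertension")):
        add("C09AA02" if bern(0.6) else "C09AA05")
    if has("hypertension") and bern(0.15):
        add("C09CA01")
    if bern(0.40 * has("congestive_heart_failure") + 0.20 * has("hypertension")):
        add("C07AB07" if bern(0.6) else "C07AB02")
    if bern(0.60 * has("congestive_heart_failure") + 0.15 * has("hypertension")):
        add("C03CA01")
    if has("congestive_heart_failure") and bern(0.30):
        add("C03DA01")
    if has("hypertension") and bern(0.20):
        add("C03AA03")
    if has("hypertension") and bern(0.25):
        add("C08CA01")
    took_ppi = bern(0.80 if has("peptic_ulcer") else 0.40)
    if took_ppi:
        add("A02BC01", duration=int(rng.integers(30, 366)))
        if bern(0.5):
            qualifiers.add("ppi_full_dose")
    took_opioid = bern(0.12)
    if took_opioid:
        if bern(0.4):
            add("N02AB03" if bern(0.5) else "N02AE01")
            if bern(0.2):
                add("N02AA01")
        else:
            add("N02AX02")
    if bern(0.40 if took_opioid else (0.5 if has("constipation") else 0.10)):
        add("A06AB06" if bern(0.5) else "A06AD11")
    if bern(0.25):
        add("A11CC05")
    if bern(0.10):
        add("A12AX", combo=True)  # fixed calcium + colecalciferol combination
    if has("prostatism_urinary_retention"):
        if bern(0.45):
            add("G04CA02")
        if bern(0.25):
            add("G04CB01")
    if has("copd_asthma") and bern(0.50):
        add("R03AC02" if bern(0.5) else "R03BB04")
    if has("diabetes_mellitus") and bern(0.60):
        add("A10BB01" if bern(0.3) else "A10AB01")
    if bern(0.05):
        add("R06AB04")  # first-generation antihistamine
    if bern(0.03):
        add("B01AC05")  # ticlopidine
    if has("urinary_incontinence") and bern(0.30):
        add("G04BD04")  # oxybutynin

    target = _nbinom_count(rng, cfg)
    filler = list(FILLER_CODES)
    rng.shuffle(filler)
    while len(meds) < target and filler:
        add(filler.pop())
    if len(meds) > cfg.med_count_max:
        del meds[cfg.med_count_max :]

    for _ in range(int(rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1]))):  # as-needed
        meds.append(
            MedicationEntry(
                drug_code="N02BE01",
                is_regular=False,
                duration_days=int(rng.integers(1, 30)),
                daily_doses=1,
            )
        )

    return PatientRecord(
        id=f"P{index:05d}",
        age_years=age,
        gender="female" if female else "male",
        provenience=provenience,
        discharge=discharge,
        length_of_stay_days=los,
        diagnoses=[DiagnosisEntry(c) for c in sorted(conditions)],
        medications=meds,
        enteral_nutrition=bern(marg["enteral_nutrition"]),
        housebound_or_falls=bern(marg["housebound_or_falls"]),
        fall_risk_medium_high=bern(marg["fall_risk_medium_high"]),
        dependency_adl=bern(marg["dependency_adl"]),
        malnutrition=bern(marg["malnutrition"]),
        obesity=bern(marg["obesity"]),
        pressure_ulcers=bern(marg["pressure_ulcers"]),
        recent_fracture=bern(marg["recent_fracture"]),
        qualifiers=frozenset(qualifiers),
    )


def generate(config: CohortConfig) -> list[PatientRecord]:
    """Generate a reproducible synthetic cohort under the given configuration."""
    marg = config.validate()
    return [_generate_patient(i, config, marg) for i in range(config.n)]


def plant_outcome(
    cohort: list[PatientRecord],
    coefficients: dict[str, float],
    seed: int,
) -> np.ndarray:
    """Draw a binary outcome from logit(p) = b0 + sum(b_i * x_i).

    ``coefficients`` maps covariate names (columns of
    :func:`~stoppstart.cohort.covariate_frame`) to log-odds effects; the key
    ``"intercept"`` holds b0.  Used to build parameter-recovery fixtures.
    """
    frame = covariate_frame(cohort)
    eta = np.full(len(cohort), float(coefficients.get("intercept", 0.0)))
    for name, beta in coefficients.items():
        if name == "intercept":
            continue
        if name not in frame.columns:
            raise ConfigError(f"unknown covariate in planted effects: {name!r}")
        eta += float(beta) * frame[name].to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(seed)
    return (rng.random(len(cohort)) < p).astype(int)
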