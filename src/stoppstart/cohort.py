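"""Patient-level domain model for a post-acute / long-term-care cohort.

Holds the record types every other module consumes (medications, diagnoses,
patients), derivation of the age-adjusted Charlson comorbidity index and the
geriatric-syndrome profile, and delimited-text cohort I/O.

Counting conventions
--------------------
* Only medications taken on a regular basis count; as-needed (SOS) entries
  are excluded from all counts and screening rules.
* A fixed-dose combination is a single medication entry and counts as one.
* Polypharmacy means >= 5 regular drugs per day; multimorbidity means >= 2
  comorbidities from the tabulated comorbidity list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from .vocab import CHARLSON_WEIGHTS, COMORBIDITY_LIST, CONDITIONS, QUALIFIERS

MIN_AGE = 65  # inclusion criterion: patients aged >= 65 years

GENDERS = ("male", "female")
PROVENIENCES = ("hospital", "residence", "nursing_home", "primary_care", "other")
DISCHARGES = (
    "residence",
    "death",
    "rncci",
    "social",
    "nursing_home",
    "other",
    "emergency",
)

POLYPHARMACY_THRESHOLD = 5
MULTIMORBID_THRESHOLD = 2


class CohortValidationError(ValueError):
    """Raised when a record violates the cohort schema or inclusion criteria."""


@dataclass(frozen=True)
class MedicationEntry:
    """One medication on the current therapeutic list.

    ``drug_code`` is an ATC-style class code (e.g. ``"N05BA01"``); rules match
    on code prefixes.  ``is_regular`` distinguishes scheduled intake from
    as-needed (SOS) use; ``is_fixed_combination`` marks fixed-dose combination
    products, which count as one medication.
    """

    drug_code: str
    is_regular: bool = True
    duration_days: int = 0
    daily_doses: int = 1
    is_fixed_combination: bool = False

    def __post_init__(self) -> None:
        if not self.drug_code or not self.drug_code[0].isalpha():
            raise CohortValidationError(f"malformed drug code: {self.drug_code!r}")
        if self.duration_days < 0:
            raise CohortValidationError("duration_days must be non-negative")
        if self.daily_doses < 1:
            raise CohortValidationError("daily_doses must be positive")


@dataclass(frozen=True)
class DiagnosisEntry:
    """A coded diagnosis, optionally with qualifier flags (e.g. severity)."""

    condition: str
    qualifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise CohortValidationError(f"unknown condition label: {self.condition!r}")


@dataclass
class PatientRecord:
    """One admitted patient: demographics, diagnoses, medications, syndromes.

    The age >= 65 inclusion criterion is enforced when cohorts are read from
    disk or generated, not at construction time, so that derivation helpers
    can be exercised on arbitrary ages.
    """

    id: str
    age_years: int
    gender: str
    provenience: str = "hospital"
    discharge: str = "residence"
    length_of_stay_days: int = 1
    diagnoses: list[DiagnosisEntry] = field(default_factory=list)
    medications: list[MedicationEntry] = field(default_factory=list)
    enteral_nutrition: bool = False
    housebound_or_falls: bool = False
    fall_risk_medium_high: bool = False
    dependency_adl: bool = False
    malnutrition: bool = False
    obesity: bool = False
    pressure_ulcers: bool = False
    recent_fracture: bool = False
    qualifiers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise CohortValidationError(f"unknown gender: {self.gender!r}")
        if self.provenience not in PROVENIENCES:
            raise CohortValidationError(f"unknown provenience: {self.provenience!r}")
        if self.discharge not in DISCHARGES:
            raise CohortValidationError(f"unknown discharge: {self.discharge!r}")
        if self.length_of_stay_days < 1:
            raise CohortValidationError("length_of_stay_days must be positive")
        seen: set[str] = set()
        for dx in self.diagnoses:
            if dx.condition in seen:
                raise CohortValidationError(
                    f"condition appears more than once: {dx.condition!r}"
                )
            seen.add(dx.condition)
        unknown = set(self.qualifiers) - QUALIFIERS
        if unknown:
            raise CohortValidationError(f"unknown qualifier flags: {sorted(unknown)}")

    # -- convenience views -------------------------------------------------
    @property
    def conditions(self) -> frozenset[str]:
        return frozenset(dx.condition for dx in self.diagnoses)

    @property
    def all_flags(self) -> frozenset[str]:
        """Patient qualifiers plus qualifiers attached to any diagnosis."""
        flags = set(self.qualifiers)
        for dx in self.diagnoses:
            flags.update(dx.qualifiers)
        return frozenset(flags)

    @property
    def regular_medications(self) -> list[MedicationEntry]:
        return [m for m in self.medications if m.is_regular]

    def has_condition(self, label: str) -> bool:
        if label not in CONDITIONS:
            raise CohortValidationError(f"unknown condition label: {label!r}")
        return label in self.conditions


@dataclass(frozen=True)
class GeriatricProfile:
    """Derived covariates: medication burden, comorbidity and Charlson index."""

    n_medications: int
    n_daily_doses: int
    polypharmacy: bool
    n_comorbid: int
    multimorbid: bool
    cci: int
    cci_ge4: bool
    cci_ge6: bool


def charlson_age_points(age_years: int) -> int:
    """One point per completed decade from 50-59 upward, capped at 4."""
    if age_years < 50:
        return 0
    return min(4, (age_years - 40) // 10)


def charlson_score(age_years: int, conditions: frozenset[str] | set[str]) -> int:
    """Age-adjusted Charlson comorbidity index over the controlled vocabulary.

    The most severe variant of a graded condition is scored once: metastatic
    disease supersedes a localized tumour, and diabetes with renal end-organ
    damage supersedes uncomplicated diabetes.
    """
    unknown = set(conditions) - CONDITIONS
    if unknown:
        raise CohortValidationError(
            f"unknown condition label: {sorted(unknown)[0]!r}"
        )
    scored = set(conditions)
    if "metastatic_solid_tumor" in scored:
        scored.discard("non_metastatic_solid_tumor")
    if "proteinuric_diabetic_renal_disease" in scored:
        scored.discard("diabetes_mellitus")
    weight_sum = sum(CHARLSON_WEIGHTS.get(c, 0) for c in scored)
    return weight_sum + charlson_age_points(age_years)


def compute_cci(patient: PatientRecord) -> int:
    """Age-adjusted Charlson comorbidity index of a patient record."""
    return charlson_score(patient.age_years, patient.conditions)


def derive_profile(patient: PatientRecord) -> GeriatricProfile:
    """Derive the medication-burden and comorbidity covariates of a patient."""
    regular = patient.regular_medications
    n_med = len(regular)
    n_doses = sum(m.daily_doses for m in regular)
    n_comorbid = sum(1 for c in COMORBIDITY_LIST if c in patient.conditions)
    cci = compute_cci(patient)
    return GeriatricProfile(
        n_medications=n_med,
        n_daily_doses=n_doses,
        polypharmacy=n_med >= POLYPHARMACY_THRESHOLD,
        n_comorbid=n_comorbid,
        multimorbid=n_comorbid >= MULTIMORBID_THRESHOLD,
        cci=cci,
        cci_ge4=cci >= 4,
        cci_ge6=cci >= 6,
    )


# ---------------------------------------------------------------------------
# Delimited-text cohort I/O
# ---------------------------------------------------------------------------

_BOOL_FIELDS = (
    "enteral_nutrition",
    "housebound_or_falls",
    "fall_risk_medium_high",
    "dependency_adl",
    "malnutrition",
    "obesity",
    "pressure_ulcers",
    "recent_fracture",
)

COHORT_COLUMNS = (
    "id",
    "age_years",
    "gender",
    "provenience",
    "discharge",
    "length_of_stay_days",
    *_BOOL_FIELDS,
    "qualifiers",
    "diagnoses",
    "medications",
)


def _format_medication(m: MedicationEntry) -> str:
    flags = ("R" if m.is_regular else "S") + ("C" if m.is_fixed_combination else "")
    return f"{m.drug_code}:{m.duration_days}:{m.daily_doses}:{flags}"


def _parse_medication(text: str) -> MedicationEntry:
    parts = text.split(":")
    if len(parts) != 4:
        raise CohortValidationError(f"malformed medication field: {text!r}")
    code, duration, doses, flags = parts
    if not set(flags) <= {"R", "S", "C"} or ("R" in flags) == ("S" in flags):
        raise CohortValidationError(f"malformed medication flags: {text!r}")
    return MedicationEntry(
        drug_code=code,
        is_regular="R" in flags,
        duration_days=int(duration),
        daily_doses=int(doses),
        is_fixed_combination="C" in flags,
    )


def _format_diagnosis(d: DiagnosisEntry) -> str:
    if d.qualifiers:
        return d.condition + "|" + "|".join(d.qualifiers)
    return d.condition


def _parse_diagnosis(text: str) -> DiagnosisEntry:
    parts = text.split("|")
    return DiagnosisEntry(condition=parts[0], qualifiers=tuple(parts[1:]))


def _record_to_row(p: PatientRecord) -> dict:
    row: dict = {
        "id": p.id,
        "age_years": p.age_years,
        "gender": p.gender,
        "provenience": p.provenience,
        "discharge": p.discharge,
        "length_of_stay_days": p.length_of_stay_days,
    }
    for f in _BOOL_FIELDS:
        row[f] = int(getattr(p, f))
    row["qualifiers"] = ";".join(sorted(p.qualifiers))
    row["diagnoses"] = ";".join(_format_diagnosis(d) for d in p.diagnoses)
    row["medications"] = ";".join(_format_medication(m) for m in p.medications)
    return row


def _row_to_record(row: dict, rownum: int, enforce_age: bool = True) -> PatientRecord:
    try:
        age = int(row["age_years"])
        if enforce_age and age < MIN_AGE:
            raise CohortValidationError(
                f"age {age} violates the inclusion criterion (patients aged >= {MIN_AGE})"
            )
        meds = [
            _parse_medication(t) for t in str(row["medications"]).split(";") if t
        ]
        dxs = [_parse_diagnosis(t) for t in str(row["diagnoses"]).split(";") if t]
        quals = frozenset(t for t in str(row["qualifiers"]).split(";") if t)
        return PatientRecord(
            id=str(row["id"]),
            age_years=age,
            gender=str(row["gender"]),
            provenience=str(row["provenience"]),
            discharge=str(row["discharge"]),
            length_of_stay_days=int(row["length_of_stay_days"]),
            diagnoses=dxs,
            medications=meds,
            qualifiers=quals,
            **{f: bool(int(row[f])) for f in _BOOL_FIELDS},
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"row {rownum}: {exc}") from None
    except (KeyError, ValueError) as exc:
        raise CohortValidationError(f"row {rownum}: malformed value ({exc})") from None


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write a cohort as UTF-8 comma-separated text, one row per patient."""
    df = pd.DataFrame([_record_to_row(p) for p in records], columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> list[PatientRecord]:
    """Read a delimited cohort file; rejects bad rows naming the row number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"missing mandatory column(s): {sorted(missing)}")
    return [
        _row_to_record(row, rownum=i + 2)  # +2: header line plus 1-based rows
        for i, row in enumerate(df.to_dict(orient="records"))
    ]


def covariate_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Numeric covariate matrix (one row per patient) for association models.

    Binary covariates are 0/1; counts and ages are left on their natural
    per-unit scale.  Column names are the covariate names accepted by outcome
    planting and model fitting.
    """
    rows = []
    for p in cohort:
        prof = derive_profile(p)
        row = {
            "female": int(p.gender == "female"),
            "age_years": p.age_years,
            "hospital_provenience": int(p.provenience == "hospital"),
            "length_of_stay_days": p.length_of_stay_days,
            "n_medications": prof.n_medications,
            "n_daily_doses": prof.n_daily_doses,
            "n_comorbid": prof.n_comorbid,
            "multimorbid": int(prof.multimorbid),
            "cci": prof.cci,
            "cci_ge4": int(prof.cci_ge4),
            "cci_ge6": int(prof.cci_ge6),
            "polypharmacy": int(prof.polypharmacy),
        }
        for f in _BOOL_FIELDS:
            row[f] = int(getattr(p, f))
        for c in COMORBIDITY_LIST:
            row[c] = int(c in p.conditions)
        rows.append(row)
    return pd.DataFrame(rows, index=[p.id for p in cohort])


def write_cohort_json(records: list[PatientRecord], path) -> None:
    """Structured one-record-per-patient serialization with identical names."""
    payload = []
    for p in records:
        d = asdict(p)
        d["qualifiers"] = sorted(p.qualifiers)
        payload.append(d)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_cohort_json(path) -> list[PatientRecord]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    records = []
    for i, d in enumerate(payload):
        if int(d["age_years"]) < MIN_AGE:
            raise CohortValidationError(
                f"record {i}: age {d['age_years']} violates the inclusion "
                f"criterion (patients aged >= {MIN_AGE})"
            )
        records.append(
            PatientRecord(
                id=d["id"],
                age_years=int(d["age_years"]),
                gender=d["gender"],
                provenience=d["provenience"],
                discharge=d["discharge"],
                length_of_stay_days=int(d["length_of_stay_days"]),
                diagnoses=[DiagnosisEntry(x["condition"], tuple(x["qualifiers"])) for x in d["diagnoses"]],
                medications=[MedicationEntry(**m) for m in d["medications"]],
                qualifiers=frozenset(d["qualifiers"]),
                **{f: bool(d[f]) for f in _BOOL_FIELDS},
            )
        )
    return records
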