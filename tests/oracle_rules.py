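"""Independent brute-force screening oracle.

Re-states every shipped criterion as a direct Python predicate over the
patient record, reading the rule texts rather than the catalog file, and
sharing no evaluation code with the package engine.  Used to cross-check
``evaluate_patient`` on small cohorts.
"""

from collections import Counter


def _view(patient):
    meds = [m for m in patient.medications if m.is_regular]
    codes = [m.drug_code for m in meds]
    conds = {d.condition for d in patient.diagnoses}
    flags = set(patient.qualifiers)
    for d in patient.diagnoses:
        flags.update(d.qualifiers)
    return meds, codes, conds, flags


def _any_code(codes, *prefixes):
    return any(c.startswith(prefixes) for c in codes)


_ANTICHOL = ("N06AA", "N04AA", "G04BD", "A03BA", "A03BB", "R06AB", "R06AD", "N05BB")
_BENZO = ("N05BA", "N05CD")
_CONSTIPATING = ("N02A", "N06AA", "N04AA", "G04BD", "A03BA", "A03BB", "C08DA", "B03AA")


def _neuroleptic(codes):
    return any(c.startswith("N05A") and not c.startswith("N05AN") for c in codes)


def oracle_stopp(patient):
    meds, codes, conds, flags = _view(patient)
    fired = set()
    if "drug_without_indication" in flags:
        fired.add("STOPP-A1")
    if any(n >= 2 for n in Counter(c[:5] for c in codes).values()):
        fired.add("STOPP-A3")
    if (
        _any_code(codes, "C03C")
        and "hypertension" in conds
        and "urinary_incontinence" in conds
    ):
        fired.add("STOPP-B9")
    if (
        _any_code(codes, "C03DA")
        and _any_code(codes, "C03DB", "C09A", "C09B", "C09C", "C09D")
        and "serum_potassium_not_monitored" in flags
    ):
        fired.add("STOPP-B12")
    if _any_code(codes, "B01AC05"):
        fired.add("STOPP-C7")
    if _any_code(codes, "N06AA") and conds & {
        "dementia",
        "glaucoma_narrow_angle",
        "cardiac_conduction_abnormality",
        "prostatism_urinary_retention",
    }:
        fired.add("STOPP-D1")
    if _any_code(codes, "N06AA") and "tca_first_line" in flags:
        fired.add("STOPP-D2")
    if any(m.drug_code.startswith(_BENZO) and m.duration_days >= 28 for m in meds):
        fired.add("STOPP-D5")
    if _any_code(codes, *_ANTICHOL) and conds & {"delirium", "dementia"}:
        fired.add("STOPP-D7")
    if (
        _neuroleptic(codes)
        and "dementia" in conds
        and "behavioural_symptoms_mild" in flags
    ):
        fired.add("STOPP-D9")
    if _any_code(codes, "N06DA") and (
        conds & {"bradycardia", "cardiac_conduction_abnormality"}
        or _any_code(codes, "C07", "C08DA", "C08DB", "C01AA")
    ):
        fired.add("STOPP-D11")
    if _any_code(codes, "R06AA", "R06AB", "R06AD"):
        fired.add("STOPP-D14")
    if (
        any(m.drug_code.startswith("A02BC") and m.duration_days >= 57 for m in meds)
        and "peptic_ulcer" in conds
        and "ppi_full_dose" in flags
    ):
        fired.add("STOPP-F2")
    if _any_code(codes, *_CONSTIPATING) and "constipation" in conds:
        fired.add("STOPP-F3")
    if _any_code(codes, *_BENZO) and "respiratory_failure" in conds:
        fired.add("STOPP-G5")
    if _any_code(codes, *_BENZO):
        fired.add("STOPP-K1")
    if _neuroleptic(codes):
        fired.add("STOPP-K2")
    if _any_code(codes, "N05CF"):
        fired.add("STOPP-K4")
    if _any_code(codes, "N02A") and not _any_code(codes, "A06A"):
        fired.add("STOPP-L2")
    if _any_code(codes, "N02AB03", "N02AE01") and not _any_code(
        codes, "N02AA01", "N02AX02", "N02AJ"
    ):
        fired.add("STOPP-L3")
    if len({c for c in codes if c.startswith(_ANTICHOL)}) >= 2:
        fired.add("STOPP-N1")
    return fired


def oracle_start(patient):
    meds, codes, conds, flags = _view(patient)
    fired = set()
    vascular = bool(
        conds
        & {
            "coronary_artery_disease",
            "cerebrovascular_disease",
            "peripheral_vascular_disease",
        }
    )
    if "atrial_fibrillation" in conds and not _any_code(codes, "B01AA", "B01AE", "B01AF"):
        fired.add("START-A1")
    if vascular and not _any_code(codes, "B01AC"):
        fired.add("START-A3")
    if (
        vascular
        and not _any_code(codes, "C10AA")
        and not ("end_of_life" in flags or patient.age_years > 85)
    ):
        fired.add("START-A5")
    if (
        conds & {"congestive_heart_failure", "coronary_artery_disease"}
        and not _any_code(codes, "C09A", "C09B")
    ):
        fired.add("START-A6")
    if "congestive_heart_failure" in conds and not _any_code(
        codes, "C07AB02", "C07AB07", "C07AB12", "C07AG02"
    ):
        fired.add("START-A8")
    if "copd_asthma" in conds and not _any_code(
        codes, "R03AC", "R03AK", "R03AL", "R03BB"
    ):
        fired.add("START-B1")
    if "major_depressive_symptoms" in conds and not _any_code(codes, "N06AB", "N06AX"):
        fired.add("START-C2")
    has_combo = _any_code(codes, "A12AX")
    if ("osteoporosis" in conds or patient.recent_fracture) and not (
        has_combo or (_any_code(codes, "A11CC") and _any_code(codes, "A12AA"))
    ):
        fired.add("START-E3")
    if (
        (patient.housebound_or_falls or "osteopenia" in conds)
        and not _any_code(codes, "A11CC")
        and not has_combo
    ):
        fired.add("START-E5")
    if "proteinuric_diabetic_renal_disease" in conds and not _any_code(codes, "C09"):
        fired.add("START-F1")
    prostatism_ok = (
        "prostatism_urinary_retention" in conds
        and "prostatectomy_considered_necessary" not in flags
    )
    if prostatism_ok and not _any_code(codes, "G04CA"):
        fired.add("START-G1")
    if prostatism_ok and not _any_code(codes, "G04CB"):
        fired.add("START-G2")
    if _any_code(codes, "N02A") and not _any_code(codes, "A06A"):
        fired.add("START-H2")
    return fired
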