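"""Unadjusted 2x2 odds ratios with Woolf confidence intervals and Wald tests.

The exposure-outcome orientation follows the screening tables: the outcome is
"has at least one PIM" (or PPO), ``a``/``c`` are exposed patients with and
without the outcome, ``b``/``d`` the reference level.  A zero cell leaves the
odds ratio undefined and the row is rendered as a dash, exactly as clinical
papers print it; an opt-in Haldane-Anscombe +0.5 correction is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import round_half_up
from .cohort import PatientRecord, covariate_frame
from .criteria import ScreeningResult

__all__ = [
    "ContingencyTable2x2",
    "AssociationRow",
    "odds_ratio",
    "woolf_ci",
    "wald_p",
    "associate_all",
    "BINARY_COVARIATES",
    "CONTINUOUS_COVARIATES",
]


class UndefinedOddsRatio(ValueError):
    """A zero cell makes the cross-product odds ratio undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed w/ outcome, b = unexposed w/ outcome,
    c = exposed w/o outcome, d = unexposed w/o outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cell counts must be non-negative integers")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def corrected(self) -> "ContingencyTable2x2":
        """Haldane-Anscombe table with +0.5 in every cell (returned as floats
        packed in a plain tuple-like view used internally)."""
        return _FloatTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class _FloatTable:
    a: float
    b: float
    c: float
    d: float

    has_zero_cell = False


def _require_defined(t) -> None:
    if getattr(t, "has_zero_cell", False):
        raise UndefinedOddsRatio(
            "odds ratio undefined for a table with a zero cell (rendered as '-')"
        )


def odds_ratio(t: ContingencyTable2x2, correction: bool = False) -> float:
    """Cross-product odds ratio (a*d)/(b*c)."""
    if correction and t.has_zero_cell:
        t = t.corrected()
    _require_defined(t)
    return (t.a * t.d) / (t.b * t.c)


def _log_se(t) -> float:
    return math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)


def woolf_ci(
    t: ContingencyTable2x2, level: float = 0.95, correction: bool = False
) -> tuple[float, float]:
    """Woolf (log-scale Wald) confidence interval for the odds ratio."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if correction and t.has_zero_cell:
        t = t.corrected()
    _require_defined(t)
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * _log_se(t)
    return math.exp(log_or - half), math.exp(log_or + half)


def wald_p(t: ContingencyTable2x2, correction: bool = False) -> float:
    """Two-sided Wald p-value for log OR = 0."""
    if correction and t.has_zero_cell:
        t = t.corrected()
    _require_defined(t)
    z = math.log((t.a * t.d) / (t.b * t.c)) / _log_se(t)
    return 2.0 * stats.norm.sf(abs(z))


@dataclass(frozen=True)
class AssociationRow:
    """One covariate-outcome screen: point OR, 95% CI and Wald p.

    ``defined`` is False when a zero cell (binary covariates) or a degenerate
    fit (continuous covariates) leaves the estimate undefined; such rows print
    a dash.  Printed values round half-up to 2 decimals (OR/CI) and 3 (p).
    """

    covariate: str
    outcome: str
    kind: str  # "binary" | "continuous"
    table: ContingencyTable2x2 | None
    or_point: float | None
    ci_low: float | None
    ci_high: float | None
    p_wald: float | None
    defined: bool

    def formatted(self) -> str:
        if not self.defined:
            return f"{self.covariate}\t—\t—"
        return (
            f"{self.covariate}\t"
            f"{round_half_up(self.or_point, 2):.2f} "
            f"({round_half_up(self.ci_low, 2):.2f}; {round_half_up(self.ci_high, 2):.2f})\t"
            f"{round_half_up(self.p_wald, 3):.3f}"
        )


# Covariates screened against each outcome, mirroring the demographic,
# clinical-feature and comorbidity tables (reference level = absence / male).
BINARY_COVARIATES = (
    "female",
    "hospital_provenience",
    "enteral_nutrition",
    "polypharmacy",
    "multimorbid",
    "cci_ge4",
    "cci_ge6",
    "dependency_adl",
    "fall_risk_medium_high",
    "malnutrition",
    "obesity",
    "pressure_ulcers",
    "recent_fracture",
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
CONTINUOUS_COVARIATES = (
    "age_years",
    "length_of_stay_days",
    "n_medications",
    "n_daily_doses",
    "n_comorbid",
    "cci",
)


def table_from_vectors(exposure: np.ndarray, outcome: np.ndarray) -> ContingencyTable2x2:
    exposure = np.asarray(exposure, dtype=bool)
    outcome = np.asarray(outcome, dtype=bool)
    return ContingencyTable2x2(
        a=int((exposure & outcome).sum()),
        b=int((~exposure & outcome).sum()),
        c=int((exposure & ~outcome).sum()),
        d=int((~exposure & ~outcome).sum()),
    )


def _binary_row(name: str, outcome_name: str, t: ContingencyTable2x2) -> AssociationRow:
    if t.has_zero_cell:
        return AssociationRow(name, outcome_name, "binary", t, None, None, None, None, False)
    lo, hi = woolf_ci(t)
    return AssociationRow(
        name, outcome_name, "binary", t, odds_ratio(t), lo, hi, wald_p(t), True
    )


def _continuous_row(name: str, outcome_name: str, x: np.ndarray, y: np.ndarray) -> AssociationRow:
    # per-unit OR from a single-covariate logistic fit
    from .logistic import LogisticError, fit_logistic

    try:
        fit = fit_logistic(x.reshape(-1, 1), y, names=[name])
    except LogisticError:
        return AssociationRow(name, outcome_name, "continuous", None, None, None, None, None, False)
    if not fit.converged:
        return AssociationRow(name, outcome_name, "continuous", None, None, None, None, None, False)
    return AssociationRow(
        name,
        outcome_name,
        "continuous",
        None,
        float(fit.odds_ratios[1]),
        float(fit.or_ci_low[1]),
        float(fit.or_ci_high[1]),
        float(fit.p_values[1]),
        True,
    )


def associate_all(
    cohort: list[PatientRecord],
    results: list[ScreeningResult],
    covariates: tuple[str, ...] | None = None,
    outcomes: tuple[str, ...] = ("pim", "ppo"),
) -> list[AssociationRow]:
    """Screen every covariate against each outcome (>=1 PIM / >=1 PPO).

    Binary covariates yield cross-product ORs from the 2x2 table; continuous
    covariates yield per-unit ORs from single-covariate logistic fits.
    """
    by_id = {r.patient_id: r for r in results}
    missing = [p.id for p in cohort if p.id not in by_id]
    if missing:
        raise ValueError(f"screening results missing for patients: {missing[:5]}")
    frame = covariate_frame(cohort)
    outcome_vectors = {}
    if "pim" in outcomes:
        outcome_vectors["pim"] = np.array([by_id[p.id].n_pims > 0 for p in cohort], dtype=int)
    if "ppo" in outcomes:
        outcome_vectors["ppo"] = np.array([by_id[p.id].n_ppos > 0 for p in cohort], dtype=int)

    if covariates is None:
        covariates = BINARY_COVARIATES + CONTINUOUS_COVARIATES
    rows: list[AssociationRow] = []
    for outcome_name, y in outcome_vectors.items():
        for name in covariates:
            if name not in frame.columns:
                raise ValueError(f"covariate absent from cohort frame: {name!r}")
            x = frame[name].to_numpy(dtype=float)
            if name in CONTINUOUS_COVARIATES:
                rows.append(_continuous_row(name, outcome_name, x, y))
            else:
                rows.append(_binary_row(name, outcome_name, table_from_vectors(x > 0, y > 0)))
    return rows
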