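"""Declarative STOPP/START rule catalog and screening engine.

A criterion is a predicate over a :class:`~stoppstart.cohort.PatientRecord`,
built from a small set of primitives (drug-class presence/absence, treatment
duration, diagnosis labels, co-prescription, qualifier flags, age, drug
counts, duplicate classes) combined with ``all`` / ``any`` / ``not``.
Drug classes are ATC code-prefix sets declared in the catalog file, so the
catalog is data, not code.

Counting conventions follow the medication-review literature: one PIM is one
distinct fired STOPP criterion (a single benzodiazepine prescribed for six
weeks fires both the duration rule and the falls-risk rule), and likewise for
PPOs and START criteria.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from ._util import pct, round_half_up
from .cohort import PatientRecord, derive_profile
from .vocab import CONDITIONS, QUALIFIERS

logger = logging.getLogger(__name__)

_PRIMITIVES = {
    "has_drug_class",
    "drug_duration_ge",
    "has_condition",
    "lacks_drug_class",
    "co_prescribed",
    "qualifier",
    "age_gt",
    "drug_count_ge",
    "duplicate_drug_class",
}
_COMBINATORS = {"all", "any", "not"}

# Boolean fields of PatientRecord addressable by the `qualifier` primitive in
# addition to the judgement flags of the qualifier vocabulary.
_RECORD_FLAGS = {
    "enteral_nutrition",
    "housebound_or_falls",
    "fall_risk_medium_high",
    "dependency_adl",
    "malnutrition",
    "obesity",
    "pressure_ulcers",
    "recent_fracture",
}


class CatalogError(ValueError):
    """Raised for a malformed or inconsistent screening catalog."""


@dataclass(frozen=True)
class DrugClass:
    """A named drug class: ATC code prefixes minus optional exclusions."""

    name: str
    prefixes: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def matches(self, code: str) -> bool:
        return code.startswith(tuple(self.prefixes)) and not (
            self.exclude and code.startswith(tuple(self.exclude))
        )


@dataclass(frozen=True)
class CriterionRule:
    """One STOPP or START criterion with a machine-evaluable condition."""

    id: str
    tool: str  # "STOPP" | "START"
    section: str  # section letter
    section_label: str
    description: str
    condition: dict


@dataclass(frozen=True)
class Catalog:
    version: str
    drug_classes: dict[str, DrugClass]
    rules: tuple[CriterionRule, ...]
    section_labels: dict[str, dict[str, str]]

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def rule(self, rule_id: str) -> CriterionRule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(r.id for r in self.rules)


@dataclass(frozen=True)
class ScreeningResult:
    """Fired criterion ids for one patient."""

    patient_id: str
    stopp_ids: frozenset[str]
    start_ids: frozenset[str]

    @property
    def n_pims(self) -> int:
        return len(self.stopp_ids)

    @property
    def n_ppos(self) -> int:
        return len(self.start_ids)


# ---------------------------------------------------------------------------
# Catalog loading and validation
# ---------------------------------------------------------------------------


def _validate_condition(node, classes: dict[str, DrugClass], rule_id: str) -> None:
    if not isinstance(node, dict) or len(node) != 1:
        raise CatalogError(f"rule {rule_id}: condition node must be a single-key map")
    key, value = next(iter(node.items()))
    if key in _COMBINATORS:
        children = value if key != "not" else [value]
        if key != "not" and not isinstance(children, list):
            raise CatalogError(f"rule {rule_id}: '{key}' expects a list")
        for child in children:
            _validate_condition(child, classes, rule_id)
        return
    if key not in _PRIMITIVES:
        raise CatalogError(f"rule {rule_id}: unknown predicate {key!r}")
    if key in {"has_drug_class", "lacks_drug_class"}:
        names = [value]
    elif key in {"drug_duration_ge", "drug_count_ge"}:
        names = [value["class"]]
    elif key == "co_prescribed":
        names = [value["class_a"], value["class_b"]]
    elif key == "has_condition":
        if value not in CONDITIONS:
            raise CatalogError(f"rule {rule_id}: unknown condition label {value!r}")
        return
    elif key == "qualifier":
        if value not in QUALIFIERS | _RECORD_FLAGS:
            raise CatalogError(f"rule {rule_id}: unknown qualifier flag {value!r}")
        return
    else:  # age_gt, duplicate_drug_class
        return
    for name in names:
        if name not in classes:
            raise CatalogError(f"rule {rule_id}: unknown drug class {name!r}")


def _contains_omission(node: dict) -> bool:
    key, value = next(iter(node.items()))
    if key == "lacks_drug_class":
        return True
    if key == "not":
        return True  # negation of a presence predicate is an omission clause
    if key in {"all", "any"}:
        return any(_contains_omission(child) for child in value)
    return False


def _parse_catalog(raw: dict) -> Catalog:
    classes = {}
    for name, spec in (raw.get("drug_classes") or {}).items():
        classes[name] = DrugClass(
            name=name,
            prefixes=tuple(spec["prefixes"]),
            exclude=tuple(spec.get("exclude", ())),
        )
    sections = {
        tool: dict(labels) for tool, labels in (raw.get("sections") or {}).items()
    }
    rules: list[CriterionRule] = []
    seen: set[str] = set()
    for spec in raw.get("rules") or []:
        rid = spec["id"]
        if rid in seen:
            raise CatalogError(f"duplicate criterion id: {rid!r}")
        seen.add(rid)
        tool = spec["tool"]
        if tool not in ("STOPP", "START"):
            raise CatalogError(f"rule {rid}: tool must be STOPP or START")
        _validate_condition(spec["condition"], classes, rid)
        if tool == "START" and not _contains_omission(spec["condition"]):
            raise CatalogError(
                f"rule {rid}: START rules must contain an omission predicate"
            )
        rules.append(
            CriterionRule(
                id=rid,
                tool=tool,
                section=spec["section"],
                section_label=sections.get(tool, {}).get(spec["section"], spec["section"]),
                description=" ".join(str(spec["description"]).split()),
                condition=spec["condition"],
            )
        )
    if not rules:
        logger.warning("screening catalog contains no rules")
    return Catalog(
        version=str(raw.get("version", "0")),
        drug_classes=classes,
        rules=tuple(rules),
        section_labels=sections,
    )


def load_catalog(path=None) -> Catalog:
    """Load a screening catalog; ``path=None`` loads the packaged default."""
    if path is None:
        text = resources.files("stoppstart.data").joinpath("catalog.yaml").read_text(
            encoding="utf-8"
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    return _parse_catalog(raw)


def save_catalog(catalog: Catalog, path) -> None:
    """Write a catalog back to its editable file format (round-trips)."""
    raw = {
        "version": catalog.version,
        "drug_classes": {
            c.name: (
                {"prefixes": list(c.prefixes), "exclude": list(c.exclude)}
                if c.exclude
                else {"prefixes": list(c.prefixes)}
            )
            for c in catalog.drug_classes.values()
        },
        "sections": catalog.section_labels,
        "rules": [
            {
                "id": r.id,
                "tool": r.tool,
                "section": r.section,
                "description": r.description,
                "condition": r.condition,
            }
            for r in catalog.rules
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _qualifier_value(patient: PatientRecord, flag: str) -> bool:
    if flag in _RECORD_FLAGS:
        return bool(getattr(patient, flag))
    return flag in patient.all_flags


def _eval(node: dict, patient: PatientRecord, catalog: Catalog) -> bool:
    key, value = next(iter(node.items()))
    meds = patient.regular_medications
    if key == "all":
        return all(_eval(child, patient, catalog) for child in value)
    if key == "any":
        return any(_eval(child, patient, catalog) for child in value)
    if key == "not":
        return not _eval(value, patient, catalog)
    if key == "has_drug_class":
        cls = catalog.drug_classes[value]
        return any(cls.matches(m.drug_code) for m in meds)
    if key == "lacks_drug_class":
        cls = catalog.drug_classes[value]
        return not any(cls.matches(m.drug_code) for m in meds)
    if key == "drug_duration_ge":
        cls = catalog.drug_classes[value["class"]]
        days = int(value["days"])
        return any(cls.matches(m.drug_code) and m.duration_days >= days for m in meds)
    if key == "co_prescribed":
        a = catalog.drug_classes[value["class_a"]]
        b = catalog.drug_classes[value["class_b"]]
        return any(a.matches(m.drug_code) for m in meds) and any(
            b.matches(m.drug_code) for m in meds
        )
    if key == "has_condition":
        return value in patient.conditions
    if key == "qualifier":
        return _qualifier_value(patient, value)
    if key == "age_gt":
        return patient.age_years > int(value)
    if key == "drug_count_ge":
        cls = catalog.drug_classes[value["class"]]
        n_distinct = len({m.drug_code for m in meds if cls.matches(m.drug_code)})
        return n_distinct >= int(value["n"])
    if key == "duplicate_drug_class":
        level = int(value.get("level", 5))
        groups: dict[str, int] = {}
        for m in meds:
            groups[m.drug_code[:level]] = groups.get(m.drug_code[:level], 0) + 1
        return any(count >= 2 for count in groups.values())
    raise CatalogError(f"unknown predicate {key!r}")  # pragma: no cover


def evaluate_patient(patient: PatientRecord, catalog: Catalog) -> ScreeningResult:
    """Screen one patient against every catalog rule.

    A criterion contributes at most once per patient, but one drug may fire
    several criteria.  Predicates whose qualifier flag is absent evaluate to
    not-fired (benefit of the doubt).
    """
    stopp, start = set(), set()
    for rule in catalog.rules:
        if _eval(rule.condition, patient, catalog):
            (stopp if rule.tool == "STOPP" else start).add(rule.id)
    return ScreeningResult(
        patient_id=patient.id, stopp_ids=frozenset(stopp), start_ids=frozenset(start)
    )


def screen_cohort(cohort: list[PatientRecord], catalog: Catalog) -> list[ScreeningResult]:
    return [evaluate_patient(p, catalog) for p in cohort]


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

COUNT_BUCKETS = ("0", "1", "2", "3", "4", "5", "6", ">=7")


@dataclass(frozen=True)
class ToolSummary:
    """Distribution and frequency summary for one screening tool."""

    tool: str
    n_total: int
    distribution: dict[str, int]  # bucket -> patient count
    prevalence_count: int  # patients with >= 1 finding
    prevalence_pct: float
    mean: float
    sd: float
    median: float
    p25: float
    p75: float
    per_criterion: dict[str, tuple[int, float]]  # id -> (n, %)
    per_section: dict[str, tuple[int, float]]  # letter -> (n, %)


@dataclass(frozen=True)
class CohortScreeningSummary:
    n_total: int
    stopp: ToolSummary
    start: ToolSummary
    catalog_version: str = "0"


def _bucket(k: int) -> str:
    return str(k) if k < 7 else ">=7"


def _summarize_tool(
    tool: str,
    results: list[ScreeningResult],
    catalog: Catalog,
    n_total: int,
) -> ToolSummary:
    ids_of = (lambda r: r.stopp_ids) if tool == "STOPP" else (lambda r: r.start_ids)
    counts = np.array([len(ids_of(r)) for r in results], dtype=float)
    distribution = {b: 0 for b in COUNT_BUCKETS}
    for k in counts.astype(int):
        distribution[_bucket(int(k))] += 1
    prevalence_count = int((counts >= 1).sum())
    rules = [r for r in catalog.rules if r.tool == tool]
    per_criterion = {}
    for rule in rules:
        n = sum(1 for r in results if rule.id in ids_of(r))
        per_criterion[rule.id] = (n, pct(n, n_total))
    per_section: dict[str, tuple[int, float]] = {}
    for letter in sorted({r.section for r in rules}):
        members = {r.id for r in rules if r.section == letter}
        n = sum(1 for r in results if ids_of(r) & members)  # once per section
        per_section[letter] = (n, pct(n, n_total))
    if counts.size:
        mean = round_half_up(float(counts.mean()), 1)
        sd = round_half_up(float(counts.std(ddof=1)), 1) if counts.size > 1 else 0.0
        # quartiles by linear interpolation between order statistics
        p25, med, p75 = (float(q) for q in np.percentile(counts, [25, 50, 75]))
    else:
        mean = sd = med = p25 = p75 = 0.0
    return ToolSummary(
        tool=tool,
        n_total=n_total,
        distribution=distribution,
        prevalence_count=prevalence_count,
        prevalence_pct=pct(prevalence_count, n_total),
        mean=mean,
        sd=sd,
        median=med,
        p25=p25,
        p75=p75,
        per_criterion=per_criterion,
        per_section=per_section,
    )


def summarize_cohort(
    results: list[ScreeningResult],
    catalog: Catalog,
    n_total: int | None = None,
) -> CohortScreeningSummary:
    """Tabulate PIM/PPO count distributions, prevalence and rule frequencies."""
    ids = [r.patient_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_id in screening results: {dupes}")
    unknown = set().union(*(r.stopp_ids | r.start_ids for r in results), set())
    unknown -= catalog.ids
    if unknown:
        raise ValueError(f"screening results reference unknown criteria: {sorted(unknown)}")
    if n_total is None:
        n_total = len(results)
    if not math.isfinite(n_total) or n_total < len(results):
        raise ValueError("n_total must be at least the number of results")
    return CohortScreeningSummary(
        n_total=n_total,
        stopp=_summarize_tool("STOPP", results, catalog, n_total),
        start=_summarize_tool("START", results, catalog, n_total),
        catalog_version=catalog.version,
    )
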