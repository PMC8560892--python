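"""Report rendering and pipeline orchestration.

Renders the screening summary (count distribution, prevalence, per-section
and per-criterion frequencies), the association table and the model fits as
plain text / delimited files, and wires the whole analysis together:
simulate or ingest -> screen -> summarize -> associate -> fit.

Every artifact carries a provenance header (seed, catalog version); reruns
with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_up
from .association import AssociationRow, associate_all
from .cohort import covariate_frame, read_cohort, write_cohort
from .criteria import (
    COUNT_BUCKETS,
    Catalog,
    CohortScreeningSummary,
    ScreeningResult,
    ToolSummary,
    load_catalog,
    screen_cohort,
    summarize_cohort,
)
from .logistic import ForwardSelectionResult, diagnostics, forward_select
from .simulate import CohortConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (one seed drives everything)."""

    out_dir: str
    seed: int = 0
    n: int = 161
    cohort_path: str | None = None  # ingest instead of simulate when given
    catalog_path: str | None = None  # packaged default when None
    outcomes: tuple[str, ...] = ("pim", "ppo")
    p_enter: float = 0.05
    p_report: float = 0.1


# ---------------------------------------------------------------------------
# Screening results I/O
# ---------------------------------------------------------------------------


def write_screening(results: list[ScreeningResult], path, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("patient_id,stopp_ids,start_ids,n_pims,n_ppos\n")
        for r in results:
            fh.write(
                f"{r.patient_id},{';'.join(sorted(r.stopp_ids))},"
                f"{';'.join(sorted(r.start_ids))},{r.n_pims},{r.n_ppos}\n"
            )


def read_screening(path) -> list[ScreeningResult]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    results = []
    for _, row in df.iterrows():
        results.append(
            ScreeningResult(
                patient_id=row["patient_id"],
                stopp_ids=frozenset(t for t in row["stopp_ids"].split(";") if t),
                start_ids=frozenset(t for t in row["start_ids"].split(";") if t),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fmt_pct(x: float) -> str:
    return f"{round_half_up(x, 1):.1f}"


def _render_tool_distribution(s: ToolSummary) -> list[str]:
    lines = []
    for bucket in COUNT_BUCKETS:
        n = s.distribution[bucket]
        lines.append(f"  {bucket:>3}  {n} ({_fmt_pct(100.0 * n / s.n_total if s.n_total else 0.0)})")
    lines.append(f"  Total >=1: {s.prevalence_count} ({_fmt_pct(s.prevalence_pct)})")
    lines.append(f"  Mean +/- SD: {s.mean:.1f} +/- {s.sd:.1f}")
    lines.append(f"  Median (P25; P75): {s.median:g} ({s.p25:g}; {s.p75:g})")
    return lines


def render_summary(summary: CohortScreeningSummary, catalog: Catalog) -> str:
    """Plain-text screening report: distributions then per-section/criterion
    frequencies, percentages at one decimal."""
    lines: list[str] = []
    lines.append(f"Cohort size: {summary.n_total}")
    for tool_summary, label in ((summary.stopp, "PIMs (STOPP)"), (summary.start, "PPOs (START)")):
        lines.append("")
        lines.append(f"Number of {label} per patient:")
        lines.extend(_render_tool_distribution(tool_summary))
    for tool, tool_summary in (("STOPP", summary.stopp), ("START", summary.start)):
        lines.append("")
        lines.append(f"{tool} criteria frequencies, n (%):")
        for letter, (n_sec, pct_sec) in tool_summary.per_section.items():
            label = catalog.section_labels.get(tool, {}).get(letter, letter)
            lines.append(f"  {letter}  {label}  {n_sec} ({_fmt_pct(pct_sec)})")
            for rule in catalog.rules:
                if rule.tool == tool and rule.section == letter:
                    n_r, pct_r = tool_summary.per_criterion[rule.id]
                    lines.append(f"    {rule.id}  {n_r} ({_fmt_pct(pct_r)})")
    return "\n".join(lines) + "\n"


def summary_payload(summary: CohortScreeningSummary) -> dict:
    """Structured (JSON-ready) mirror of the rendered summary."""

    def tool_dict(s: ToolSummary) -> dict:
        return {
            "distribution": s.distribution,
            "prevalence_count": s.prevalence_count,
            "prevalence_pct": s.prevalence_pct,
            "mean": s.mean,
            "sd": s.sd,
            "median": s.median,
            "p25": s.p25,
            "p75": s.p75,
            "per_criterion": {k: list(v) for k, v in s.per_criterion.items()},
            "per_section": {k: list(v) for k, v in s.per_section.items()},
        }

    return {
        "n_total": summary.n_total,
        "catalog_version": summary.catalog_version,
        "stopp": tool_dict(summary.stopp),
        "start": tool_dict(summary.start),
    }


def render_associations(rows: list[AssociationRow]) -> str:
    lines = ["covariate\toutcome\tOR (95%CI)\tp"]
    for r in rows:
        if r.defined:
            lines.append(
                f"{r.covariate}\t{r.outcome}\t"
                f"{round_half_up(r.or_point, 2):.2f} "
                f"({round_half_up(r.ci_low, 2):.2f}; {round_half_up(r.ci_high, 2):.2f})\t"
                f"{round_half_up(r.p_wald, 3):.3f}"
            )
        else:
            lines.append(f"{r.covariate}\t{r.outcome}\t—\t—")
    return "\n".join(lines) + "\n"


def render_model(result: ForwardSelectionResult, diag) -> str:
    fit = result.fit
    lines = ["Forward-selected logistic model (Wald entry)"]
    if result.note:
        lines.append(f"note: {result.note}")
    lines.append("selected order: " + (", ".join(result.selected) or "(none)"))
    lines.append("")
    lines.append("term\tOR\t95% CI\tp")
    for i, name in enumerate(fit.names):
        lines.append(
            f"{name}\t{round_half_up(float(fit.odds_ratios[i]), 2):.2f}\t"
            f"({round_half_up(float(fit.or_ci_low[i]), 2):.2f}; "
            f"{round_half_up(float(fit.or_ci_high[i]), 2):.2f})\t"
            f"{round_half_up(float(fit.p_values[i]), 3):.3f}"
        )
    if diag is not None:
        lines.append("")
        lines.append(
            f"Omnibus p = {round_half_up(diag.omnibus_p, 3):.3f}; "
            f"Hosmer-Lemeshow p = {round_half_up(diag.hl_p, 3):.3f} "
            f"(chi2 = {round_half_up(diag.hl_statistic, 2):.2f}, df = {diag.hl_df}); "
            f"AUC = {round_half_up(diag.auc, 3):.3f} "
            f"(95% CI {round_half_up(diag.auc_ci_low, 3):.3f}; "
            f"{round_half_up(diag.auc_ci_high, 3):.3f})"
        )
        lines.append(
            f"Sensitivity = {_fmt_pct(100 * diag.sensitivity)}% and "
            f"Specificity = {_fmt_pct(100 * diag.specificity)}% at cutoff "
            f"{round_half_up(diag.cutoff, 4):.4f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/ingest -> screen -> summarize -> associate -> fit.

    Returns a report bundle (dict of in-memory results) and writes every
    artifact under ``config.out_dir``.  All statistical output is a pure
    function of the configuration, so reruns are byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        catalog = load_catalog(config.catalog_path)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage catalog: {exc}") from exc
    header = f"# seed={config.seed} catalog_version={catalog.version}\n"

    try:
        if config.cohort_path is None:
            cohort = generate(CohortConfig(n=config.n, seed=config.seed))
            logger.info("simulate: %d patients generated", len(cohort))
        else:
            cohort = read_cohort(config.cohort_path)
            logger.info("ingest: %d patients read", len(cohort))
        write_cohort(cohort, out / "cohort.csv")
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage cohort: {exc}") from exc

    try:
        results = screen_cohort(cohort, catalog)
        write_screening(results, out / "screening.csv", header=header)
        summary = summarize_cohort(results, catalog)
        (out / "summary.txt").write_text(header + render_summary(summary, catalog), encoding="utf-8")
        (out / "summary.json").write_text(
            json.dumps({"seed": config.seed, **summary_payload(summary)}, indent=1),
            encoding="utf-8",
        )
        logger.info(
            "screen: %d results; PIM prevalence %.1f%%, PPO prevalence %.1f%%",
            len(results),
            summary.stopp.prevalence_pct,
            summary.start.prevalence_pct,
        )
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage screen/summarize: {exc}") from exc

    try:
        assoc_rows = associate_all(cohort, results, outcomes=config.outcomes)
        n_undef = sum(1 for r in assoc_rows if not r.defined)
        if n_undef:
            logger.warning("associate: %d row(s) undefined (zero cells)", n_undef)
        (out / "associations.tsv").write_text(
            header + render_associations(assoc_rows), encoding="utf-8"
        )
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage associate: {exc}") from exc

    models = {}
    try:
        frame = covariate_frame(cohort)
        by_id = {r.patient_id: r for r in results}
        for outcome in config.outcomes:
            y = np.array(
                [
                    (by_id[p.id].n_pims if outcome == "pim" else by_id[p.id].n_ppos) > 0
                    for p in cohort
                ],
                dtype=int,
            )
            # candidate pool: covariates with a defined, significant
            # univariate association for this outcome
            sig = [
                r.covariate
                for r in assoc_rows
                if r.outcome == outcome and r.defined and r.p_wald < 0.05
            ]
            sel = forward_select(frame, y, candidates=sig, p_enter=config.p_enter,
                                 p_report=config.p_report)
            diag = None
            if sel.selected:
                diag = diagnostics(
                    sel.fit, frame[sel.selected].to_numpy(dtype=float), y
                )
            models[outcome] = (sel, diag)
            (out / f"model_{outcome}.txt").write_text(
                header + render_model(sel, diag), encoding="utf-8"
            )
            logger.info("fit[%s]: selected %s", outcome, sel.selected or "none")
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage fit: {exc}") from exc

    return {
        "cohort": cohort,
        "results": results,
        "summary": summary,
        "associations": assoc_rows,
        "models": models,
    }
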