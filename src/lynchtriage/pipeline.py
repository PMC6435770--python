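"""End-to-end pipeline: pedigrees -> CFDR -> triage -> costs -> stats.

The pipeline chains the library stages over a cohort and writes the
report bundle (TSV for humans-with-spreadsheets, JSON mirrors for
machines): ``cfdr.tsv``, ``triage.tsv``, ``costs_standard.{tsv,json}``,
``costs_panel.{tsv,json}``, ``comparison.json``, ``summary.json`` and
``scatter.tsv`` (the CFDR-vs-LAD point cloud plus the triage cutoff
polyline, ready for any plotting layer).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import cfdr as cfdr_mod
from . import costs as cost_mod
from . import stats as stats_mod
from . import triage as triage_mod
from .io import parse_lab_results, parse_ped
from .types import CFDRResult, LabResult, Pedigree, TriageDecision, ValidationError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

ARTIFACTS = (
    "cfdr.tsv",
    "triage.tsv",
    "costs_standard.tsv",
    "costs_standard.json",
    "costs_panel.tsv",
    "costs_panel.json",
    "comparison.json",
    "summary.json",
    "scatter.tsv",
)


@dataclass
class PipelineConfig:
    ped_path: Optional[PathLike] = None
    tumors_path: Optional[PathLike] = None
    lab_path: Optional[PathLike] = None
    cost_table_path: Optional[PathLike] = None
    out_dir: PathLike = "out"
    seed: int = 0
    workup: triage_mod.WorkupConfig = field(default_factory=triage_mod.WorkupConfig)


def compute_cfdr(pedigrees: Sequence[Pedigree]) -> list[CFDRResult]:
    """CFDR per pedigree; pedigrees whose proband is unaffected are
    excluded (no symptomatic tissue to anchor the referral)."""
    out = []
    for p in pedigrees:
        if not p.proband_affected:
            logger.warning(
                "family %s: proband unaffected, excluded from CFDR statistics",
                p.family_id,
            )
            continue
        out.append(cfdr_mod.select_cfdr(p))
    return out


def triage_cohort(
    cfdr_results: Sequence[CFDRResult],
    lab_results: Mapping[str, LabResult],
) -> list[TriageDecision]:
    """Classify every proband; MMR-first cases are resolved with the
    lab record when one with a conclusive MMR result exists."""
    decisions = []
    for r in cfdr_results:
        d = triage_mod.classify(r)
        if d.category == "mmr_first":
            lab = lab_results.get(r.proband_id)
            if lab is not None:
                try:
                    d = triage_mod.resolve_mmr_first(d, lab)
                except ValidationError:
                    logger.warning(
                        "%s: MMR-first case without MMR result, path left "
                        "unextended", r.proband_id,
                    )
        decisions.append(d)
    return decisions


def run_cohort(
    pedigrees: Sequence[Pedigree],
    lab_results: Mapping[str, LabResult],
    cost_table: Optional[cost_mod.CostTable] = None,
    workup: Optional[triage_mod.WorkupConfig] = None,
) -> dict:
    """Run every analysis stage in memory and return the bundle."""
    table = cost_table or cost_mod.CostTable()
    cfdr_results = compute_cfdr(pedigrees)
    decisions = triage_cohort(cfdr_results, lab_results)

    standard_paths = []
    for r in cfdr_results:
        lab = lab_results.get(r.proband_id)
        if lab is None:
            logger.warning("%s: no lab record, standard path empty", r.proband_id)
            standard_paths.append([])
            continue
        standard_paths.append(triage_mod.standard_workup_path(r, lab, workup))
    standard = cost_mod.aggregate_paths(
        standard_paths, table, name="standard_workup"
    )
    panel = cost_mod.aggregate_paths(
        (d.analyses_planned for d in decisions), table, name="direct_panel"
    )
    comparison = cost_mod.compare_strategies(standard, panel)

    summary = stats_mod.summarize(cfdr_results, lab_results)
    try:
        mmr_tests = stats_mod.compare_by_mmr_status(cfdr_results, lab_results)
    except ValueError:
        mmr_tests = None

    return {
        "cfdr": cfdr_results,
        "triage": decisions,
        "standard_paths": standard_paths,
        "costs_standard": standard,
        "costs_panel": panel,
        "comparison": comparison,
        "summary": summary,
        "mmr_tests": mmr_tests,
    }


def cfdr_frame(results: Sequence[CFDRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "proband_id": r.proband_id,
                "tumor_count": r.tumor_count,
                "lad": r.lad,
                "branch": r.branch,
                "member_ids": ";".join(sorted(r.member_ids)),
            }
            for r in results
        ]
    )


def triage_frame(decisions: Sequence[TriageDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "proband_id": d.proband_id,
                "category": d.category,
                "analyses_planned": ";".join(d.analyses_planned),
            }
            for d in decisions
        ]
    )


def scatter_frame(
    cfdr_results: Sequence[CFDRResult],
    lab_results: Mapping[str, LabResult],
) -> pd.DataFrame:
    """Figure data: one point per CFDR plus the panel-cutoff polyline
    (series ``cutoff``) separating direct-panel from the rest."""
    max_tc = max((r.tumor_count for r in cfdr_results), default=3)
    rows = []
    for r in cfdr_results:
        lab = lab_results.get(r.proband_id)
        rows.append(
            {
                "series": "point",
                "proband_id": r.proband_id,
                "lad": r.lad,
                "tumor_count": r.tumor_count,
                "mmr_functional": lab.mmr_functional if lab else "not_done",
                "variant_class": (lab.variant_class or "") if lab else "",
            }
        )
    cutoff = [
        (40, 0.5), (40, 1.5), (50, 1.5), (50, 2.5), (60, 2.5), (60, max_tc + 0.5),
    ]
    for lad, tc in cutoff:
        rows.append(
            {
                "series": "cutoff",
                "proband_id": "",
                "lad": lad,
                "tumor_count": tc,
                "mmr_functional": "",
                "variant_class": "",
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, pedigrees=None, lab_results=None) -> dict:
    """File-level entry point: parse inputs (unless given in memory),
    run all stages, and write the report bundle to ``cfg.out_dir``."""
    if pedigrees is None:
        if cfg.ped_path is None or cfg.tumors_path is None:
            raise ValidationError("pipeline needs ped/tumors paths or pedigrees")
        pedigrees = parse_ped(cfg.ped_path, cfg.tumors_path)
    if lab_results is None:
        if cfg.lab_path is None:
            raise ValidationError("pipeline needs a lab results path or mapping")
        lab_results = parse_lab_results(cfg.lab_path)
    table = (
        cost_mod.CostTable.from_file(cfg.cost_table_path)
        if cfg.cost_table_path
        else cost_mod.CostTable()
    )

    bundle = run_cohort(pedigrees, lab_results, table, cfg.workup)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfdr_frame(bundle["cfdr"]).to_csv(out / "cfdr.tsv", sep="\t", index=False)
    triage_frame(bundle["triage"]).to_csv(out / "triage.tsv", sep="\t", index=False)
    cost_mod.write_report(
        bundle["costs_standard"], out / "costs_standard.tsv", out / "costs_standard.json"
    )
    cost_mod.write_report(
        bundle["costs_panel"], out / "costs_panel.tsv", out / "costs_panel.json"
    )
    (out / "comparison.json").write_text(json.dumps(bundle["comparison"], indent=1))
    summary_doc = bundle["summary"].to_dict()
    if bundle["mmr_tests"] is not None:
        summary_doc["mmr_status_tests"] = {
            k: {
                "u_statistic": t.u_statistic,
                "p_value": t.p_value,
                "method": t.method,
                "n1": t.n1,
                "n2": t.n2,
                "median_diff": t.median_diff,
            }
            for k, t in bundle["mmr_tests"].items()
        }
    (out / "summary.json").write_text(json.dumps(summary_doc, indent=1))
    scatter_frame(bundle["cfdr"], lab_results).to_csv(
        out / "scatter.tsv", sep="\t", index=False
    )
    logger.info(
        "pipeline complete: %d pedigrees, %d CFDR results, totals %d / %d EUR",
        len(pedigrees),
        len(bundle["cfdr"]),
        bundle["costs_standard"].total,
        bundle["costs_panel"].total,
    )
    return bundle


_FOOTNOTES = {
    "gene_panel": "a",
    "mmr_functional": "b",
    "sequencing_2_genes": "c",
}


def make_table2(
    counts_standard: Mapping[str, int],
    counts_panel: Mapping[str, int],
    table: Optional[cost_mod.CostTable] = None,
) -> str:
    """Render the two-strategy cost comparison as a side-by-side text
    table with footnote markers on the simulated-approach rows."""
    table = table or cost_mod.CostTable()
    std = cost_mod.aggregate(counts_standard, table, name="standard")
    pan = cost_mod.aggregate(counts_panel, table, name="panel")
    # panel side printed panel-first
    pan_items = sorted(
        pan.line_items, key=lambda it: (it[0] != "gene_panel", it[0])
    )

    def fmt(items, footnoted):
        lines = []
        for a, c, u, s in items:
            mark = f"^{_FOOTNOTES[a]}" if footnoted and a in _FOOTNOTES else ""
            lines.append(f"{c}{mark}\t{a}\t{u} EUR\t{s:,} EUR")
        return lines

    left = fmt(std.line_items, footnoted=False)
    right = fmt(pan_items, footnoted=True)
    width = max((len(l) for l in left), default=0) + 4
    lines = ["No.\tLS standard laboratory work-up" + " " * 4 + "No.\tSimulated approach"]
    for i in range(max(len(left), len(right))):
        l = left[i] if i < len(left) else ""
        r = right[i] if i < len(right) else ""
        lines.append(l.ljust(width) + r)
    lines.append(
        f"Sum of total costs {std.total:,} EUR".ljust(width)
        + f"Sum of total costs {pan.total:,} EUR"
    )
    lines.append("a: cases fulfilling criteria for direct gene panel testing")
    lines.append("b: cases with a single CFDR tumor and LAD 40-49 years")
    lines.append("c: cases above (b) with MMR deficient tumor")
    return "\n".join(lines)
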