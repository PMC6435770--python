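"""Triage rules for direct gene-panel testing and the historical
step-wise Lynch-syndrome work-up.

Direct-panel criteria (simulated strategy), on the CFDR statistic:

* (a) one tumour and LAD < 40 years      -> gene panel
* (b) two tumours and LAD < 50 years     -> gene panel
* (c) >= 3 tumours and LAD < 60 years    -> gene panel
* one tumour, LAD 40-49                  -> MMR functional analysis
  first; mutation screening follows only if the tumour is MMR deficient
* anything else                          -> no testing

Reporting categories use exact tumour counts (1 / 2 / >=3) so the
partition over (tumor_count, LAD) is exhaustive and mutually exclusive;
panel eligibility is the union of (a)-(c).  Age boundaries are strict
(``<``); the MMR-first band is the closed integer range [40, 49].
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import CFDRResult, LabResult, TriageDecision, ValidationError


@dataclass
class WorkupConfig:
    """Knobs for the reconstructed historical work-up decision tree."""

    braf_available: bool = True
    msi_only_gene_count: int = 4
    # probands that went straight to germline sequencing (no tumour
    # work-up); value = number of genes sequenced
    direct_sequencing_overrides: dict[str, int] = field(default_factory=dict)


def _sequencing_analysis(n_genes: int) -> str:
    if not 1 <= n_genes <= 4:
        raise ValidationError(f"sequencing gene count {n_genes} outside 1..4")
    return f"sequencing_{n_genes}_gene" + ("s" if n_genes > 1 else "")


def _ihc_gene_count(lab: LabResult, msi_only_gene_count: int = 4) -> int:
    """Number of genes to sequence after a deficient tumour result.

    Paired heterodimer loss (MLH1/PMS2 or MSH2/MSH6) points at two
    candidate genes, a single lost protein at one; MSI positivity
    without informative IHC leaves all four MMR genes on the table.
    """
    if lab.ihc_pattern:
        return min(len(lab.ihc_pattern), 4)
    return msi_only_gene_count


def classify(r: CFDRResult) -> TriageDecision:
    """Map a CFDR statistic to its triage category under the simulated
    direct-panel strategy."""
    tc, lad = r.tumor_count, r.lad
    if tc == 1:
        if lad < 40:
            category = "panel_a"
        elif lad <= 49:
            category = "mmr_first"
        else:
            category = "none"
    elif tc == 2:
        category = "panel_b" if lad < 50 else "none"
    else:
        category = "panel_c" if lad < 60 else "none"
    if category.startswith("panel"):
        analyses: tuple[str, ...] = ("gene_panel",)
    elif category == "mmr_first":
        analyses = ("mmr_functional",)
    else:
        analyses = ()
    return TriageDecision(
        proband_id=r.proband_id, category=category, analyses_planned=analyses
    )


def resolve_mmr_first(d: TriageDecision, lab: LabResult) -> TriageDecision:
    """Extend an MMR-first decision with the lab outcome: a deficient
    tumour earns targeted germline sequencing (gene count per the IHC
    pattern), a proficient one ends the work-up."""
    if d.category != "mmr_first":
        raise ValidationError(
            f"{d.proband_id}: resolve_mmr_first on category {d.category!r}"
        )
    if lab.mmr_functional == "not_done":
        raise ValidationError(f"{d.proband_id}: unresolved MMR-first case")
    if lab.mmr_functional == "proficient":
        return d
    n = _ihc_gene_count(lab)
    return TriageDecision(
        proband_id=d.proband_id,
        category=d.category,
        analyses_planned=d.analyses_planned + (_sequencing_analysis(n),),
    )


def standard_workup_path(
    r: CFDRResult, lab: LabResult, cfg: WorkupConfig | None = None
) -> list[str]:
    """Analyses performed under the historical step-wise work-up.

    MMR functional analysis first; a deficient tumour with MLH1 loss is
    reflexed to BRAF V600E (when available) to flag sporadic promoter-
    methylation cases — BRAF positive stops the cascade; otherwise
    deficiency leads to germline sequencing of the genes implicated by
    the IHC pattern.  Direct-sequencing overrides model the rare
    probands who went straight to germline analysis.
    """
    cfg = cfg or WorkupConfig()
    if r.proband_id in cfg.direct_sequencing_overrides:
        return [_sequencing_analysis(cfg.direct_sequencing_overrides[r.proband_id])]
    path = ["mmr_functional"]
    if lab.mmr_functional != "deficient":
        return path
    mlh1_pattern = lab.ihc_pattern is not None and "MLH1" in lab.ihc_pattern
    if mlh1_pattern and cfg.braf_available:
        path.append("braf_v600e")
        if lab.braf_v600e == "positive":
            return path  # somatic origin, no germline screening
    path.append(
        _sequencing_analysis(_ihc_gene_count(lab, cfg.msi_only_gene_count))
    )
    return path
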