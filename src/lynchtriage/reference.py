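"""Reported margins of the historical referral cohort (a clinical-
genetics unit's 1996-2012 Lynch-syndrome work-up series of 372 adult
probands) that the package's defaults model.

Per-patient microdata for that cohort were never released; what is
available are the analysis counts billed under each strategy, the
triage-category counts, and the cohort margins (tested / deficient /
screened / mutation-positive, and the per-gene mutation split).  These
serve as fixture inputs for desk-scale reproduction of the cost
arithmetic and summary fractions.
"""

from __future__ import annotations

from .types import CFDRResult, LabResult

#: Analyses billed under the historical step-wise work-up.
STANDARD_ANALYSIS_COUNTS: dict[str, int] = {
    "mmr_functional": 368,
    "braf_v600e": 15,
    "sequencing_1_gene": 44,
    "sequencing_2_genes": 47,
    "sequencing_3_genes": 13,
    "sequencing_4_genes": 10,
}

#: Analyses under the simulated direct-panel strategy: 237 probands meet
#: a panel criterion, 40 single-tumour LAD-40-49 probands get MMR
#: functional analysis first, of whom 6 (MMR deficient) proceed to
#: two-gene sequencing.
PANEL_ANALYSIS_COUNTS: dict[str, int] = {
    "gene_panel": 237,
    "mmr_functional": 40,
    "sequencing_2_genes": 6,
}

#: Triage partition of the 372 probands by (tumour count, LAD) category.
TRIAGE_CATEGORY_COUNTS: dict[str, int] = {
    "panel_a": 31,   # one tumour, LAD < 40
    "panel_b": 77,   # two tumours, LAD < 50
    "panel_c": 129,  # >= 3 tumours, LAD < 60
    "mmr_first": 40,  # one tumour, LAD 40-49
    "none": 95,
}

#: Cohort margins: probands, MMR tested, MMR deficient, mutation
#: screened, mutation positive.
COHORT_MARGINS = dict(
    n_probands=372, n_mmr_tested=368, n_mmr_deficient=92,
    n_screened=114, n_mutation=48,
)

#: Pathogenic mutations per MMR gene among the 48 carriers.
GENE_MUTATION_COUNTS: dict[str, int] = {
    "MLH1": 15, "MSH2": 22, "MSH6": 10, "PMS2": 1,
}

#: Per-gene mean CFDR tumour count and mean LAD among carriers.
GENE_MEAN_TUMOR_COUNT = {"MLH1": 4.3, "MSH2": 3.4, "MSH6": 3.2, "PMS2": 2.0}
GENE_MEAN_LAD = {"MLH1": 37, "MSH2": 39, "MSH6": 42, "PMS2": 44}

_HETERODIMER = {
    "MLH1": ("MLH1", "PMS2"),
    "MSH2": ("MSH2", "MSH6"),
    "MSH6": ("MSH6",),
    "PMS2": ("PMS2",),
}

#: Representative (tumour count, LAD) per triage category, used when a
#: synthetic CFDR statistic consistent with a category is needed.
CATEGORY_EXEMPLARS = {
    "panel_a": (1, 35),
    "panel_b": (2, 45),
    "panel_c": (3, 50),
    "mmr_first": (1, 45),
    "none": (1, 55),
}


def category_cfdr_results() -> list[CFDRResult]:
    """One synthetic CFDR statistic per proband, with the category
    margins of the historical cohort (31 / 77 / 129 / 40 / 95)."""
    out, k = [], 0
    for cat, n in TRIAGE_CATEGORY_COUNTS.items():
        tc, lad = CATEGORY_EXEMPLARS[cat]
        for _ in range(n):
            k += 1
            pid = f"P{k:03d}"
            out.append(
                CFDRResult(proband_id=pid, member_ids=frozenset({pid}),
                           tumor_count=tc, lad=lad, branch="nuclear")
            )
    return out


def marginal_lab_cohort() -> tuple[list[CFDRResult], dict[str, LabResult]]:
    """Synthetic per-proband records whose margins equal the historical
    cohort's: 372 probands, 368 MMR tested, 92 deficient, 114 screened,
    48 pathogenic mutations split 15/22/10/1 across the MMR genes.

    The per-patient detail (which proband pairs with which margin) is a
    fixture construction; only the margins are meaningful.
    """
    genes = [g for g, n in GENE_MUTATION_COUNTS.items() for _ in range(n)]
    cfdr, lab = [], {}
    k = 0

    def add(result: dict, tc: int, lad: int) -> None:
        nonlocal k
        k += 1
        pid = f"P{k:03d}"
        lab[pid] = LabResult(proband_id=pid, **result)
        cfdr.append(
            CFDRResult(proband_id=pid, member_ids=frozenset({pid}),
                       tumor_count=tc, lad=lad, branch="nuclear")
        )

    for g in genes:  # mutation carriers: deficient and screened
        loss = _HETERODIMER[g]
        add(
            dict(mmr_functional="deficient", ihc_pattern=frozenset(loss),
                 screened_genes=loss, mutation_gene=g,
                 variant_class="pathogenic"),
            round(GENE_MEAN_TUMOR_COUNT[g]), GENE_MEAN_LAD[g],
        )
    n_mut = len(genes)
    for _ in range(COHORT_MARGINS["n_mmr_deficient"] - n_mut):
        add(dict(mmr_functional="deficient",
                 ihc_pattern=frozenset({"MLH1", "PMS2"}),
                 screened_genes=("MLH1", "PMS2"), variant_class="none"),
            2, 50)
    for _ in range(COHORT_MARGINS["n_screened"] - COHORT_MARGINS["n_mmr_deficient"]):
        add(dict(mmr_functional="proficient", screened_genes=("MLH1",),
                 variant_class="none"), 2, 55)
    while k < COHORT_MARGINS["n_mmr_tested"]:
        add(dict(mmr_functional="proficient"), 1, 60)
    while k < COHORT_MARGINS["n_probands"]:
        add(dict(mmr_functional="not_done"), 1, 60)
    return cfdr, lab
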