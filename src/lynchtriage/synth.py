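"""Synthetic referral cohorts for hereditary-CRC triage pipelines.

No per-patient microdata accompany the clinical cohort this package
models, so every pipeline stage is exercised on generated families.
The generator emulates a clinical-genetics referral series: ~13% of
probands carry a Lynch-syndrome (LS) mutation in one of the mismatch-
repair genes, carriers sit in densely affected early-onset family
branches (autosomal dominant segregation from a founder grandparent),
and the sporadic background contributes late-onset colorectal tumours
of which ~15% are MMR deficient through somatic MLH1 promoter
methylation (BRAF V600E positive in a majority of those).

Pedigrees are three generations deep: four grandparents, the parental
couple with optional aunts/uncles on each side, and the proband with
optional siblings.  The proband always has at least one tumour — an
unaffected proband would not have been referred for tumour-based
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    HETERODIMER_LOSS,
    Individual,
    LabResult,
    MMR_GENES,
    Pedigree,
    TumorRecord,
    ValidationError,
)

#: Per-gene mean age at diagnosis (years) in carrier branches.
DEFAULT_ONSET_MEAN = {"MLH1": 37.0, "MSH2": 39.0, "MSH6": 42.0, "PMS2": 44.0}
#: Printed onset ranges; PMS2 (a single observed family) gets a
#: synthetic symmetric range consistent with a 6-year spread.
DEFAULT_ONSET_RANGE = {
    "MLH1": (23.0, 48.0),
    "MSH2": (22.0, 57.0),
    "MSH6": (34.0, 51.0),
    "PMS2": (32.0, 56.0),
}
#: Expected number of LS-associated tumours in the carrier branch.
DEFAULT_TUMOR_INTENSITY = {"MLH1": 4.3, "MSH2": 3.4, "MSH6": 3.2, "PMS2": 2.0}

DEFAULT_GENE_MIX = {"MLH1": 0.31, "MSH2": 0.46, "MSH6": 0.21, "PMS2": 0.02}

# site frequencies for carrier tumours; female-only sites fall back to
# colorectal in males
CARRIER_SITES = {
    "colorectal": 0.60,
    "rectal": 0.06,
    "endometrial": 0.14,
    "ovarian": 0.06,
    "gastric": 0.06,
    "small_bowel": 0.04,
    "upper_urinary_tract": 0.04,
}
SPORADIC_SITES = {
    "colorectal": 0.75,
    "rectal": 0.15,
    "endometrial": 0.10,
}


@dataclass
class SyntheticCohortParams:
    """Generator settings; defaults are the referral-cohort conditions
    the package models."""

    n_probands: int = 372
    seed: int = 0
    ls_fraction: float = 0.13
    gene_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENE_MIX))
    onset_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ONSET_MEAN))
    onset_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_RANGE)
    )
    carrier_tumor_intensity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_INTENSITY)
    )
    sporadic_onset_mean: float = 55.0
    sporadic_onset_sd: float = 10.0
    #: probability an adult non-carrier relative has a sporadic LS-site tumour
    sporadic_tumor_rate: float = 0.12
    sporadic_mmr_deficiency_rate: float = 0.15
    braf_positive_given_methylation: float = 0.6
    assay_sensitivity: float = 47.0 / 48.0
    detection_rate: float = 1.0
    mmr_not_done_rate: float = 4.0 / 372.0
    #: deficient result carried by MSI only, with no informative IHC
    msi_only_rate: float = 0.10
    vus_rate: float = 0.06
    mean_siblings: float = 1.5
    mean_parent_siblings: float = 1.5

    def __post_init__(self) -> None:
        if self.n_probands < 1:
            raise ValidationError("n_probands must be >= 1")
        if abs(sum(self.gene_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("gene_mix must sum to 1")
        for name in (
            "ls_fraction",
            "sporadic_tumor_rate",
            "sporadic_mmr_deficiency_rate",
            "braf_positive_given_methylation",
            "assay_sensitivity",
            "detection_rate",
            "mmr_not_done_rate",
            "msi_only_rate",
            "vus_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def onset_spread(self, gene: str) -> float:
        lo, hi = self.onset_range[gene]
        return (hi - lo) / 4.0

    def onset_truncated_mean(self, gene: str) -> float:
        """Closed-form mean of the truncated onset distribution — the
        quantity large simulations should recover."""
        mu, sd = self.onset_mean[gene], self.onset_spread(gene)
        lo, hi = self.onset_range[gene]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))


def _draw_site(rng: np.random.Generator, table: dict[str, float], sex: str) -> str:
    names = list(table)
    probs = np.array([table[n] for n in names])
    site = rng.choice(names, p=probs / probs.sum())
    if sex == "male" and site in ("endometrial", "ovarian"):
        site = "colorectal"
    return str(site)


def _draw_onset(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> int:
    lo, hi = max(lo, 18.0), min(hi, 90.0)
    if sd <= 0 or hi <= lo:
        return int(round(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return int(round(x))


def generate_pedigree(
    params: SyntheticCohortParams,
    carrier_gene: Optional[str],
    rng: np.random.Generator,
    family_id: str = "F1",
) -> tuple[Pedigree, dict]:
    """Build one three-generation pedigree and its latent truth record.

    If ``carrier_gene`` is set the mutation segregates dominantly from
    one founder grandparent with Mendelian transmission probability 1/2
    along the non-ascertained lines; the line down to the proband is
    forced carrier, reflecting ascertainment through the referred
    (mutation-positive) proband.
    """
    f = family_id

    def make(iid, father, mother, sex):
        return Individual(
            individual_id=f"{f}_{iid}",
            family_id=f,
            father_id=f"{f}_{father}" if father else None,
            mother_id=f"{f}_{mother}" if mother else None,
            sex=sex,
        )

    inds: dict[str, Individual] = {}

    def add(ind: Individual) -> Individual:
        inds[ind.individual_id] = ind
        return ind

    # grandparents
    add(make("GFP", None, None, "male"))
    add(make("GMP", None, None, "female"))
    add(make("GFM", None, None, "male"))
    add(make("GMM", None, None, "female"))
    father = add(make("FA", "GFP", "GMP", "male"))
    mother = add(make("MO", "GFM", "GMM", "female"))
    n_unc_p = int(rng.poisson(params.mean_parent_siblings))
    n_unc_m = int(rng.poisson(params.mean_parent_siblings))
    for k in range(n_unc_p):
        add(make(f"PU{k + 1}", "GFP", "GMP", "male" if rng.random() < 0.5 else "female"))
    for k in range(n_unc_m):
        add(make(f"MU{k + 1}", "GFM", "GMM", "male" if rng.random() < 0.5 else "female"))
    proband = add(make("PB", "FA", "MO", "male" if rng.random() < 0.5 else "female"))
    proband.is_proband = True
    n_sibs = int(rng.poisson(params.mean_siblings))
    for k in range(n_sibs):
        add(make(f"S{k + 1}", "FA", "MO", "male" if rng.random() < 0.5 else "female"))

    carriers: set[str] = set()
    branch_side = None
    if carrier_gene is not None:
        branch_side = "maternal" if rng.random() < 0.5 else "paternal"
        if branch_side == "maternal":
            founder, carrier_parent = ("GFM" if rng.random() < 0.5 else "GMM"), "MO"
            uncles = [f"MU{k + 1}" for k in range(n_unc_m)]
        else:
            founder, carrier_parent = ("GFP" if rng.random() < 0.5 else "GMP"), "FA"
            uncles = [f"PU{k + 1}" for k in range(n_unc_p)]
        # ascertained line is carrier by construction
        carriers.update({f"{f}_{founder}", f"{f}_{carrier_parent}", proband.individual_id})
        for u in uncles:  # 1/2 transmission to non-ascertained lines
            if rng.random() < 0.5:
                carriers.add(f"{f}_{u}")
        for k in range(n_sibs):
            if rng.random() < 0.5:
                carriers.add(f"{f}_S{k + 1}")

        # distribute the branch tumour load over carriers, proband first
        intensity = params.carrier_tumor_intensity[carrier_gene]
        n_tumors = 1 + int(rng.poisson(max(intensity - 1.0, 0.0)))
        # keep the affected set first-degree connected where possible:
        # proband and carrier parent head the allocation order
        order = [proband.individual_id, f"{f}_{carrier_parent}"]
        order += sorted(c for c in carriers if c not in order)
        targets = [order[0]]
        for _ in range(n_tumors - 1):
            targets.append(order[int(rng.integers(0, min(len(order), 4)))])
        mu = params.onset_mean[carrier_gene]
        sd = params.onset_spread(carrier_gene)
        lo, hi = params.onset_range[carrier_gene]
        for iid in targets:
            ind = inds[iid]
            ind.tumors.append(
                TumorRecord(
                    individual_id=iid,
                    site=_draw_site(rng, CARRIER_SITES, ind.sex),
                    age_at_diagnosis=_draw_onset(rng, mu, sd, lo, hi),
                    tumor_index=len(ind.tumors) + 1,
                )
            )

    # sporadic background among non-carriers; the proband must have a
    # tumour (referral condition)
    for ind in inds.values():
        if ind.individual_id in carriers:
            continue
        forced = ind.is_proband and not ind.tumors
        if forced or rng.random() < params.sporadic_tumor_rate:
            ind.tumors.append(
                TumorRecord(
                    individual_id=ind.individual_id,
                    site=_draw_site(rng, SPORADIC_SITES, ind.sex),
                    age_at_diagnosis=_draw_onset(
                        rng,
                        params.sporadic_onset_mean,
                        params.sporadic_onset_sd,
                        18.0,
                        90.0,
                    ),
                    tumor_index=len(ind.tumors) + 1,
                )
            )

    ped = Pedigree(family_id=f, individuals=inds, proband_id=proband.individual_id)
    truth = {
        "family_id": f,
        "proband_id": proband.individual_id,
        "carrier_gene": carrier_gene,
        "carrier_ids": sorted(carriers),
        "branch_side": branch_side,
    }
    return ped, truth


def generate_lab_results(
    pedigree: Pedigree,
    truth: dict,
    params: SyntheticCohortParams,
    rng: np.random.Generator,
) -> LabResult:
    """Simulate the proband's laboratory record under the historical
    step-wise work-up.

    Carriers show tumour MMR deficiency with probability
    ``assay_sensitivity`` and an IHC pattern matching their gene's
    heterodimer; sporadic colorectal tumours are deficient with
    probability ``sporadic_mmr_deficiency_rate`` (MLH1/PMS2 loss) and
    then BRAF V600E positive with probability
    ``braf_positive_given_methylation``.  Mutation screening happens
    downstream of deficiency (BRAF-positive cases stop the cascade).
    """
    pid = pedigree.proband_id
    gene = truth.get("carrier_gene")
    if not pedigree.proband_affected:
        raise ValidationError(f"{pid}: proband has no tumor; no tissue to test")

    if rng.random() < params.mmr_not_done_rate:
        return LabResult(proband_id=pid, mmr_functional="not_done")

    sporadic_methylation = False
    if gene is not None:
        deficient = rng.random() < params.assay_sensitivity
        loss = HETERODIMER_LOSS[gene]
    else:
        has_colon = any(
            t.site == "colorectal" for t in pedigree.proband.tumors
        )
        deficient = has_colon and rng.random() < params.sporadic_mmr_deficiency_rate
        sporadic_methylation = deficient
        loss = HETERODIMER_LOSS["MLH1"]

    if not deficient:
        return LabResult(proband_id=pid, mmr_functional="proficient")

    msi_only = rng.random() < params.msi_only_rate
    ihc = None if msi_only else frozenset(loss)

    braf = "not_done"
    if ihc is None or "MLH1" in ihc:
        if sporadic_methylation:
            braf = (
                "positive"
                if rng.random() < params.braf_positive_given_methylation
                else "negative"
            )
        else:
            braf = "negative"

    if braf == "positive":  # cascade stops: somatic origin
        return LabResult(
            proband_id=pid,
            mmr_functional="deficient",
            ihc_pattern=ihc,
            braf_v600e=braf,
        )

    screened = tuple(sorted(ihc)) if ihc else MMR_GENES
    if gene is not None and gene in screened and rng.random() < params.detection_rate:
        mutation_gene, vclass = gene, "pathogenic"
    elif rng.random() < params.vus_rate:
        mutation_gene, vclass = None, "VUS"
    else:
        mutation_gene, vclass = None, "none"
    return LabResult(
        proband_id=pid,
        mmr_functional="deficient",
        ihc_pattern=ihc,
        braf_v600e=braf,
        screened_genes=screened,
        mutation_gene=mutation_gene,
        variant_class=vclass,
    )


def generate_cohort(
    params: SyntheticCohortParams,
) -> tuple[list[Pedigree], dict[str, LabResult], pd.DataFrame]:
    """Generate ``n_probands`` independent referral pedigrees with lab
    results and a latent truth table (one row per proband)."""
    rng = np.random.default_rng(params.seed)
    genes = list(params.gene_mix)
    gene_p = np.array([params.gene_mix[g] for g in genes])
    gene_p = gene_p / gene_p.sum()

    pedigrees: list[Pedigree] = []
    lab: dict[str, LabResult] = {}
    rows = []
    for k in range(params.n_probands):
        carrier_gene = None
        if rng.random() < params.ls_fraction:
            carrier_gene = str(rng.choice(genes, p=gene_p))
        ped, truth = generate_pedigree(
            params, carrier_gene, rng, family_id=f"F{k + 1:05d}"
        )
        result = generate_lab_results(ped, truth, params, rng)
        pedigrees.append(ped)
        lab[ped.proband_id] = result
        rows.append(
            {
                "proband_id": ped.proband_id,
                "family_id": ped.family_id,
                "carrier_gene": carrier_gene or "",
                "carrier_ids": ";".join(truth["carrier_ids"]),
                "branch_side": truth["branch_side"] or "",
                "mmr_functional": result.mmr_functional,
                "screened": result.screened,
                "mutation_gene": result.mutation_gene or "",
                "variant_class": result.variant_class or "",
            }
        )
    return pedigrees, lab, pd.DataFrame(rows)
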