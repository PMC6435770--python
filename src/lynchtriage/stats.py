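"""Cohort summaries and the Mann-Whitney U comparison of CFDR features
between MMR-deficient and MMR-proficient tumours."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import CFDRResult, LabResult, MMR_GENES


@dataclass(frozen=True)
class TestResult:
    u_statistic: float
    p_value: float
    method: str  # exact_permutation | normal_approximation
    n1: int
    n2: int
    median_diff: float  # median(x) - median(y)


def _has_ties(x: Sequence[float], y: Sequence[float]) -> bool:
    pooled = list(x) + list(y)
    return len(set(pooled)) < len(pooled)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 400
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    U is computed by midranks.  The p-value uses the exact permutation
    null when ``n1 * n2 <= exact_limit`` and the pooled sample is free
    of ties, and otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = x.size * y.size <= exact_limit and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    # U at the null mean: every relabelling is at least as extreme, so
    # the two-tailed permutation p is exactly 1 (the normal
    # approximation's continuity shift would report slightly less)
    p = 1.0 if res.statistic == x.size * y.size / 2 else float(min(res.pvalue, 1.0))
    return TestResult(
        u_statistic=float(res.statistic),
        p_value=p,
        method="exact_permutation" if exact else "normal_approximation",
        n1=int(x.size),
        n2=int(y.size),
        median_diff=float(np.median(x) - np.median(y)),
    )


def round_percent(x: float) -> int:
    """Integer percent, half rounded away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class CohortSummary:
    n_probands: int
    n_mmr_tested: int
    n_mmr_deficient: int
    n_screened: int
    n_mutation: int
    per_gene_counts: dict[str, int]
    per_gene_mean_tumor_count: dict[str, float]
    per_gene_mean_lad: dict[str, float]
    mean_tumor_count: float
    mean_lad: float

    @property
    def frac_deficient_of_tested(self) -> Optional[float]:
        return (
            self.n_mmr_deficient / self.n_mmr_tested if self.n_mmr_tested else None
        )

    @property
    def frac_mutation_of_screened(self) -> Optional[float]:
        return self.n_mutation / self.n_screened if self.n_screened else None

    @property
    def frac_mutation_of_cohort(self) -> Optional[float]:
        return self.n_mutation / self.n_probands if self.n_probands else None

    def gene_share_percent(self, gene: str) -> Optional[int]:
        if not self.n_mutation:
            return None
        return round_percent(100.0 * self.per_gene_counts.get(gene, 0) / self.n_mutation)

    def to_dict(self) -> dict:
        def pct(v: Optional[float]) -> Optional[int]:
            return None if v is None else round_percent(100.0 * v)

        return {
            "n_probands": self.n_probands,
            "n_mmr_tested": self.n_mmr_tested,
            "n_mmr_deficient": self.n_mmr_deficient,
            "pct_deficient_of_tested": pct(self.frac_deficient_of_tested),
            "n_screened": self.n_screened,
            "n_mutation": self.n_mutation,
            "pct_mutation_of_screened": pct(self.frac_mutation_of_screened),
            "pct_mutation_of_cohort": pct(self.frac_mutation_of_cohort),
            "per_gene_counts": self.per_gene_counts,
            "per_gene_share_pct": {
                g: self.gene_share_percent(g) for g in MMR_GENES
            },
            "per_gene_mean_tumor_count": self.per_gene_mean_tumor_count,
            "per_gene_mean_lad": self.per_gene_mean_lad,
            "mean_tumor_count": self.mean_tumor_count,
            "mean_lad": self.mean_lad,
        }


def summarize(
    cfdr_results: Iterable[CFDRResult],
    lab_results: Mapping[str, LabResult],
) -> CohortSummary:
    """Cohort-level counts, fractions and per-gene CFDR summaries.

    Pure function of the cohort: order-independent and deterministic.
    Exact fractions are retained; report display rounds to whole
    percent (half away from zero).
    """
    cfdr = {r.proband_id: r for r in cfdr_results}
    n = len(cfdr)
    tested = [
        r for r in lab_results.values() if r.mmr_functional in ("deficient", "proficient")
    ]
    deficient = [r for r in tested if r.mmr_functional == "deficient"]
    screened = [r for r in lab_results.values() if r.screened]
    mutated = [r for r in screened if r.variant_class == "pathogenic"]

    per_gene_counts = {g: 0 for g in MMR_GENES}
    per_gene_tc: dict[str, list[float]] = {g: [] for g in MMR_GENES}
    per_gene_lad: dict[str, list[float]] = {g: [] for g in MMR_GENES}
    for r in mutated:
        g = r.mutation_gene
        if g is None:
            continue
        per_gene_counts[g] += 1
        if r.proband_id in cfdr:
            per_gene_tc[g].append(cfdr[r.proband_id].tumor_count)
            per_gene_lad[g].append(cfdr[r.proband_id].lad)

    def mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    return CohortSummary(
        n_probands=n,
        n_mmr_tested=len(tested),
        n_mmr_deficient=len(deficient),
        n_screened=len(screened),
        n_mutation=len(mutated),
        per_gene_counts=per_gene_counts,
        per_gene_mean_tumor_count={g: mean(per_gene_tc[g]) for g in MMR_GENES},
        per_gene_mean_lad={g: mean(per_gene_lad[g]) for g in MMR_GENES},
        mean_tumor_count=mean([r.tumor_count for r in cfdr.values()]),
        mean_lad=mean([r.lad for r in cfdr.values()]),
    )


def compare_by_mmr_status(
    cfdr_results: Iterable[CFDRResult],
    lab_results: Mapping[str, LabResult],
) -> dict[str, TestResult]:
    """Compare CFDR tumour counts and LAD between probands with MMR-
    deficient and MMR-proficient tumours (two-tailed Mann-Whitney U).

    ``median_diff`` is deficient minus proficient, so the expected
    pattern in an LS-enriched cohort is positive for ``tumor_count``
    and negative for ``lad``.
    """
    cfdr = {r.proband_id: r for r in cfdr_results}
    groups: dict[str, list[CFDRResult]] = {"deficient": [], "proficient": []}
    for pid, lab in lab_results.items():
        if lab.mmr_functional in groups and pid in cfdr:
            groups[lab.mmr_functional].append(cfdr[pid])
    if not groups["deficient"] or not groups["proficient"]:
        raise ValueError("both MMR status groups must be non-empty")
    out = {}
    for feature in ("tumor_count", "lad"):
        out[feature] = mann_whitney_u(
            [getattr(r, feature) for r in groups["deficient"]],
            [getattr(r, feature) for r in groups["proficient"]],
        )
    return out
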