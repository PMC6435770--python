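"""Core domain types for hereditary-CRC pedigree triage.

The data model mirrors the clinical workflow: pedigrees with tumour
histories arrive per referred proband, each proband has a record of
laboratory results (MMR functional status, IHC pattern, BRAF status,
mutation screening outcome), and downstream stages derive the CFDR
(cluster of first-degree relatives) statistic and a triage decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Tumour sites considered Lynch-syndrome (LS) associated.  Rectal cancer is
# kept distinct from colon cancer because MMR deficiency in rectal tumours
# is rare in sporadic disease and therefore a strong LS indicator.
TUMOR_SITES = (
    "colorectal",
    "rectal",
    "endometrial",
    "ovarian",
    "gastric",
    "small_bowel",
    "upper_urinary_tract",
    "other",
)
LS_SITES = frozenset(s for s in TUMOR_SITES if s != "other")

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

# IHC heterodimer partners: loss of MLH1 drags PMS2 down with it, and loss
# of MSH2 drags MSH6; the minor partners can be lost alone.
HETERODIMER_LOSS = {
    "MLH1": frozenset({"MLH1", "PMS2"}),
    "PMS2": frozenset({"PMS2"}),
    "MSH2": frozenset({"MSH2", "MSH6"}),
    "MSH6": frozenset({"MSH6"}),
}

SEXES = ("male", "female", "unknown")
MMR_STATUSES = ("deficient", "proficient", "not_done")
BRAF_STATUSES = ("positive", "negative", "not_done")
VARIANT_CLASSES = ("pathogenic", "VUS", "none")

BRANCHES = ("maternal", "paternal", "nuclear", "unrelated")

TRIAGE_CATEGORIES = ("panel_a", "panel_b", "panel_c", "mmr_first", "none")

ANALYSES = (
    "mmr_functional",
    "braf_v600e",
    "sequencing_1_gene",
    "sequencing_2_genes",
    "sequencing_3_genes",
    "sequencing_4_genes",
    "gene_panel",
)


class ValidationError(ValueError):
    """Raised when an input file or object violates the data model."""


@dataclass(frozen=True)
class TumorRecord:
    """One primary tumour in one individual.

    Metachronous and synchronous primaries are separate records
    distinguished by ``tumor_index`` and each counts as an independent
    tumour case in the CFDR statistic.
    """

    individual_id: str
    site: str
    age_at_diagnosis: int
    tumor_index: int = 1

    def __post_init__(self) -> None:
        if self.site not in TUMOR_SITES:
            raise ValidationError(f"unknown tumor site {self.site!r}")
        if not 0 <= self.age_at_diagnosis <= 120:
            raise ValidationError(
                f"age_at_diagnosis {self.age_at_diagnosis} outside [0, 120]"
            )
        if self.tumor_index < 1:
            raise ValidationError("tumor_index must be >= 1")

    @property
    def ls_associated(self) -> bool:
        return self.site in LS_SITES


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    tumors: list[TumorRecord] = field(default_factory=list)
    is_proband: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")

    @property
    def ls_tumors(self) -> list[TumorRecord]:
        return [t for t in self.tumors if t.ls_associated]

    @property
    def affected(self) -> bool:
        """Affected means >= 1 LS-associated tumour; 'other'-site tumours
        never confer affected status."""
        return any(t.ls_associated for t in self.tumors)


@dataclass
class Pedigree:
    """One family anchored on a single referred proband."""

    family_id: str
    individuals: dict[str, Individual]
    proband_id: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.proband_id not in self.individuals:
            raise ValidationError(
                f"family {self.family_id}: proband {self.proband_id!r} not in pedigree"
            )
        probands = [i for i in self.individuals.values() if i.is_proband]
        if len(probands) != 1 or probands[0].individual_id != self.proband_id:
            raise ValidationError(
                f"family {self.family_id}: exactly one proband required"
            )
        dangling = []
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.individuals:
                    dangling.append((ind.individual_id, pid))
            if ind.family_id != self.family_id:
                raise ValidationError(
                    f"individual {ind.individual_id} has family_id "
                    f"{ind.family_id!r}, expected {self.family_id!r}"
                )
        if dangling:
            raise ValidationError(
                f"family {self.family_id}: dangling parent references {dangling}"
            )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative ancestor walk; a cycle revisits an id on the stack
        state: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(start: str) -> None:
            stack = [(start, iter(self._parents(start)))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 0:
                        raise ValidationError(
                            f"family {self.family_id}: cyclic parentage involving "
                            f"{p!r}"
                        )
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parents(p))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

        for iid in self.individuals:
            if iid not in state:
                visit(iid)

    def _parents(self, iid: str) -> list[str]:
        ind = self.individuals[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    @property
    def proband(self) -> Individual:
        return self.individuals[self.proband_id]

    @property
    def proband_affected(self) -> bool:
        return self.proband.affected

    def affected_ids(self) -> list[str]:
        return sorted(
            i.individual_id for i in self.individuals.values() if i.affected
        )

    def all_tumors(self) -> list[TumorRecord]:
        out: list[TumorRecord] = []
        for ind in self.individuals.values():
            out.extend(ind.tumors)
        return out


@dataclass
class LabResult:
    """Laboratory work-up record for one proband."""

    proband_id: str
    mmr_functional: str = "not_done"
    ihc_pattern: Optional[frozenset[str]] = None
    braf_v600e: str = "not_done"
    screened_genes: tuple[str, ...] = ()
    mutation_gene: Optional[str] = None
    variant_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mmr_functional not in MMR_STATUSES:
            raise ValidationError(
                f"{self.proband_id}: bad mmr_functional {self.mmr_functional!r}"
            )
        if self.braf_v600e not in BRAF_STATUSES:
            raise ValidationError(
                f"{self.proband_id}: bad braf_v600e {self.braf_v600e!r}"
            )
        if self.ihc_pattern is not None:
            bad = set(self.ihc_pattern) - set(MMR_GENES)
            if bad:
                raise ValidationError(
                    f"{self.proband_id}: unknown IHC proteins {sorted(bad)}"
                )
            self.ihc_pattern = frozenset(self.ihc_pattern)
        if self.mutation_gene is not None and self.mutation_gene not in MMR_GENES:
            raise ValidationError(
                f"{self.proband_id}: unknown mutation gene {self.mutation_gene!r}"
            )
        if self.variant_class is not None and self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"{self.proband_id}: bad variant_class {self.variant_class!r}"
            )
        if self.mutation_gene is not None and self.variant_class != "pathogenic":
            raise ValidationError(
                f"{self.proband_id}: mutation_gene set but variant_class is "
                f"{self.variant_class!r}, expected 'pathogenic'"
            )
        if self.variant_class is not None and not self.screened_genes:
            raise ValidationError(
                f"{self.proband_id}: variant_class set but no screened_genes"
            )

    @property
    def screened(self) -> bool:
        return self.variant_class is not None


@dataclass(frozen=True)
class CFDRResult:
    """Per-proband cluster statistic: the single-branch, first-degree-
    connected set of affected relatives carrying the most LS-associated
    tumours, with the lowest age at diagnosis (LAD) in that branch."""

    proband_id: str
    member_ids: frozenset[str]
    tumor_count: int
    lad: int
    branch: str

    def __post_init__(self) -> None:
        if self.tumor_count < 1:
            raise ValidationError("CFDR tumor_count must be >= 1")
        if self.branch not in ("maternal", "paternal", "nuclear"):
            raise ValidationError(f"bad CFDR branch {self.branch!r}")


@dataclass(frozen=True)
class TriageDecision:
    proband_id: str
    category: str
    analyses_planned: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CATEGORIES:
            raise ValidationError(f"bad triage category {self.category!r}")
        for a in self.analyses_planned:
            if a not in ANALYSES:
                raise ValidationError(f"unknown analysis {a!r}")
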