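"""Readers and writers for pedigree, tumour and laboratory tables.

Formats
-------
* Pedigree: standard 6-column PED (family, individual, father, mother,
  sex, phenotype).  Both tab- and space-delimited files are accepted;
  ``0`` or an empty field denotes a missing parent; sex is coded 1/2/0
  for male/female/unknown.  The phenotype placeholder column is used to
  mark the proband: value ``2`` on exactly one row per family.
* Tumours: TSV with header ``individual_id  site  age_at_diagnosis
  tumor_index``.  Sites outside the recognised list map to ``other``
  with a logged warning (they never count as LS-associated).
* Lab results: TSV with header ``proband_id  mmr_functional
  ihc_pattern  braf_v600e  screened_genes  mutation_gene
  variant_class``; set-valued fields are semicolon-joined.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .types import (
    Individual,
    LabResult,
    Pedigree,
    TumorRecord,
    TUMOR_SITES,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SEX_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODE.items()}

TUMOR_COLUMNS = ["individual_id", "site", "age_at_diagnosis", "tumor_index"]
LAB_COLUMNS = [
    "proband_id",
    "mmr_functional",
    "ihc_pattern",
    "braf_v600e",
    "screened_genes",
    "mutation_gene",
    "variant_class",
]


def _missing(token: str) -> bool:
    return token in ("", "0", "NA", "nan")


def parse_ped(ped_path: PathLike, tumors_path: PathLike) -> list[Pedigree]:
    """Parse a PED file plus its tumour table into validated pedigrees.

    Raises :class:`ValidationError` on dangling parent references,
    cyclic parentage, duplicate (individual, tumor_index) pairs, tumours
    for unknown individuals, or families without exactly one proband.
    """
    ped = pd.read_csv(
        ped_path, sep=r"\s+", header=None, dtype=str, comment="#"
    ).fillna("")
    if ped.shape[1] < 6:
        raise ValidationError(
            f"PED file needs >= 6 columns, found {ped.shape[1]}"
        )
    tumors = read_tumor_table(tumors_path)

    individuals: dict[str, Individual] = {}
    families: dict[str, list[str]] = {}
    for row in ped.itertuples(index=False):
        fid, iid, father, mother, sex, pheno = (str(v).strip() for v in row[:6])
        if iid in individuals:
            raise ValidationError(f"duplicate individual id {iid!r}")
        individuals[iid] = Individual(
            individual_id=iid,
            family_id=fid,
            father_id=None if _missing(father) else father,
            mother_id=None if _missing(mother) else mother,
            sex=_SEX_CODE.get(sex, "unknown"),
            is_proband=(pheno == "2"),
        )
        families.setdefault(fid, []).append(iid)

    for rec in tumors:
        if rec.individual_id not in individuals:
            raise ValidationError(
                f"tumor record for unknown individual {rec.individual_id!r}"
            )
        individuals[rec.individual_id].tumors.append(rec)
    for ind in individuals.values():
        ind.tumors.sort(key=lambda t: (t.tumor_index, t.age_at_diagnosis))

    pedigrees = []
    for fid in sorted(families):
        members = {iid: individuals[iid] for iid in families[fid]}
        probands = [i for i in members.values() if i.is_proband]
        if len(probands) != 1:
            raise ValidationError(
                f"family {fid}: expected exactly one proband row "
                f"(phenotype column = 2), found {len(probands)}"
            )
        pedigrees.append(
            Pedigree(family_id=fid, individuals=members,
                     proband_id=probands[0].individual_id)
        )
    return pedigrees


def read_tumor_table(path: PathLike) -> list[TumorRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing_cols = set(TUMOR_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(
            f"tumor table missing columns {sorted(missing_cols)}"
        )
    records: list[TumorRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        site = str(row.site).strip()
        if site not in TUMOR_SITES:
            logger.warning(
                "row %d: tumor site %r not recognised, mapped to 'other' "
                "(not LS-associated)", i, site,
            )
            site = "other"
        try:
            rec = TumorRecord(
                individual_id=str(row.individual_id).strip(),
                site=site,
                age_at_diagnosis=int(row.age_at_diagnosis),
                tumor_index=int(row.tumor_index) if str(row.tumor_index) else 1,
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"tumor table row {i}: {exc}") from exc
        key = (rec.individual_id, rec.tumor_index)
        if key in seen:
            raise ValidationError(
                f"duplicate (individual_id, tumor_index) = {key}"
            )
        seen.add(key)
        records.append(rec)
    return records


def parse_lab_results(path: PathLike) -> dict[str, LabResult]:
    """Parse the per-proband laboratory results TSV.

    Proband ids are not cross-checked against any pedigree here; the
    join happens at pipeline time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing_cols = set(LAB_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"lab table missing columns {sorted(missing_cols)}")
    out: dict[str, LabResult] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.proband_id).strip()
        if pid in out:
            raise ValidationError(f"lab table row {i}: duplicate proband {pid!r}")
        ihc = str(row.ihc_pattern).strip()
        genes = str(row.screened_genes).strip()
        try:
            out[pid] = LabResult(
                proband_id=pid,
                mmr_functional=str(row.mmr_functional).strip() or "not_done",
                ihc_pattern=(
                    frozenset(g.strip() for g in ihc.split(";") if g.strip())
                    if ihc else None
                ),
                braf_v600e=str(row.braf_v600e).strip() or "not_done",
                screened_genes=tuple(
                    g.strip() for g in genes.split(";") if g.strip()
                ),
                mutation_gene=str(row.mutation_gene).strip() or None,
                variant_class=str(row.variant_class).strip() or None,
            )
        except ValidationError as exc:
            raise ValidationError(f"lab table row {i}: {exc}") from exc
    return out


def write_ped(pedigrees: Iterable[Pedigree], path: PathLike) -> None:
    rows = []
    for ped in pedigrees:
        for iid in sorted(ped.individuals):
            ind = ped.individuals[iid]
            rows.append(
                [
                    ped.family_id,
                    ind.individual_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _SEX_TO_CODE[ind.sex],
                    "2" if ind.is_proband else "1",
                ]
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_tumor_table(pedigrees: Iterable[Pedigree], path: PathLike) -> None:
    rows = []
    for ped in pedigrees:
        for iid in sorted(ped.individuals):
            for t in ped.individuals[iid].tumors:
                rows.append(
                    [t.individual_id, t.site, t.age_at_diagnosis, t.tumor_index]
                )
    pd.DataFrame(rows, columns=TUMOR_COLUMNS).to_csv(path, sep="\t", index=False)


def write_lab_results(results: dict[str, LabResult], path: PathLike) -> None:
    rows = []
    for pid in sorted(results):
        r = results[pid]
        rows.append(
            [
                r.proband_id,
                r.mmr_functional,
                ";".join(sorted(r.ihc_pattern)) if r.ihc_pattern else "",
                r.braf_v600e,
                ";".join(r.screened_genes),
                r.mutation_gene or "",
                r.variant_class or "",
            ]
        )
    pd.DataFrame(rows, columns=LAB_COLUMNS).to_csv(path, sep="\t", index=False)


def cohort_to_json(
    pedigrees: Iterable[Pedigree], lab: dict[str, LabResult], path: PathLike
) -> None:
    """Serialize a validated cohort as a single JSON document."""
    doc = {
        "pedigrees": [
            {
                "family_id": p.family_id,
                "proband_id": p.proband_id,
                "individuals": [
                    {
                        "individual_id": i.individual_id,
                        "father_id": i.father_id,
                        "mother_id": i.mother_id,
                        "sex": i.sex,
                        "is_proband": i.is_proband,
                        "tumors": [
                            {
                                "site": t.site,
                                "age_at_diagnosis": t.age_at_diagnosis,
                                "tumor_index": t.tumor_index,
                            }
                            for t in i.tumors
                        ],
                    }
                    for _, i in sorted(p.individuals.items())
                ],
            }
            for p in pedigrees
        ],
        "lab_results": [
            {
                "proband_id": r.proband_id,
                "mmr_functional": r.mmr_functional,
                "ihc_pattern": sorted(r.ihc_pattern) if r.ihc_pattern else None,
                "braf_v600e": r.braf_v600e,
                "screened_genes": list(r.screened_genes),
                "mutation_gene": r.mutation_gene,
                "variant_class": r.variant_class,
            }
            for _, r in sorted(lab.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def cohort_from_json(path: PathLike) -> tuple[list[Pedigree], dict[str, LabResult]]:
    doc = json.loads(Path(path).read_text())
    pedigrees = []
    for p in doc["pedigrees"]:
        individuals = {}
        for i in p["individuals"]:
            individuals[i["individual_id"]] = Individual(
                individual_id=i["individual_id"],
                family_id=p["family_id"],
                father_id=i["father_id"],
                mother_id=i["mother_id"],
                sex=i["sex"],
                is_proband=i["is_proband"],
                tumors=[
                    TumorRecord(
                        individual_id=i["individual_id"],
                        site=t["site"],
                        age_at_diagnosis=t["age_at_diagnosis"],
                        tumor_index=t["tumor_index"],
                    )
                    for t in i["tumors"]
                ],
            )
        pedigrees.append(
            Pedigree(
                family_id=p["family_id"],
                individuals=individuals,
                proband_id=p["proband_id"],
            )
        )
    lab = {
        r["proband_id"]: LabResult(
            proband_id=r["proband_id"],
            mmr_functional=r["mmr_functional"],
            ihc_pattern=(
                frozenset(r["ihc_pattern"]) if r["ihc_pattern"] else None
            ),
            braf_v600e=r["braf_v600e"],
            screened_genes=tuple(r["screened_genes"]),
            mutation_gene=r["mutation_gene"],
            variant_class=r["variant_class"],
        )
        for r in doc["lab_results"]
    }
    return pedigrees, lab
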