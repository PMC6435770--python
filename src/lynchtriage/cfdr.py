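"""The CFDR statistic: cluster of first-degree relatives with the most
Lynch-syndrome-associated tumours, and its lowest age at diagnosis (LAD).

Definitions
-----------
* First-degree relative: parent, child, or full sibling (both parents
  shared).  Half-siblings are second-degree; spouses are never relatives.
* A candidate cluster is a connected component of the first-degree-
  relationship graph restricted to affected individuals (>= 1
  LS-associated tumour) lying within a single family branch.  The
  proband, the proband's full siblings and descendants are "nuclear" and
  belong to both the maternal and the paternal branch subgraph.
* The CFDR is the candidate cluster maximising the number of
  LS-associated tumours, counting metachronous/synchronous primaries
  independently.  Ties break deterministically: lower LAD, then fewer
  members, then lexicographically smallest member-id set, then branch
  name.
* The LAD of a cluster is the minimum age at diagnosis over the
  cluster's own LS-associated tumours, further lowered (never raised) by
  affected second-degree relatives of the proband in the same family
  branch (grandparents, grandchildren, aunts/uncles, nieces/nephews,
  half-siblings).
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .types import CFDRResult, Pedigree


def first_degree_edges(p: Pedigree) -> set[frozenset[str]]:
    """Unordered pairs of first-degree relatives: parent-child and
    full-sibling pairs.  Spouses share no edge."""
    edges: set[frozenset[str]] = set()
    inds = p.individuals
    for ind in inds.values():
        for parent in (ind.father_id, ind.mother_id):
            if parent is not None:
                edges.add(frozenset({ind.individual_id, parent}))
    ids = sorted(inds)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ia, ib = inds[a], inds[b]
            if (
                ia.father_id is not None
                and ia.mother_id is not None
                and ia.father_id == ib.father_id
                and ia.mother_id == ib.mother_id
            ):
                edges.add(frozenset({a, b}))
    return edges


def ancestor_set(p: Pedigree, iid: str) -> set[str]:
    """Ancestors of ``iid`` including ``iid`` itself."""
    out: set[str] = set()
    stack = [iid]
    while stack:
        cur = stack.pop()
        if cur in out:
            continue
        out.add(cur)
        stack.extend(p._parents(cur))
    return out


def branch_of(p: Pedigree, iid: str) -> str:
    """Assign a family branch relative to the proband.

    Blood relationship means a shared ancestor (inclusive of self), so
    a spouse marrying in is unrelated even though the shared child
    links them in the family graph.  A relative whose shared ancestors
    with the proband all lie on the mother's side is maternal, on the
    father's side paternal; the proband, its descendants, and relatives
    anchored on both sides at once (full siblings and their
    descendants) are nuclear.
    """
    pr = p.proband
    if iid == p.proband_id:
        return "nuclear"
    anc_x = ancestor_set(p, iid)
    if p.proband_id in anc_x:
        return "nuclear"  # descendant of the proband
    shared = anc_x & ancestor_set(p, p.proband_id)
    if not shared:
        return "unrelated"
    maternal_side = ancestor_set(p, pr.mother_id) if pr.mother_id else set()
    paternal_side = ancestor_set(p, pr.father_id) if pr.father_id else set()
    m = bool(shared & maternal_side)
    f = bool(shared & paternal_side)
    if m and not f:
        return "maternal"
    if f and not m:
        return "paternal"
    return "nuclear"


def branch_map(p: Pedigree) -> dict[str, str]:
    return {iid: branch_of(p, iid) for iid in p.individuals}


def enumerate_clusters(p: Pedigree) -> list[tuple[frozenset[str], str]]:
    """Candidate clusters: per branch, connected components of affected
    individuals under first-degree edges.

    Returns (member set, branch) pairs; a member set arising identically
    in both branch subgraphs (all-nuclear membership) is merged into a
    single candidate labelled ``nuclear``.
    """
    affected = set(p.affected_ids())
    if not affected:
        raise ValueError(
            f"family {p.family_id}: no LS-associated tumor in pedigree"
        )
    branches = branch_map(p)
    edges = first_degree_edges(p)
    per_branch: dict[frozenset[str], set[str]] = {}
    for b in ("maternal", "paternal"):
        nodes = {i for i in affected if branches[i] in (b, "nuclear")}
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            if e <= nodes:
                g.add_edge(*sorted(e))
        for comp in nx.connected_components(g):
            per_branch.setdefault(frozenset(comp), set()).add(b)
    # affected individuals on no branch (unrelated to the proband by
    # blood, e.g. an affected spouse) are intentionally not clustered
    if not per_branch:
        raise ValueError(
            f"family {p.family_id}: no affected blood relative of the proband"
        )
    out = []
    for members, bs in per_branch.items():
        label = "nuclear" if len(bs) == 2 else next(iter(bs))
        out.append((members, label))
    out.sort(key=lambda c: (sorted(c[0]), c[1]))
    return out


def score_cluster(p: Pedigree, members: Iterable[str]) -> tuple[int, int]:
    """(tumor_count, internal_min_age) over the members' LS-associated
    tumours; metachronous/synchronous primaries count independently."""
    records = [
        t
        for iid in members
        for t in p.individuals[iid].ls_tumors
    ]
    if not records:
        raise ValueError("cluster has no LS-associated tumors")
    return len(records), min(t.age_at_diagnosis for t in records)


def second_degree_ids(p: Pedigree) -> set[str]:
    """Second-degree relatives of the proband: grandparents,
    grandchildren, aunts/uncles, nieces/nephews, half-siblings."""
    inds = p.individuals
    pr = p.proband

    def parents(iid: str) -> list[str]:
        i = inds[iid]
        return [x for x in (i.father_id, i.mother_id) if x is not None]

    def children(iid: str) -> list[str]:
        return [
            c.individual_id
            for c in inds.values()
            if iid in (c.father_id, c.mother_id)
        ]

    def full_sibs(iid: str) -> list[str]:
        i = inds[iid]
        if i.father_id is None or i.mother_id is None:
            return []
        return [
            s.individual_id
            for s in inds.values()
            if s.individual_id != iid
            and s.father_id == i.father_id
            and s.mother_id == i.mother_id
        ]

    out: set[str] = set()
    my_parents = parents(pr.individual_id)
    for par in my_parents:
        out.update(parents(par))        # grandparents
        out.update(full_sibs(par))      # aunts / uncles
    for child in children(pr.individual_id):
        out.update(children(child))     # grandchildren
    for sib in full_sibs(pr.individual_id):
        out.update(children(sib))       # nieces / nephews
    for s in inds.values():             # half-siblings: exactly one shared parent
        if s.individual_id == pr.individual_id:
            continue
        shared = len(
            {x for x in (s.father_id, s.mother_id) if x is not None}
            & set(my_parents)
        )
        both_shared = (
            s.father_id == pr.father_id
            and s.mother_id == pr.mother_id
            and s.father_id is not None
            and s.mother_id is not None
        )
        if shared == 1 and not both_shared:
            out.add(s.individual_id)
    out.discard(pr.individual_id)
    return out


def compute_lad(p: Pedigree, cluster: Iterable[str], branch: str) -> int:
    """Cluster LAD: internal minimum age, lowered by affected
    second-degree relatives of the proband in the same branch (or the
    nuclear core).  A ``nuclear`` cluster draws on both branches."""
    members = set(cluster)
    _, internal_min = score_cluster(p, members)
    if branch in ("maternal", "paternal"):
        allowed = {branch, "nuclear"}
    else:
        allowed = {"maternal", "paternal", "nuclear"}
    branches = branch_map(p)
    lad = internal_min
    for iid in second_degree_ids(p):
        if iid in members or branches[iid] not in allowed:
            continue
        ind = p.individuals[iid]
        for t in ind.ls_tumors:
            lad = min(lad, t.age_at_diagnosis)
    return lad


def select_cfdr(p: Pedigree) -> CFDRResult:
    """Pick the CFDR: the candidate cluster with the most LS-associated
    tumours, deterministic tie-breaking by lower LAD, fewer members,
    lexicographic member ids, branch name."""
    candidates = enumerate_clusters(p)
    scored = []
    for members, branch in candidates:
        count, _ = score_cluster(p, members)
        lad = compute_lad(p, members, branch)
        scored.append((members, branch, count, lad))
    members, branch, count, lad = min(
        scored,
        key=lambda c: (-c[2], c[3], len(c[0]), sorted(c[0]), c[1]),
    )
    return CFDRResult(
        proband_id=p.proband_id,
        member_ids=members,
        tumor_count=count,
        lad=lad,
        branch=branch,
    )
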