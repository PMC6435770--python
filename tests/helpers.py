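"""Shared test utilities: pedigree builders and independent brute-force
oracles (kept free of the implementation paths they check)."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from lynchtriage.types import Individual, Pedigree, TumorRecord


def build_pedigree(rows, tumors=(), family_id="FAM1", proband=None):
    """Compact pedigree builder.

    rows: iterable of (iid, father, mother, sex); tumors: iterable of
    (iid, site, age) or (iid, site, age, index).  The proband defaults
    to the first row.
    """
    individuals = {}
    for iid, father, mother, sex in rows:
        individuals[iid] = Individual(
            individual_id=iid,
            family_id=family_id,
            father_id=father,
            mother_id=mother,
            sex=sex,
        )
    proband = proband or rows[0][0]
    individuals[proband].is_proband = True
    counters = {}
    for t in tumors:
        iid, site, age = t[:3]
        idx = t[3] if len(t) > 3 else counters.get(iid, 0) + 1
        counters[iid] = idx
        individuals[iid].tumors.append(
            TumorRecord(individual_id=iid, site=site, age_at_diagnosis=age,
                        tumor_index=idx)
        )
    return Pedigree(family_id=family_id, individuals=individuals, proband_id=proband)


def random_small_pedigree(rng: np.random.Generator, max_members: int = 8) -> Pedigree:
    """Random pedigree of <= max_members around a proband trio, with
    random grandparents / siblings / uncles / children and random
    LS-associated and 'other' tumours.  At least one individual is
    guaranteed affected."""
    has_pat_gp = rng.random() < 0.5
    has_mat_gp = rng.random() < 0.5
    rows = [
        ("PB", "FA", "MO", "female"),
        ("FA", "GFP" if has_pat_gp else None, "GMP" if has_pat_gp else None, "male"),
        ("MO", "GFM" if has_mat_gp else None, "GMM" if has_mat_gp else None, "female"),
    ]
    if has_pat_gp:
        rows += [("GFP", None, None, "male"), ("GMP", None, None, "female")]
    if has_mat_gp:
        rows += [("GFM", None, None, "male"), ("GMM", None, None, "female")]
    extras = []
    for k in range(int(rng.integers(0, 3))):
        extras.append((f"S{k}", "FA", "MO", "male"))
    if rng.random() < 0.4:
        extras.append(("PU0", "GFP", "GMP", "male"))
    if rng.random() < 0.4:
        extras.append(("MU0", "GFM", "GMM", "female"))
    if rng.random() < 0.3:
        extras.append(("CH0", None, "PB", "male"))
    if rng.random() < 0.2:
        extras.append(("HS0", "FA", None, "female"))
    rng.shuffle(extras)
    for r in extras:
        if len(rows) >= max_members:
            break
        fa, mo = r[1], r[2]
        have = {x[0] for x in rows}
        if (fa is None or fa in have) and (mo is None or mo in have):
            rows.append(r)

    sites = ["colorectal", "rectal", "endometrial", "gastric"]
    tumors = []
    for iid, _, _, _ in rows:
        if rng.random() < 0.5:
            for k in range(int(rng.integers(1, 3))):
                tumors.append(
                    (iid, sites[int(rng.integers(0, len(sites)))],
                     int(rng.integers(20, 81)), k + 1)
                )
        elif rng.random() < 0.2:
            tumors.append((iid, "other", int(rng.integers(20, 81)), 9))
    if not any(t[1] != "other" for t in tumors):
        tumors.append(("PB", "colorectal", int(rng.integers(25, 61)), 5))
    return build_pedigree(rows, tumors)


# ---------------------------------------------------------------- oracles


def oracle_first_degree_pairs(p: Pedigree) -> set[frozenset]:
    """Pairwise predicate over all pairs: parent-child or full sibling."""
    out = set()
    inds = p.individuals
    for a, b in combinations(sorted(inds), 2):
        ia, ib = inds[a], inds[b]
        parent_child = b in (ia.father_id, ia.mother_id) or a in (
            ib.father_id, ib.mother_id
        )
        full_sib = (
            None not in (ia.father_id, ia.mother_id)
            and ia.father_id == ib.father_id
            and ia.mother_id == ib.mother_id
        )
        if parent_child or full_sib:
            out.add(frozenset({a, b}))
    return out


def oracle_branch(p: Pedigree, iid: str) -> str:
    """Branch via exhaustive enumeration of genealogical paths.

    A blood path from the proband to a relative climbs to ancestors and
    then descends (up* down*); paths that change direction more than
    once pass "through" a spouse and are not kinship.  The oracle
    enumerates every simple path in the parent-child graph, keeps the
    genealogical ones, and classifies by whether all of them run
    through the proband's mother or father.
    """
    if iid == p.proband_id:
        return "nuclear"
    g = nx.Graph()
    g.add_nodes_from(p.individuals)
    parent_of = {}
    for ind in p.individuals.values():
        for parent in (ind.father_id, ind.mother_id):
            if parent is not None:
                g.add_edge(ind.individual_id, parent)
                parent_of.setdefault(ind.individual_id, set()).add(parent)

    def genealogical(path):
        descending = False
        for a, b in zip(path, path[1:]):
            up = b in parent_of.get(a, ())
            if up and descending:
                return False
            if not up:
                descending = True
        return True

    if not nx.has_path(g, p.proband_id, iid):
        return "unrelated"
    paths = [
        path
        for path in nx.all_simple_paths(g, p.proband_id, iid)
        if genealogical(path)
    ]
    if not paths:
        return "unrelated"
    pr = p.proband
    thru_mother = pr.mother_id is not None and all(
        pr.mother_id in path[1:] for path in paths
    )
    thru_father = pr.father_id is not None and all(
        pr.father_id in path[1:] for path in paths
    )
    if thru_mother and not thru_father:
        return "maternal"
    if thru_father and not thru_mother:
        return "paternal"
    return "nuclear"


def oracle_best_cluster(p: Pedigree) -> tuple[int, list[frozenset]]:
    """Exhaustive enumeration of every single-branch, first-degree-
    connected affected subset; returns the maximal LS-tumour count and
    all subsets attaining it."""
    affected = [i for i in sorted(p.individuals) if p.individuals[i].affected]
    pairs = oracle_first_degree_pairs(p)
    branches = {i: oracle_branch(p, i) for i in affected}

    def tumor_count(subset):
        return sum(len(p.individuals[i].ls_tumors) for i in subset)

    def connected(subset):
        if len(subset) == 1:
            return True
        g = nx.Graph()
        g.add_nodes_from(subset)
        for pair in pairs:
            if pair <= subset:
                g.add_edge(*sorted(pair))
        return nx.is_connected(g)

    def single_branch(subset):
        bs = {branches[i] for i in subset}
        if "unrelated" in bs:
            return False
        return not ({"maternal", "paternal"} <= bs)

    best, winners = 0, []
    for r in range(1, len(affected) + 1):
        for combo in combinations(affected, r):
            s = frozenset(combo)
            if not (single_branch(s) and connected(s)):
                continue
            c = tumor_count(s)
            if c > best:
                best, winners = c, [s]
            elif c == best:
                winners.append(s)
    return best, winners


def oracle_mann_whitney(x, y):
    """Brute-force two-tailed permutation Mann-Whitney for tie-free
    samples: U by direct pair counting, p by exhaustive relabelling."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    mean = n1 * n2 / 2.0
    d_obs = abs(u_obs - mean)
    total = extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean) >= d_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total
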