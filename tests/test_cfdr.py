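"""CFDR statistic: first-degree graph, branches, clusters, LAD, selection."""

import numpy as np
import pytest

from helpers import (
    build_pedigree,
    oracle_best_cluster,
    oracle_branch,
    oracle_first_degree_pairs,
    random_small_pedigree,
)
from lynchtriage.cfdr import (
    branch_of,
    compute_lad,
    enumerate_clusters,
    first_degree_edges,
    score_cluster,
    select_cfdr,
)


class TestFirstDegreeEdges:
    def test_trio_has_no_spouse_edge(self, trio):
        edges = first_degree_edges(trio)
        assert edges == {frozenset({"F1", "C1"}), frozenset({"M1", "C1"})}

    def test_full_vs_half_siblings(self):
        p = build_pedigree(
            rows=[("A", "F", "M", "male"), ("B", "F", "M", "female"),
                  ("H", "F", None, "male"), ("F", None, None, "male"),
                  ("M", None, None, "female")],
            tumors=[("A", "colorectal", 40)],
        )
        edges = first_degree_edges(p)
        assert frozenset({"A", "B"}) in edges          # full siblings
        assert frozenset({"A", "H"}) not in edges      # half siblings
        assert frozenset({"H", "F"}) in edges          # still child of F

    def test_matches_pairwise_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            p = random_small_pedigree(rng, max_members=10)
            assert first_degree_edges(p) == oracle_first_degree_pairs(p)


class TestBranchOf:
    def test_definitional_cases(self, three_generation):
        p = three_generation
        assert branch_of(p, "GMM") == "maternal"   # maternal grandmother
        assert branch_of(p, "GFP") == "paternal"
        assert branch_of(p, "SB") == "nuclear"     # full sibling
        assert branch_of(p, "MO") == "maternal"
        assert branch_of(p, "AUNT") == "maternal"
        assert branch_of(p, "COUSIN") == "maternal"
        assert branch_of(p, "AUNT_HUSB") == "unrelated"  # married in

    def test_matches_path_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            p = random_small_pedigree(rng, max_members=10)
            for iid in p.individuals:
                assert branch_of(p, iid) == oracle_branch(p, iid), iid


class TestEnumerateClusters:
    def test_only_proband_affected_single_nuclear_candidate(self, trio):
        clusters = enumerate_clusters(trio)
        assert clusters == [(frozenset({"C1"}), "nuclear")]

    def test_chain_within_maternal_branch(self):
        p = build_pedigree(
            rows=[("PB", "FA", "MO", "female"), ("FA", None, None, "male"),
                  ("MO", "GFM", "GMM", "female"), ("GFM", None, None, "male"),
                  ("GMM", None, None, "female")],
            tumors=[("PB", "colorectal", 44), ("MO", "endometrial", 50),
                    ("GMM", "colorectal", 55)],
        )
        clusters = enumerate_clusters(p)
        assert (frozenset({"PB", "MO", "GMM"}), "maternal") in clusters

    def test_no_cluster_spans_both_branches(self):
        p = build_pedigree(
            rows=[("PB", "FA", "MO", "female"), ("FA", None, None, "male"),
                  ("MO", None, None, "female")],
            tumors=[("PB", "colorectal", 44), ("MO", "colorectal", 50),
                    ("FA", "colorectal", 52)],
        )
        members = {frozenset(m) for m, _ in enumerate_clusters(p)}
        assert members == {frozenset({"PB", "MO"}), frozenset({"PB", "FA"})}

    def test_no_affected_individual_raises(self):
        p = build_pedigree(
            rows=[("PB", None, None, "male")], tumors=[("PB", "other", 50)]
        )
        with pytest.raises(ValueError, match="no LS-associated"):
            enumerate_clusters(p)


class TestScoreCluster:
    def test_metachronous_tumors_count_independently(self):
        p = build_pedigree(
            rows=[("PB", None, None, "female")],
            tumors=[("PB", "colorectal", 45, 1), ("PB", "endometrial", 52, 2)],
        )
        assert score_cluster(p, {"PB"}) == (2, 45)

    def test_other_site_contributes_zero(self):
        p = build_pedigree(
            rows=[("PB", "FA", "MO", "male"), ("FA", None, None, "male"),
                  ("MO", None, None, "female")],
            tumors=[("PB", "colorectal", 50), ("FA", "other", 30)],
        )
        assert score_cluster(p, {"PB", "FA"})[0] == 1

    def test_indicator_sum_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = random_small_pedigree(rng)
            members = set(p.affected_ids())
            if not members:
                continue
            expect = sum(
                1
                for iid in members
                for t in p.individuals[iid].tumors
                if t.site != "other"
            )
            count, _ = score_cluster(p, members)
            assert count == expect


class TestComputeLad:
    def build(self, aunt_branch_parents, aunt_age=41):
        return build_pedigree(
            rows=[("PB", "FA", "MO", "female"),
                  ("FA", "GFP", "GMP", "male"), ("MO", "GFM", "GMM", "female"),
                  ("GFP", None, None, "male"), ("GMP", None, None, "female"),
                  ("GFM", None, None, "male"), ("GMM", None, None, "female"),
                  ("AUNT", *aunt_branch_parents, "female")],
            tumors=[("PB", "colorectal", 48), ("AUNT", "colorectal", aunt_age)],
        )

    def test_second_degree_same_branch_lowers_lad(self):
        p = self.build(("GFM", "GMM"))  # maternal aunt
        assert compute_lad(p, {"PB"}, "maternal") == 41

    def test_no_affected_second_degree_identity(self, trio):
        assert compute_lad(trio, {"C1"}, "maternal") == 45

    def test_opposite_branch_does_not_lower(self):
        maternal_aunt = self.build(("GFM", "GMM"))
        paternal_aunt = self.build(("GFP", "GMP"))
        assert compute_lad(maternal_aunt, {"PB"}, "paternal") == 48
        assert compute_lad(paternal_aunt, {"PB"}, "paternal") == 41


class TestSelectCfdr:
    def test_strict_max_tumor_count(self):
        p = build_pedigree(
            rows=[("PB", "FA", "MO", "female"), ("FA", None, None, "male"),
                  ("MO", None, None, "female")],
            tumors=[("PB", "colorectal", 44, 1),
                    ("MO", "colorectal", 50, 1), ("MO", "endometrial", 55, 2),
                    ("FA", "colorectal", 52, 1)],
        )
        r = select_cfdr(p)
        assert r.member_ids == frozenset({"PB", "MO"})
        assert r.tumor_count == 3
        assert r.branch == "maternal"

    def test_tie_broken_by_lower_lad(self):
        p = build_pedigree(
            rows=[("PB", "FA", "MO", "female"), ("FA", None, None, "male"),
                  ("MO", None, None, "female")],
            tumors=[("PB", "colorectal", 51, 1),
                    ("MO", "colorectal", 44, 1),
                    ("FA", "colorectal", 46, 1)],
        )
        r = select_cfdr(p)
        # both two-member clusters have 2 tumours; maternal LAD 44 < 46
        assert r.member_ids == frozenset({"PB", "MO"})
        assert r.lad == 44

    def test_determinism_and_result_invariants(self):
        rng = np.random.default_rng(99)
        ages = set()
        for _ in range(40):
            p = random_small_pedigree(rng)
            r1, r2 = select_cfdr(p), select_cfdr(p)
            assert r1 == r2
            assert r1.tumor_count >= 1
            ages = {
                t.age_at_diagnosis
                for i in p.individuals.values()
                for t in i.tumors
            }
            assert r1.lad in ages

    def test_monotone_under_added_tumor(self):
        """Adding an LS tumour to a selected member never decreases the
        count and never raises the LAD."""
        from lynchtriage.types import TumorRecord

        rng = np.random.default_rng(5)
        for _ in range(30):
            p = random_small_pedigree(rng)
            before = select_cfdr(p)
            target = sorted(before.member_ids)[0]
            ind = p.individuals[target]
            ind.tumors.append(
                TumorRecord(
                    individual_id=target, site="gastric",
                    age_at_diagnosis=int(rng.integers(20, 81)),
                    tumor_index=max((t.tumor_index for t in ind.tumors), default=0) + 1,
                )
            )
            after = select_cfdr(p)
            assert after.tumor_count >= before.tumor_count + 1
            assert after.lad <= before.lad

    def test_agrees_with_exhaustive_subset_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            p = random_small_pedigree(rng, max_members=8)
            best, winners = oracle_best_cluster(p)
            r = select_cfdr(p)
            assert r.tumor_count == best
            assert r.member_ids in winners
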