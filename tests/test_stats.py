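"""Mann-Whitney U wrapper and cohort summaries."""

import numpy as np
import pytest

from helpers import oracle_mann_whitney
from lynchtriage.stats import (
    compare_by_mmr_status,
    mann_whitney_u,
    round_percent,
    summarize,
)
from lynchtriage.types import CFDRResult, LabResult


class TestMannWhitney:
    def test_identical_multisets_symmetric(self):
        r = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.u_statistic == 8.0  # n1*n2/2
        assert r.p_value == 1.0

    def test_fully_separated_small_samples(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.u_statistic in (0.0, 9.0)
        assert r.method == "exact_permutation"
        assert r.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings

    def test_matches_brute_force_oracle_small_samples(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            r = mann_whitney_u(x, y)
            u_o, p_o = oracle_mann_whitney(x, y)
            assert r.u_statistic == pytest.approx(u_o)
            assert r.p_value == pytest.approx(p_o)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n1, n2 = int(rng.integers(5, 10)), int(rng.integers(5, 10))
            pooled = rng.choice(10_000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            exact = mann_whitney_u(x, y)
            approx = mann_whitney_u(x, y, exact_limit=0)
            assert exact.method == "exact_permutation"
            assert approx.method == "normal_approximation"
            assert abs(exact.p_value - approx.p_value) < 0.02

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_within_bounds_and_method_recorded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r = mann_whitney_u(x, y)
        assert 0 <= r.u_statistic <= r.n1 * r.n2
        assert r.method == "normal_approximation"  # 900 pairs > exact limit


def test_round_percent_half_away_from_zero():
    assert round_percent(12.5) == 13
    assert round_percent(42.105) == 42
    assert round_percent(-12.5) == -13
    assert round_percent(65.38) == 65


class TestSummarize:
    def test_reproduces_marginal_fixture_fractions(self, marginal_cohort):
        cfdr, lab = marginal_cohort
        s = summarize(cfdr, lab)
        assert (s.n_probands, s.n_mmr_tested) == (372, 368)
        assert (s.n_mmr_deficient, s.n_screened, s.n_mutation) == (92, 114, 48)
        d = s.to_dict()
        assert d["pct_deficient_of_tested"] == 25
        assert d["pct_mutation_of_screened"] == 42
        assert d["pct_mutation_of_cohort"] == 13
        assert d["per_gene_share_pct"] == {"MLH1": 31, "MSH2": 46, "MSH6": 21, "PMS2": 2}

    def test_order_independent(self, marginal_cohort):
        cfdr, lab = marginal_cohort
        a = summarize(cfdr, lab)
        b = summarize(list(reversed(cfdr)), dict(reversed(list(lab.items()))))
        assert a == b

    def test_empty_cohort(self):
        s = summarize([], {})
        assert s.n_probands == 0
        assert s.frac_deficient_of_tested is None
        assert s.to_dict()["pct_mutation_of_cohort"] is None

    def test_singleton_per_gene_means_are_identities(self):
        cfdr, lab = [], {}
        for k, (g, age) in enumerate(
            [("MLH1", 37), ("MSH2", 39), ("MSH6", 42), ("PMS2", 44)]
        ):
            pid = f"P{k}"
            cfdr.append(
                CFDRResult(proband_id=pid, member_ids=frozenset({pid}),
                           tumor_count=k + 1, lad=age, branch="nuclear")
            )
            lab[pid] = LabResult(
                proband_id=pid, mmr_functional="deficient",
                screened_genes=(g,), mutation_gene=g, variant_class="pathogenic",
            )
        s = summarize(cfdr, lab)
        assert s.per_gene_mean_lad == {"MLH1": 37, "MSH2": 39, "MSH6": 42, "PMS2": 44}
        assert s.per_gene_mean_tumor_count == {"MLH1": 1, "MSH2": 2, "MSH6": 3, "PMS2": 4}


class TestCompareByMmrStatus:
    def build(self, deficient_feats, proficient_feats):
        cfdr, lab = [], {}
        for k, (status, (tc, lad)) in enumerate(
            [("deficient", f) for f in deficient_feats]
            + [("proficient", f) for f in proficient_feats]
        ):
            pid = f"P{k}"
            cfdr.append(
                CFDRResult(proband_id=pid, member_ids=frozenset({pid}),
                           tumor_count=tc, lad=lad, branch="nuclear")
            )
            lab[pid] = LabResult(proband_id=pid, mmr_functional=status)
        return cfdr, lab

    def test_identical_groups_p_one(self):
        feats = [(2, 45), (3, 50), (1, 40)]
        cfdr, lab = self.build(feats, feats)
        tests = compare_by_mmr_status(cfdr, lab)
        assert tests["tumor_count"].p_value == 1.0
        assert tests["lad"].p_value == 1.0

    def test_empty_group_raises(self):
        cfdr, lab = self.build([(2, 45)], [])
        with pytest.raises(ValueError):
            compare_by_mmr_status(cfdr, lab)

    def test_direction_reported(self):
        cfdr, lab = self.build(
            [(4, 30), (5, 35), (6, 28)], [(1, 60), (1, 65), (2, 62)]
        )
        tests = compare_by_mmr_status(cfdr, lab)
        assert tests["tumor_count"].median_diff > 0
        assert tests["lad"].median_diff < 0


def test_null_calibration_type_one_error():
    """Rejection rate at nominal alpha=0.05 stays within 3 Monte-Carlo
    SEs over 400 independent null replicates (and below 0.07)."""
    rng = np.random.default_rng(314)
    reps = 400
    rejections = 0
    for _ in range(reps):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        if mann_whitney_u(x, y).p_value < 0.05:
            rejections += 1
    rate = rejections / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert rate <= 0.07
    assert 0.05 - 3 * se <= rate <= 0.05 + 3 * se
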