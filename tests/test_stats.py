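import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from adhesivect.phantom import load_table1_fixture
from adhesivect.stats import (
    WidthRecord,
    mann_whitney_u,
    summarize,
    width_range,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(a, b):
    d = (np.asarray(b, float) - np.asarray(a, float))
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    obs = ranks[d > 0].sum()
    hits = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            hits += 1
    return hits / 2 ** len(d)


def brute_force_mwu_p(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ranks = rankdata(np.concatenate([a, b]))
    na, n = a.size, a.size + b.size
    mu = na * (n + 1) / 2.0
    obs = ranks[:na].sum()
    hits = total = 0
    for comb in itertools.combinations(range(n), na):
        ra = ranks[list(comb)].sum()
        total += 1
        if abs(ra - mu) >= abs(obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestWidthTables:
    def test_reported_group_ranges(self):
        records = load_table1_fixture()
        assert width_range(records, 4, "microct") == (0.011, 0.032)
        assert width_range(records, 1, "microscopy") == (0.021, 0.29)

    def test_single_record_degenerate_range(self):
        rec = [WidthRecord(1, 1, "oral", "microct", 0.05)]
        assert width_range(rec, 1, "microct") == (0.05, 0.05)

    def test_no_matching_records(self):
        with pytest.raises(ValueError, match="no records"):
            width_range([], 1, "microct")

    def test_summary_against_hand_arithmetic(self):
        records = load_table1_fixture()
        widths = [r.width for r in records
                  if r.group == 4 and r.method == "microct" and r.area == "vestibular"]
        s = summarize([r for r in records if r.group == 4], "microct", "vestibular")
        assert s["n"] == 5
        assert s["mean"] == pytest.approx(sum(widths) / 5)
        assert s["min"] == min(widths) and s["max"] == max(widths)

    def test_constant_summary(self):
        rec = [WidthRecord(1, i + 1, "oral", "microct", 0.05) for i in range(4)]
        s = summarize(rec, "microct", "oral")
        assert s["sd"] == 0.0 and s["min"] == s["max"] == s["mean"] == 0.05

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match=">= 2 records"):
            summarize([], "microct", "oral")

    def test_invalid_record_fields(self):
        with pytest.raises(ValueError, match="area"):
            WidthRecord(1, 1, "lingual", "microct", 0.05)
        with pytest.raises(ValueError, match="width"):
            WidthRecord(1, 1, "oral", "microct", -0.1)


class TestWilcoxonSignedRank:
    def test_identical_pairs_give_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.verdict == "is"

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            n = int(rng.integers(5, 11))
            a = rng.integers(0, 6, n).astype(float)
            b = rng.integers(0, 6, n).astype(float)
            if np.all(a == b):
                continue
            res = wilcoxon_signed_rank(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_signed_rank_p(a, b), abs=1e-12)

    def test_one_sided_structure_visible(self):
        a = [1.0, 2, 3, 4, 5, 6]
        b = [2.0, 3, 4, 5, 6, 7]
        res = wilcoxon_signed_rank(a, b)
        assert res.arms["negative"]["n"] == 0
        assert res.arms["positive"]["rank_sum"] == 21.0  # 6 * 7 / 2

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 40)
        b = a + rng.normal(0.2, 1.0, 40)
        res = wilcoxon_signed_rank(a, b, exact=False)
        expected = wilcoxon(b, a, correction=False, mode="approx").pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_exact_vs_asymptotic_agreement(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(0, 1, 11)
            b = a + rng.normal(0.3, 1, 11)
            p_exact = wilcoxon_signed_rank(a, b, exact=True).p_value
            p_asym = wilcoxon_signed_rank(a, b, exact=False).p_value
            assert abs(p_exact - p_asym) < 0.05

    @given(st.lists(st.integers(0, 9), min_size=6, max_size=14))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rank_sum_conservation(self, deltas):
        a = np.zeros(len(deltas))
        b = np.array(deltas, dtype=float)
        m = int(np.sum(b != 0))
        if m == 0:
            return
        res = wilcoxon_signed_rank(a, b)
        total = res.arms["negative"]["rank_sum"] + res.arms["positive"]["rank_sum"]
        assert total == pytest.approx(m * (m + 1) / 2)


class TestMannWhitneyU:
    def test_identical_samples(self):
        res = mann_whitney_u([1, 2, 3, 7, 8, 9], [1, 2, 3, 7, 8, 9])
        assert res.statistic == pytest.approx(18.0)  # n_a n_b / 2
        assert res.p_value == 1.0

    def test_complete_separation(self):
        res = mann_whitney_u([1.0, 2, 3], [4.0, 5, 6])
        assert res.statistic == 0.0

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(12):
            na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            a = rng.integers(0, 8, na).astype(float)
            b = rng.integers(0, 8, nb).astype(float)
            res = mann_whitney_u(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.10, 0.05, 30)
        b = rng.normal(0.07, 0.05, 30)
        res = mann_whitney_u(a, b)
        expected = mannwhitneyu(a, b, use_continuity=False, method="asymptotic").pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_reported_effect_sizes_flag_significance(self):
        """Group 1 vs Group 4 vestibular effect (0.136±0.096 vs 0.024±0.008,
        n=30) is detected at alpha=0.05 in nearly every replicate."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = np.abs(rng.normal(0.136, 0.096, 30)) + 1e-6
            b = np.abs(rng.normal(0.024, 0.008, 30)) + 1e-6
            hits += mann_whitney_u(a, b).significant
        assert hits / n_rep >= 0.95

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0, 2.0])

    def test_table_layout_fields_present(self):
        res = mann_whitney_u([0.1, 0.2, 0.3, 0.4], [0.05, 0.06, 0.07, 0.08])
        arm = res.arms["a"]
        assert arm.n == 4
        assert arm.rank_sum == pytest.approx(arm.mean_rank * 4)
        d = res.to_dict()
        assert {"test", "statistic", "p_value", "significant"} <= set(d)
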