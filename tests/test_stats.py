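"""Exact 2x2 statistics: point probabilities, Fisher tests, percentages."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs
from scipy.stats import fisher_exact

from memtube.scenarios import EventTable, paper_event_tables
from memtube.stats import (
    PAPER_COMPARISONS,
    ContingencyTable2x2,
    analyze_all,
    compare_conditions,
    fisher_two_sided,
    fission_percentage,
    hypergeom_point_prob,
)


def enumeration_two_sided(a, b, c, d):
    """Independent oracle: exact enumeration with integer combinatorics."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    denom = comb(n, k)
    probs = {x: comb(r1, x) * comb(r2, k - x)
             for x in range(max(0, k - r2), min(r1, k) + 1)}
    obs = probs[a]
    total = sum(v for v in probs.values() if v <= obs)
    return total / denom


class TestPointProbability:
    def test_three_by_three_margins(self):
        # C(3,0) C(3,3) / C(6,3) = 1/20
        assert hypergeom_point_prob(0, 3, 3, 3) == pytest.approx(1 / 20)

    def test_pmf_normalises(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r1, r2 = rng.integers(1, 40, 2)
            k = int(rng.integers(0, r1 + r2 + 1))
            lo, hi = max(0, k - r2), min(r1, k)
            total = sum(hypergeom_point_prob(x, r1, r2, k)
                        for x in range(lo, hi + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_margins_symmetric_pmf(self):
        for a in range(0, 6):
            assert hypergeom_point_prob(a, 5, 5, 5) == pytest.approx(
                hypergeom_point_prob(5 - a, 5, 5, 5), abs=1e-14)

    def test_infeasible_cell_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_point_prob(4, 3, 3, 3)


class TestFisherTwoSided:
    def test_shigella_wt_vs_crispr_bound(self):
        res = fisher_two_sided(ContingencyTable2x2(13, 10, 0, 50))
        assert res.p_two_sided < 1e-7

    def test_mode_table_gives_one(self):
        assert fisher_two_sided(ContingencyTable2x2(5, 5, 5, 5)).p_two_sided == 1.0

    def test_small_enumerated_table(self):
        # all four feasible tables have point prob <= 9/20 => p = 1
        assert fisher_two_sided(ContingencyTable2x2(2, 1, 1, 2)).p_two_sided \
            == pytest.approx(1.0)

    def test_degenerate_margins_give_one(self):
        assert fisher_two_sided(ContingencyTable2x2(0, 0, 3, 7)).p_two_sided == 1.0
        assert fisher_two_sided(ContingencyTable2x2(0, 5, 0, 7)).p_two_sided == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(10_000):
            n = int(rng.integers(1, 31))
            a_, b_, c_ = sorted(rng.integers(0, n + 1, 3))
            a, b, c, d = a_, b_ - a_, c_ - b_, n - c_
            mine = fisher_two_sided(ContingencyTable2x2(a, b, c, d)).p_two_sided
            oracle = enumeration_two_sided(a, b, c, d)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_matches_scipy_on_paper_sized_tables(self):
        cases = [(13, 10, 0, 50), (13, 10, 0, 19), (36, 5, 10, 31),
                 (67, 17, 10, 62), (77, 13, 36, 52), (67, 17, 46, 74),
                 (16, 2, 8, 24), (34, 4, 18, 3)]
        for a, b, c, d in cases:
            mine = fisher_two_sided(ContingencyTable2x2(a, b, c, d)).p_two_sided
            ref = fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, 4)
            if a + b + c + d == 0:
                continue
            p = fisher_two_sided(ContingencyTable2x2(a, b, c, d)).p_two_sided
            assert fisher_two_sided(
                ContingencyTable2x2(c, d, a, b)).p_two_sided == pytest.approx(p)
            assert fisher_two_sided(
                ContingencyTable2x2(b, a, d, c)).p_two_sided == pytest.approx(p)

    def test_moving_toward_mode_never_decreases_p(self):
        # fixed margins (10, 10; 10): a from extreme to mode
        ps = [fisher_two_sided(
            ContingencyTable2x2(a, 10 - a, 10 - a, a)).p_two_sided
            for a in range(0, 6)]
        assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(len(ps) - 1))

    def test_type_one_error_conservative(self):
        # equal-p binomial nulls: rejection rate at 0.05 must not exceed
        # nominal (the exact test is conservative)
        rng = np.random.default_rng(3)
        n1, n2, p = 25, 30, 0.35
        rejections = 0
        reps = 2000
        for _ in range(reps):
            k1 = rng.binomial(n1, p)
            k2 = rng.binomial(n2, p)
            t = ContingencyTable2x2(k1, n1 - k1, k2, n2 - k2)
            if fisher_two_sided(t).p_two_sided < 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps <= 0.05 + 3 * se

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


@given(hs.integers(0, 12), hs.integers(0, 12), hs.integers(0, 12),
       hs.integers(0, 12))
@settings(max_examples=250, deadline=None, derandomize=True)
def test_fisher_invariants_hold_for_any_table(a, b, c, d):
    """p in [point_prob, 1], invariant under row and column swaps."""
    if a + b + c + d == 0:
        return
    res = fisher_two_sided(ContingencyTable2x2(a, b, c, d))
    assert res.point_prob - 1e-12 <= res.p_two_sided <= 1.0
    for swapped in ((c, d, a, b), (b, a, d, c)):
        assert fisher_two_sided(
            ContingencyTable2x2(*swapped)).p_two_sided == pytest.approx(
            res.p_two_sided, abs=1e-12)


class TestPercentages:
    @pytest.mark.parametrize("n, k, expected", [
        (23, 13, 56.5),   # wild-type Shigella
        (50, 0, 0.0),     # DRP1 CRISPR
        (120, 46, 38.3),  # MFF siRNA on vinyl (printed as 38%)
        (84, 67, 79.8),   # scrambled vinyl (printed as 80%)
        (38, 34, 89.5),   # ATL1-K80A (printed as 89%)
        (21, 18, 85.7),   # CLIMP-63 (printed as 86%)
        (7, 7, 100.0),
    ])
    def test_one_decimal_convention(self, n, k, expected):
        t = EventTable("x", n, k)
        assert fission_percentage(t) == expected

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            fission_percentage(EventTable("x", 0, 0))


class TestCompareConditions:
    def test_wt_vs_crispr(self):
        wt = EventTable("wt", 23, 13)
        ko = EventTable("ko", 50, 0)
        assert compare_conditions(wt, ko).p_two_sided < 1e-7

    def test_wt_vs_sirna(self):
        wt = EventTable("wt", 23, 13)
        kd = EventTable("kd", 19, 0)
        assert compare_conditions(wt, kd).p_two_sided < 1e-4

    def test_identical_conditions_give_one(self):
        t = EventTable("t", 30, 12)
        assert compare_conditions(t, t).p_two_sided == pytest.approx(1.0)


class TestAnalyzeAll:
    def test_fixture_has_the_printed_counts(self):
        tables = {t.label: t for t in paper_event_tables()}
        assert (tables["shigella_wt"].n_events,
                tables["shigella_wt"].n_positive) == (23, 13)
        assert (tables["shigella_drp1_crispr"].n_events,
                tables["shigella_drp1_crispr"].n_positive) == (50, 0)
        assert (tables["vinyl_scrambled"].n_events,
                tables["vinyl_scrambled"].n_positive) == (84, 67)
        assert all(t.provenance == "paper_fixture"
                   for t in tables.values())

    def test_key_comparison_row_satisfies_bound(self):
        df = analyze_all(paper_event_tables())
        row = df[(df.condition_1 == "shigella_wt")
                 & (df.condition_2 == "shigella_drp1_crispr")].iloc[0]
        assert row.p_two_sided < 1e-7
        assert bool(row.bound_satisfied)

    def test_deterministic_output(self):
        a = analyze_all(paper_event_tables()).to_csv(index=False)
        b = analyze_all(paper_event_tables()).to_csv(index=False)
        assert a == b

    def test_empty_comparison_list(self):
        df = analyze_all(paper_event_tables(), comparisons=())
        assert len(df) == 0
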