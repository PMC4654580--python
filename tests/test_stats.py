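"""Statistical tests against independent oracles."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from cystiquant.stats import (
    ContingencyTable,
    chi2_trend,
    compare_groups,
    fisher_exact_2x2,
    mann_whitney,
    spearman_rho,
)
from cystiquant.stats import TestResult as StatTestResult


def fisher_oracle(a, b, c, d):
    """Point-probability two-sided p by exact rational enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    total = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), total)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), total)
        if pk <= p_obs:
            p += pk
    return float(p)


def mann_whitney_oracle(a, b):
    """Two-sided exact p via rank-sum enumeration (tie-averaged ranks)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    n_le = n_ge = n_tot = 0
    for comb in combinations(range(len(pooled)), na):
        w = ranks[list(comb)].sum()
        n_tot += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / n_tot)


class TestFisher:
    def test_symmetric_table_p_one(self):
        res = fisher_exact_2x2(ContingencyTable.from_counts([[1, 1], [1, 1]]))
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # Only the two diagonal tables are as improbable: p = 2 / C(10,5)
        res = fisher_exact_2x2(ContingencyTable.from_counts([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / math.comb(10, 5), rel=1e-12)

    def test_printed_comparison_value(self):
        # plasma cell-rich area, NHIC (38 absent / 1 present) vs
        # HIC background biopsies (17 / 10)
        res = fisher_exact_2x2(ContingencyTable.from_counts([[38, 1], [17, 10]]))
        assert res.p_value == pytest.approx(0.0003, abs=5e-5)
        assert res.p_value == pytest.approx(fisher_oracle(38, 1, 17, 10), rel=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = fisher_exact_2x2(ContingencyTable.from_counts([[a, b], [c, d]]))
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours.p_value == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(ContingencyTable.from_counts([[1, 2, 3], [4, 5, 6]]))


class TestTrend:
    def test_equal_rows_no_trend(self):
        res = chi2_trend(ContingencyTable.from_counts([[5, 5, 5], [5, 5, 5]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_affine_score_invariance(self):
        t = ContingencyTable.from_counts([[33, 5, 1], [15, 7, 5]])
        base = chi2_trend(t)
        shifted = chi2_trend(t, scores=[10, 17, 24])
        assert base.statistic == pytest.approx(shifted.statistic, rel=1e-12)
        assert base.p_value == pytest.approx(shifted.p_value, rel=1e-12)

    def test_exact_conditional_agreement_small_table(self):
        """Chi-square p approximates the exact conditional (mid-p) tail."""
        tbl = np.array([[33, 5, 1], [15, 7, 5]])
        col = tbl.sum(axis=0)
        r1, n = int(tbl[0].sum()), int(tbl.sum())
        s = np.arange(3.0)
        t_obs, mean = float(tbl[0] @ s), r1 * (col @ s) / n
        d0 = abs(t_obs - mean)
        gt = eq = 0
        total = math.comb(n, r1)
        for a0 in range(min(col[0], r1) + 1):
            for a1 in range(min(col[1], r1 - a0) + 1):
                a2 = r1 - a0 - a1
                if a2 < 0 or a2 > col[2]:
                    continue
                w = (math.comb(col[0], a0) * math.comb(col[1], a1)
                     * math.comb(col[2], a2))
                dist = abs(a1 + 2.0 * a2 - mean)
                if dist > d0 + 1e-9:
                    gt += w
                elif abs(dist - d0) <= 1e-9:
                    eq += w
        mid_p = (gt + eq / 2) / total
        ours = chi2_trend(ContingencyTable.from_counts(tbl)).p_value
        assert ours == pytest.approx(mid_p, abs=0.01)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            chi2_trend(ContingencyTable.from_counts([[1, 2], [3, 4]]))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        # U = 0; the two extreme assignments out of C(6,3) = 20
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, rel=1e-12)

    def test_exact_matches_enumeration_oracle(self, rng):
        for na, nb in [(3, 3), (2, 7), (5, 4), (7, 7), (6, 3)]:
            for _ in range(4):
                a = rng.integers(0, 6, na).astype(float)  # ties likely
                b = rng.integers(0, 6, nb).astype(float)
                ours = mann_whitney(a, b).p_value
                assert ours == pytest.approx(mann_whitney_oracle(a, b), rel=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            a = rng.permutation(100)[:6].astype(float)
            b = (rng.permutation(100)[:7] + 0.5).astype(float)
            ours = mann_whitney(a, b).p_value
            ref = sps.mannwhitneyu(a, b, method="exact",
                                   alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(loc=0.5, size=15)
        p1 = mann_whitney(a, b).p_value
        p2 = mann_whitney(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3).statistic == pytest.approx(1.0)
        assert spearman_rho(x, -x - 5).statistic == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        ours = spearman_rho(x, y).statistic
        ref = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))[0]
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_constant_input_flagged(self):
        res = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.statistic)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])


class TestDispatch:
    def test_binary_goes_to_fisher(self):
        import pandas as pd
        df = pd.DataFrame({"g": ["x"] * 10 + ["y"] * 10,
                           "v": ["a", "b"] * 10})
        assert compare_groups(df, "v", "g").method == "fisher_exact"

    def test_ordinal_goes_to_trend(self):
        import pandas as pd
        df = pd.DataFrame({"g": ["x"] * 9 + ["y"] * 9,
                           "v": [0, 1, 2] * 6})
        assert compare_groups(df, "v", "g").method == "chi2_trend"

    def test_continuous_goes_to_mann_whitney(self, rng):
        import pandas as pd
        df = pd.DataFrame({"g": ["x"] * 10 + ["y"] * 10,
                           "v": rng.normal(size=20)})
        assert compare_groups(df, "v", "g").method.startswith("mann_whitney")


def test_p_value_range_enforced():
    with pytest.raises(ValueError):
        StatTestResult("m", 0.0, 1.5)
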