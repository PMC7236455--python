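"""Exact and classical tests against independent oracles.

The 2x2 Fisher oracle is a direct hypergeometric enumeration written here;
scipy's fisher_exact / mannwhitneyu / wilcoxon / f_oneway / spearmanr serve
as independent cross-checks of the bespoke implementations.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import gammaln

from cellloss.exact_tests import (
    ContingencyTable,
    anova_oneway,
    fisher_exact_2xk,
    spearman_correlation,
    wilcoxon_test,
)
from cellloss.exact_tests import _rank_sum_exact_distribution


def hypergeom_2x2_pvalue(a, b, c, d):
    """Oracle: enumerate all 2x2 tables with the observed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def logp(x):
        return (
            gammaln(c1 + 1) - gammaln(x + 1) - gammaln(c1 - x + 1)
            + gammaln(n - c1 + 1) - gammaln(r1 - x + 1) - gammaln(n - c1 - (r1 - x) + 1)
            - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
        )

    lp_obs = logp(a)
    total = 0.0
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        lp = logp(x)
        if lp <= lp_obs + 1e-12:
            total += math.exp(lp)
    return min(1.0, total)


class TestFisherExact:
    def test_balanced_2x2_is_one(self):
        assert fisher_exact_2xk(ContingencyTable.from_rows([5, 5], [5, 5])).p_value == 1.0

    def test_2x2_matches_enumeration_oracle(self):
        t = ContingencyTable.from_rows([3, 23], [12, 14])
        p = fisher_exact_2xk(t).p_value
        assert p == pytest.approx(hypergeom_2x2_pvalue(3, 23, 12, 14), rel=1e-10)
        # value frozen after cross-checking against R's fisher.test
        assert p == pytest.approx(0.01283044, abs=5e-8)

    def test_2x4_quartile_table_matches_reference(self):
        """Outcome-by-quartile table; reference value from R's fisher.test."""
        t = ContingencyTable.from_rows([3, 3, 6, 12], [23, 23, 20, 14])
        r = fisher_exact_2xk(t)
        assert r.p_value == pytest.approx(0.01406408, abs=5e-8)
        assert r.extra["tables_enumerated"] == 2925

    @pytest.mark.parametrize("seed", range(5))
    def test_random_2x2_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 30, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        mine = fisher_exact_2xk(ContingencyTable.from_rows([a, b], [c, d])).p_value
        ref = sps.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_invariant_under_column_permutation_and_row_swap(self):
        rows = ([3, 3, 6, 12], [23, 23, 20, 14])
        p0 = fisher_exact_2xk(ContingencyTable.from_rows(*rows)).p_value
        for perm in itertools.permutations(range(4)):
            r0 = [rows[0][j] for j in perm]
            r1 = [rows[1][j] for j in perm]
            assert fisher_exact_2xk(ContingencyTable.from_rows(r0, r1)).p_value == pytest.approx(
                p0, rel=1e-9
            )
        assert fisher_exact_2xk(ContingencyTable.from_rows(rows[1], rows[0])).p_value == (
            pytest.approx(p0, rel=1e-9)
        )

    def test_enumeration_probabilities_sum_to_one(self):
        """Conservation: total conditional probability over all tables is 1."""
        cols = (26, 26, 26, 26)
        r1 = 24
        n = sum(cols)
        logdenom = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
        total = 0.0
        for a in itertools.product(*(range(min(c, r1) + 1) for c in cols)):
            if sum(a) != r1:
                continue
            lp = sum(
                gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
                for x, c in zip(a, cols)
            ) - logdenom
            total += math.exp(lp)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_monotonicity_more_extreme_2x2_never_larger_p(self):
        """Shifting mass toward the diagonal (fixed margins) shrinks p."""
        prev = 1.1
        for a in range(13, 26):  # margins (26,26)x(26,26); a = diag count
            t = ContingencyTable.from_rows([a, 26 - a], [26 - a, a])
            p = fisher_exact_2xk(t).p_value
            assert p <= prev + 1e-12
            prev = p

    def test_zero_margin_degenerate(self):
        r = fisher_exact_2xk(ContingencyTable.from_rows([0, 0], [5, 7]))
        assert r.p_value == 1.0 and r.degenerate

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable.from_rows([-1, 2], [3, 4])

    def test_table_count_limit_guards_enumeration(self):
        t = ContingencyTable.from_rows([3, 3, 6, 12], [23, 23, 20, 14])
        with pytest.raises(RuntimeError, match="max_tables"):
            fisher_exact_2xk(t, max_tables=10)


class TestWilcoxon:
    def test_paired_identical_samples_degenerate(self):
        r = wilcoxon_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert r.p_value == 1.0 and r.degenerate

    def test_unpaired_fully_separated_exact(self):
        """All 20 rank assignments enumerated: two extreme ones -> p = 0.1."""
        r = wilcoxon_test([1, 2, 3], [4, 5, 6])
        assert r.method == "wilcoxon_rank_sum_exact"
        assert r.p_value == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_unpaired_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=rng.integers(3, 9))
        y = rng.normal(size=rng.integers(3, 9))
        mine = wilcoxon_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mine.method == "wilcoxon_rank_sum_exact"
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_paired_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(200 + seed)
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        mine = wilcoxon_test(x, y, paired=True)
        ref = sps.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert mine.method == "wilcoxon_signed_rank_exact"
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_normal_branches_agree_for_n15(self):
        """Full exact null (counting recurrence) vs the approximation, 15 vs 15."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=15)
            y = rng.normal(0.5, 1.0, size=15)
            approx = wilcoxon_test(x, y)  # min(n,m)=15 -> normal branch
            assert approx.method == "wilcoxon_rank_sum_normal"
            counts = _rank_sum_exact_distribution(15, 15)
            sums = np.arange(counts.size, dtype=float)
            mu = 15 * 31 / 2.0
            w = approx.statistic
            exact_p = counts[np.abs(sums - mu) >= abs(w - mu) - 1e-9].sum() / counts.sum()
            assert approx.p_value == pytest.approx(exact_p, abs=0.02)

    def test_ties_fall_back_to_corrected_normal(self):
        r = wilcoxon_test([1, 1, 2, 2], [2, 3, 3, 4])
        assert r.method == "wilcoxon_rank_sum_normal"
        ref = sps.mannwhitneyu([1, 1, 2, 2], [2, 3, 3, 4], alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestAnova:
    def test_identical_groups_degenerate_p_one(self):
        r = anova_oneway([[1, 1], [1, 1]])
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.degenerate

    def test_zero_within_variance_unequal_means_p_zero(self):
        r = anova_oneway([[1, 1], [2, 2]])
        assert r.p_value == 0.0 and r.degenerate

    def test_hand_anova_table(self):
        """SSB=6 (df 2), SSW=6 (df 6) -> F=3, p=0.125."""
        r = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert r.statistic == pytest.approx(3.0)
        assert r.p_value == pytest.approx(0.125, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_f_oneway(self, seed):
        rng = np.random.default_rng(300 + seed)
        groups = [rng.normal(m, 1.0, size=rng.integers(3, 12)) for m in (0.0, 0.3, 0.9)]
        mine = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_binary_response_by_factor_interface(self):
        """pCR 0/1 response across 4 factor levels yields a valid p per covariate."""
        rng = np.random.default_rng(9)
        groups = [(rng.random(26) < 0.2).astype(float) for _ in range(4)]
        r = anova_oneway(groups)
        assert 0.0 <= r.p_value <= 1.0 and r.n_used == 104


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_correlation(x, x).statistic == pytest.approx(1.0)
        assert spearman_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho = spearman_correlation(x, y).statistic
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(400 + seed)
        x = rng.integers(0, 5, size=20).astype(float)
        y = x + rng.normal(size=20)
        mine = spearman_correlation(x, y)
        ref = sps.spearmanr(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
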