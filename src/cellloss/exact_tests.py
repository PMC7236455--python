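"""Inferential tests used by the pipeline.

All tests are implemented here from first principles — the Freeman–Halton
extension of Fisher's exact test to 2xk tables by full enumeration of the
conditional (multivariate hypergeometric) distribution, the Wilcoxon
signed-rank and rank-sum tests with exact small-sample null distributions,
one-way ANOVA, and Spearman rank correlation.  scipy supplies only the
reference distributions (hypergeometric tail sums are never delegated).
Everything is two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats as _sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "TestResult",
    "fisher_exact_2xk",
    "wilcoxon_test",
    "anova_oneway",
    "spearman_correlation",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2xk grid of non-negative integer counts."""

    counts: tuple[tuple[int, ...], tuple[int, ...]]
    row_labels: tuple[str, ...] = ("row0", "row1")
    col_labels: tuple[str, ...] | None = None

    @classmethod
    def from_rows(cls, row0, row1, row_labels=("row0", "row1"), col_labels=None):
        r0 = tuple(int(v) for v in row0)
        r1 = tuple(int(v) for v in row1)
        if len(r0) != len(r1) or len(r0) < 2:
            raise ValueError("table must be 2xk with k >= 2")
        if any(v < 0 for v in r0 + r1):
            raise ValueError("counts must be non-negative")
        return cls(counts=(r0, r1), row_labels=tuple(row_labels), col_labels=col_labels)

    @property
    def k(self) -> int:
        return len(self.counts[0])

    def col_sums(self) -> tuple[int, ...]:
        return tuple(a + b for a, b in zip(*self.counts))

    def row_sums(self) -> tuple[int, int]:
        return (sum(self.counts[0]), sum(self.counts[1]))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (two-sided)."""

    p_value: float
    method: str
    n_used: int
    statistic: float | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "degenerate": self.degenerate,
        }
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# Freeman–Halton exact test


def _log_table_prob(a: tuple[int, ...], cols: tuple[int, ...], logdenom: float) -> float:
    # P(a) = prod_j C(c_j, a_j) / C(N, r1)
    s = 0.0
    for aj, cj in zip(a, cols):
        s += gammaln(cj + 1) - gammaln(aj + 1) - gammaln(cj - aj + 1)
    return s - logdenom


def fisher_exact_2xk(table: ContingencyTable, max_tables: int = 10_000_000) -> TestResult:
    """Two-sided Fisher / Freeman–Halton exact test on a 2xk table.

    Conditions on both margins and enumerates every 2xk table with the
    observed margins; the p-value is the total multivariate-hypergeometric
    probability of tables no more likely than the observed one (relative
    tolerance 1e-12 when comparing probabilities).  For k=2 this reduces to
    the usual two-sided Fisher exact test.
    """
    cols = table.col_sums()
    r1, r2 = table.row_sums()
    n = r1 + r2
    if r1 == 0 or r2 == 0 or all(c == 0 for c in cols):
        return TestResult(
            p_value=1.0,
            method="fisher_exact_2xk",
            n_used=n,
            degenerate=True,
        )
    # drop all-zero columns: they carry no information
    keep = [j for j, c in enumerate(cols) if c > 0]
    cols = tuple(cols[j] for j in keep)
    obs = tuple(table.counts[0][j] for j in keep)

    logdenom = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(r2 + 1)
    log_p_obs = _log_table_prob(obs, cols, logdenom)
    threshold = log_p_obs + 1e-12

    k = len(cols)
    suffix = [0] * (k + 1)  # suffix[j] = sum of cols[j:]
    for j in range(k - 1, -1, -1):
        suffix[j] = suffix[j + 1] + cols[j]

    total = 0.0
    count = 0
    a = [0] * k

    def dfs(j: int, remaining: int) -> None:
        nonlocal total, count
        if j == k - 1:
            if remaining > cols[j]:
                return
            a[j] = remaining
            count += 1
            if count > max_tables:
                raise RuntimeError(
                    f"enumeration exceeds max_tables={max_tables}; "
                    "increase the limit or use a coarser table"
                )
            lp = _log_table_prob(tuple(a), cols, logdenom)
            if lp <= threshold:
                total += math.exp(lp)
            return
        lo = max(0, remaining - suffix[j + 1])
        hi = min(cols[j], remaining)
        for v in range(lo, hi + 1):
            a[j] = v
            dfs(j + 1, remaining - v)

    dfs(0, r1)
    return TestResult(
        p_value=min(1.0, total),
        method="fisher_exact_2xk",
        n_used=n,
        extra={"tables_enumerated": count},
    )


# ---------------------------------------------------------------------------
# Wilcoxon tests

_EXACT_PAIRED_N = 12
_EXACT_UNPAIRED_MIN = 10


def _midranks(x: np.ndarray) -> np.ndarray:
    return _sps.rankdata(x, method="average")


def wilcoxon_test(x, y, paired: bool = False) -> TestResult:
    """Two-sided Wilcoxon test: signed-rank (paired) or rank-sum (unpaired).

    Paired: zero differences are dropped; the exact permutation null (all
    2^n sign assignments) is used for effective n <= 12, otherwise the
    normal approximation with midrank tie correction and a 0.5 continuity
    correction.  Unpaired: the exact rank-sum null (subset-counting
    recurrence) is used when min(n, m) <= 10 and the data are tie-free,
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape or x.size == 0:
            raise ValueError("paired samples must be equal-length and non-empty")
        return _signed_rank(x, y)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return _rank_sum(x, y)


def _signed_rank(x: np.ndarray, y: np.ndarray) -> TestResult:
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(
            p_value=1.0, method="wilcoxon_signed_rank", n_used=0, statistic=0.0, degenerate=True
        )
    r = _midranks(np.abs(d))
    w_plus = float(r[d > 0].sum())
    mu = r.sum() / 2.0

    if n <= _EXACT_PAIRED_N:
        # full enumeration of sign assignments on the (mid)ranks
        dev_obs = abs(w_plus - mu)
        hits = 0
        for signs in product((0, 1), repeat=n):
            w = float(sum(ri for ri, s in zip(r, signs) if s))
            if abs(w - mu) >= dev_obs - 1e-9:
                hits += 1
        p = hits / 2**n
        method = "wilcoxon_signed_rank_exact"
    else:
        var = float(np.sum(r**2)) / 4.0
        diff = w_plus - mu
        cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
        z = (diff - cc) / math.sqrt(var)
        p = 2.0 * _sps.norm.sf(abs(z))
        method = "wilcoxon_signed_rank_normal"
    return TestResult(p_value=min(1.0, p), method=method, n_used=n, statistic=w_plus)


def _rank_sum_exact_distribution(n: int, m: int) -> np.ndarray:
    """Counts of subsets of ranks {1..n+m} of size n by rank sum (no ties)."""
    big_n = n + m
    max_sum = n * big_n  # loose upper bound on the statistic
    # f[j][s]: number of j-subsets of {1..i} with sum s, built incrementally
    f = np.zeros((n + 1, max_sum + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, big_n + 1):
        for j in range(min(i, n), 0, -1):
            f[j, i:] += f[j - 1, : max_sum - i + 1]
    return f[n]


def _rank_sum(x: np.ndarray, y: np.ndarray) -> TestResult:
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    w = float(ranks[:n].sum())
    big_n = n + m
    mu = n * (big_n + 1) / 2.0
    has_ties = np.unique(combined).size < big_n

    if min(n, m) <= _EXACT_UNPAIRED_MIN and not has_ties:
        counts = _rank_sum_exact_distribution(n, m)
        sums = np.arange(counts.size, dtype=float)
        total = counts.sum()
        dev_obs = abs(w - mu)
        p = counts[np.abs(sums - mu) >= dev_obs - 1e-9].sum() / total
        method = "wilcoxon_rank_sum_exact"
    else:
        _, t = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(t**3 - t)) / (big_n * (big_n - 1))
        var = n * m / 12.0 * ((big_n + 1) - tie_term)
        diff = w - mu
        cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
        if var <= 0:
            return TestResult(
                p_value=1.0, method="wilcoxon_rank_sum_normal", n_used=big_n,
                statistic=w, degenerate=True,
            )
        z = (diff - cc) / math.sqrt(var)
        p = 2.0 * _sps.norm.sf(abs(z))
        method = "wilcoxon_rank_sum_normal"
    return TestResult(p_value=min(1.0, p), method=method, n_used=big_n, statistic=w)


# ---------------------------------------------------------------------------
# One-way ANOVA


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Degenerate inputs: zero within-group variance with equal means -> p=1;
    with unequal means -> p=0 (both flagged).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    g = len(arrs)
    if g < 2 or any(a.size == 0 for a in arrs):
        raise ValueError("need >= 2 non-empty groups")
    n = sum(a.size for a in arrs)
    if n <= g:
        raise ValueError("total n must exceed the number of groups")
    grand = sum(a.sum() for a in arrs) / n
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = g - 1, n - g
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult(p_value=1.0, method="anova_oneway", n_used=n,
                              statistic=0.0, degenerate=True)
        return TestResult(p_value=0.0, method="anova_oneway", n_used=n,
                          statistic=math.inf, degenerate=True)
    f_stat = (ssb / df_b) / (ssw / df_w)
    p = float(_sps.f.sf(f_stat, df_b, df_w))
    return TestResult(p_value=p, method="anova_oneway", n_used=n, statistic=float(f_stat),
                      extra={"df": (df_b, df_w)})


# ---------------------------------------------------------------------------
# Spearman rank correlation


def spearman_correlation(x, y) -> TestResult:
    """Spearman rho with midrank ties; two-sided p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rho is undefined for a constant input")
    rx = _midranks(x)
    ry = _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return TestResult(p_value=min(1.0, p), method="spearman", n_used=n, statistic=rho)
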