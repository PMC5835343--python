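"""Nonparametric tests, effect sizes, and robust correlation.

Group contrasts use the Mann-Whitney U test (independent samples, effect
size r = |Z|/√N) and the Wilcoxon signed-rank test (paired, Z statistic).
Both switch to exact permutation enumeration at small sample sizes —
which, unlike the usual normal approximation, remains exact under ties —
and to the tie-corrected normal approximation otherwise.  Association
effect sizes are Φ for 2×2 tables and Cramér's V beyond; the robust
correlation ρ^G is the Gaussian rank (normal-scores) correlation,
invariant to strictly monotone transforms of either variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "wilcoxon_signed",
    "phi_coefficient",
    "cramers_v",
    "cohens_d",
    "gaussian_rank_correlation",
]

#: Largest pooled size for which Mann-Whitney enumerates all group
#: assignments; C(12, 6) = 924 cases.
MW_EXACT_MAX_N = 12
#: Largest n for which Wilcoxon enumerates all 2^n sign patterns.
WX_EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float  # U for Mann-Whitney, W+ for Wilcoxon
    z: float
    n: tuple[int, ...]
    p_value: float
    effect_size_name: str
    effect_size: float
    method: str  # "exact" or "normal"


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _mw_u(ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(ranks[idx_a].sum() - n_a * (n_a + 1) / 2)


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    U counts, over all cross-pairs, how often an ``a`` value exceeds a
    ``b`` value (ties count half).  For pooled sizes ≤ 12 the two-sided
    p-value enumerates every assignment of the pooled values to the
    groups (exact under ties); otherwise the tie-corrected normal
    approximation is used.  Effect size r = |Z|/√(n₁+n₂).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = _rank(pooled)
    u = _mw_u(ranks, slice(0, n1), n1)

    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = 0.0 if var == 0 else (u - mu) / np.sqrt(var)

    if n <= MW_EXACT_MAX_N:
        dev = abs(u - mu)
        count = total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(_mw_u(ranks, list(idx), n1) - mu) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        p = 2 * sps.norm.sf(abs(z))
        method = "normal"
    return TestResult(
        name="mann-whitney",
        statistic=u,
        z=z,
        n=(n1, n2),
        p_value=min(1.0, p),
        effect_size_name="r",
        effect_size=abs(z) / np.sqrt(n),
        method=method,
    )


def wilcoxon_signed(x) -> TestResult:
    """Wilcoxon signed-rank test of paired differences against zero.

    Zero differences are dropped; W⁺ sums the ranks of |x| over positive
    differences.  For n ≤ 10 the two-sided p-value enumerates all 2ⁿ sign
    patterns (exact under tied magnitudes); otherwise the tie-corrected
    normal approximation applies.  Effect size r = |Z|/√n.
    """
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    n = len(x)
    if n == 0:
        raise ValueError("all differences are zero; test degenerate")
    ranks = _rank(np.abs(x))
    w_plus = float(ranks[x > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(x), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    z = 0.0 if var == 0 else (w_plus - mu) / np.sqrt(var)

    if n <= WX_EXACT_MAX_N:
        dev = abs(w_plus - mu)
        count = 0
        for bits in range(2**n):
            signs = np.array([(bits >> i) & 1 for i in range(n)])
            w = float(ranks[signs == 1].sum())
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        p = count / 2**n
        method = "exact"
    else:
        p = 2 * sps.norm.sf(abs(z))
        method = "normal"
    return TestResult(
        name="wilcoxon-signed-rank",
        statistic=w_plus,
        z=z,
        n=(n,),
        p_value=min(1.0, p),
        effect_size_name="r",
        effect_size=abs(z) / np.sqrt(n),
        method=method,
    )


def _chi2(table: np.ndarray) -> float:
    stat, _, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat)


def phi_coefficient(table) -> float:
    """Φ = √(χ²/N) for a 2×2 contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("phi is defined for 2x2 tables")
    return float(np.sqrt(_chi2(table) / table.sum()))


def cramers_v(table) -> float:
    """Cramér's V = √(χ²/(N·(k−1))), k the smaller table dimension."""
    table = np.asarray(table, dtype=float)
    k = min(table.shape)
    if k < 2:
        raise ValueError("table needs at least two rows and columns")
    return float(np.sqrt(_chi2(table) / (table.sum() * (k - 1))))


def cohens_d(a, b) -> float:
    """Cohen's d: mean difference over the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance; d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def gaussian_rank_correlation(x, y) -> float:
    """ρ^G: Pearson correlation of normal scores Φ⁻¹(rank/(n+1)).

    A robust correlation index: invariant to strictly monotone transforms
    and insensitive to marginal outliers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    n = len(x)
    sx = sps.norm.ppf(_rank(x) / (n + 1))
    sy = sps.norm.ppf(_rank(y) / (n + 1))
    return float(np.corrcoef(sx, sy)[0, 1])
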