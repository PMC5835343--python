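"""Nonparametric tests against independent enumeration oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gamblerp.stats import (
    cohens_d,
    cramers_v,
    gaussian_rank_correlation,
    mann_whitney,
    phi_coefficient,
    wilcoxon_signed,
)


def brute_force_mw_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    mu = n1 * len(b) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        hits += abs(u_of(idx) - mu) >= obs - 1e-12
    return hits / total


def brute_force_wilcoxon_p(x):
    """Two-sided exact signed-rank p by enumerating sign patterns."""
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    ranks = sps.rankdata(np.abs(x))
    n = len(x)
    mu = n * (n + 1) / 4
    obs = abs(ranks[x > 0].sum() - mu)
    hits = 0
    for bits in range(2**n):
        w = sum(r for i, r in enumerate(ranks) if (bits >> i) & 1)
        hits += abs(w - mu) >= obs - 1e-12
    return hits / 2**n


class TestMannWhitney:
    def test_separated_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_near_zero_effect(self):
        res = mann_whitney([5] * 8, [5] * 8)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    @given(
        a=st.lists(st.integers(0, 6), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 6), min_size=1, max_size=5),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b):
        assert mann_whitney(a, b).p_value == pytest.approx(brute_force_mw_p(a, b))

    @given(
        a=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=5, unique=True),
        b=st.lists(st.floats(0.5, 99.5, allow_nan=False), min_size=2, max_size=5, unique=True),
    )
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_matches_scipy_without_ties(self, a, b):
        if set(a) & set(b):
            return
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_normal_branch(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        res = mann_whitney(a, b)
        assert res.method == "normal"
        ref = sps.mannwhitneyu(a, b, method="asymptotic", alternative="two-sided",
                               use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert 0 <= res.effect_size <= 1


class TestWilcoxon:
    def test_symmetric_differences_give_p_one(self):
        res = wilcoxon_signed([-2, -1, 1, 2])
        assert res.p_value == pytest.approx(1.0)

    def test_all_positive_minimal_p(self):
        res = wilcoxon_signed(list(range(1, 11)))
        assert res.p_value == pytest.approx(2 / 2**10)

    def test_sign_flip_antisymmetry(self):
        x = [3.0, -1.5, 2.0, 4.0, -0.5]
        assert wilcoxon_signed(x).z == pytest.approx(-wilcoxon_signed([-v for v in x]).z)

    def test_all_zero_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_signed([0.0, 0.0])

    @given(x=st.lists(st.integers(-5, 5).filter(bool), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_enumeration_oracle(self, x):
        assert wilcoxon_signed(x).p_value == pytest.approx(brute_force_wilcoxon_p(x))


class TestEffectSizes:
    def test_perfect_association(self):
        assert phi_coefficient([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_independence(self):
        assert phi_coefficient([[10, 10], [10, 10]]) == pytest.approx(0.0)

    def test_cramers_v_range(self):
        v = cramers_v([[8, 2, 1], [1, 7, 2], [2, 1, 9]])
        assert 0 <= v <= 1

    def test_cohens_d_unit_shift(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100_000)
        d = cohens_d(a + 1.0, a)
        assert d == pytest.approx(1.0, abs=0.02)

    def test_cohens_d_degenerate(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1], [1, 1])


class TestGaussianRankCorrelation:
    def test_monotone_transform_invariance(self):
        x = np.linspace(-2, 2, 40)
        assert gaussian_rank_correlation(x, np.exp(x)) == pytest.approx(1.0)
        assert gaussian_rank_correlation(x, -x) == pytest.approx(-1.0)

    def test_null_is_small(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(gaussian_rank_correlation(x, y)) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            gaussian_rank_correlation([1, 1, 1], [1, 2, 3])

    @given(
        x=st.lists(st.floats(-50, 50), min_size=5, max_size=20, unique=True),
    )
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_bounded(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(x))
        r = gaussian_rank_correlation(x, y)
        assert -1 <= r <= 1
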