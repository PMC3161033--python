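"""Exact-test correctness against independently coded enumeration oracles."""

from fractions import Fraction
from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from fluoromix import (
    paired_t_test,
    sem,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately different code paths from the package)


def midranks(values):
    """Average-of-positions ranks, written without scipy."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ranksum_oracle(g1, g2):
    """Exact two-sided p by enumerating every group-1 index set."""
    pooled = list(g1) + list(g2)
    ranks = midranks(pooled)
    n, n1 = len(pooled), len(g1)
    w_obs = sum(ranks[:n1])
    lo = hi = total = 0
    for idx in combinations(range(n), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
    return float(min(1, 2 * Fraction(min(lo, hi), total)))


def signedrank_oracle(diffs, zero_method="wilcoxon"):
    """Exact two-sided p by enumerating every sign pattern."""
    diffs = [d for d in diffs] if zero_method == "pratt" else [d for d in diffs if d != 0]
    ranks = midranks([abs(d) for d in diffs])
    kept = [(r, d) for r, d in zip(ranks, diffs) if d != 0]
    w_obs = sum(r for r, d in kept if d > 0)
    lo = hi = total = 0
    for signs in product((0, 1), repeat=len(kept)):
        w = sum(r for (r, _), s in zip(kept, signs) if s)
        total += 1
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
    return float(min(1, 2 * Fraction(min(lo, hi), total)))


def t_sf_by_quadrature(t, df):
    """P(T > t) from direct numerical integration of the t density."""
    from math import gamma, sqrt, pi

    c = gamma((df + 1) / 2) / (gamma(df / 2) * sqrt(df * pi))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    val, _ = quad(pdf, t, np.inf)
    return val


# ---------------------------------------------------------------------------


class TestPairedT:
    def test_identical_pairs(self):
        res = paired_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_symmetric_differences(self):
        res = paired_t_test([0.0, 2.0], [1.0, 1.0])  # differences {-1, 1}
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_statistic(self):
        # differences {1, 2, 3}: t = 2*sqrt(3), df = 2
        res = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.p_value == pytest.approx(2 * t_sf_by_quadrature(2 * np.sqrt(3), 2), abs=1e-9)

    def test_degenerate_constant_nonzero(self):
        res = paired_t_test([2.0, 3.0], [1.0, 2.0])
        assert res.p_value == 0.0 and res.warning is not None

    def test_closed_form_on_random_inputs(self, rng):
        for _ in range(25):
            n = rng.integers(3, 12)
            x, y = rng.normal(size=(2, n))
            d = x - y
            t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            res = paired_t_test(x, y)
            assert res.statistic == pytest.approx(t_hand, abs=1e-12)
            ref = sps.ttest_rel(x, y)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestRankSum:
    def test_complete_separation(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 252, abs=1e-15)

    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1.0, 2, 3], [1.0, 2, 3], mode="exact")
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle_5v5(self, rng):
        for _ in range(20):
            g1, g2 = rng.normal(size=(2, 5))
            res = wilcoxon_rank_sum(g1, g2)
            assert res.exact
            assert res.p_value == pytest.approx(ranksum_oracle(g1, g2), abs=1e-12)

    def test_exact_with_ties_matches_oracle(self, rng):
        for _ in range(10):
            g1 = rng.integers(0, 4, size=4).astype(float)
            g2 = rng.integers(0, 4, size=5).astype(float)
            res = wilcoxon_rank_sum(g1, g2, mode="exact")
            assert res.p_value == pytest.approx(ranksum_oracle(g1, g2), abs=1e-12)

    def test_group_swap_symmetry(self, rng):
        for _ in range(10):
            g1, g2 = rng.normal(size=(2, 5))
            assert wilcoxon_rank_sum(g1, g2).p_value == pytest.approx(
                wilcoxon_rank_sum(g2, g1).p_value, abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        for transform in (np.exp, lambda v: v**3, lambda v: 2 * v + 7):
            g1, g2 = rng.normal(size=(2, 5))
            p0 = wilcoxon_rank_sum(g1, g2).p_value
            p1 = wilcoxon_rank_sum(transform(g1), transform(g2)).p_value
            assert p0 == pytest.approx(p1, abs=1e-12)

    def test_scipy_cross_check_tie_free(self, rng):
        for _ in range(10):
            g1, g2 = rng.normal(size=(2, 6))
            p_pkg = wilcoxon_rank_sum(g1, g2, mode="exact").p_value
            p_scipy = sps.mannwhitneyu(g1, g2, method="exact").pvalue
            assert p_pkg == pytest.approx(p_scipy, abs=1e-12)

    def test_normal_mode_large_samples(self, rng):
        g1 = rng.normal(0, 1, 40)
        g2 = rng.normal(1, 1, 40)
        res = wilcoxon_rank_sum(g1, g2)
        assert not res.exact
        ref = sps.mannwhitneyu(g1, g2, method="asymptotic").pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-6)


class TestSignedRank:
    def test_all_positive_n4(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0])
        assert res.statistic == 10.0
        assert res.p_value == pytest.approx(2 / 16, abs=1e-15)

    def test_symmetric_pair(self):
        res = wilcoxon_signed_rank([-2.0, 2.0])
        assert res.p_value == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_matches_enumeration_oracle(self, rng):
        for n in range(2, 11):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            assert res.exact
            assert res.p_value == pytest.approx(signedrank_oracle(d), abs=1e-12)

    def test_zeros_dropped_by_default(self, rng):
        d = np.array([0.0, 1.5, -0.7, 0.0, 2.2])
        res = wilcoxon_signed_rank(d)
        assert res.n == (3,)
        assert res.p_value == pytest.approx(signedrank_oracle(d), abs=1e-12)

    def test_pratt_mode_matches_oracle(self):
        d = np.array([0.0, 1.0, -2.0, 3.0, 0.0, 4.0])
        res = wilcoxon_signed_rank(d, zero_method="pratt")
        assert res.p_value == pytest.approx(signedrank_oracle(d, "pratt"), abs=1e-12)

    def test_scipy_cross_check(self, rng):
        for _ in range(5):
            d = rng.normal(size=8)
            p_pkg = wilcoxon_signed_rank(d, mode="exact").p_value
            p_scipy = sps.wilcoxon(d, mode="exact").pvalue
            assert p_pkg == pytest.approx(p_scipy, abs=1e-12)


def test_sem_matches_definition(rng):
    v = rng.normal(size=11)
    assert sem(v) == pytest.approx(v.std(ddof=1) / np.sqrt(11), abs=1e-14)
    with pytest.raises(ValueError):
        sem([1.0])
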