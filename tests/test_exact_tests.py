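"""Unit and oracle tests for the exact-test kernels."""

import math
from fractions import Fraction
from math import comb, lgamma

import numpy as np
import pytest
from scipy import stats

from cistrans.exact_tests import (
    bh_adjust,
    binom_two_sided,
    binom_two_sided_vec,
    estimate_common_dispersion,
    fisher_two_sided,
    nb_conditional_pvalue,
)


def binom_oracle(k: int, n: int) -> float:
    """Exact-fraction enumeration of the two-sided binomial p at p = 1/2."""
    if n == 0:
        return 1.0
    row = [comb(n, i) for i in range(n + 1)]
    return float(Fraction(sum(w for w in row if w <= row[k]), 2**n))


class TestBinomial:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (15, 20, 2 * 21700 / 2**20),  # ~0.0414
            (5, 5, 2 / 32),
            (10, 20, 1.0),
            (7, 14, 1.0),
            (0, 0, 1.0),
        ],
    )
    def test_spot_values(self, k, n, expected):
        assert binom_two_sided(k, n) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        for n in (7, 20, 33):
            for k in range(n + 1):
                assert binom_two_sided(k, n) == pytest.approx(
                    binom_two_sided(n - k, n), abs=1e-14
                )

    def test_matches_enumeration_all_totals_to_60(self):
        for n in range(61):
            for k in range(n + 1):
                assert binom_two_sided(k, n) == pytest.approx(
                    binom_oracle(k, n), abs=1e-10
                )

    def test_matches_scipy_binomtest(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            ref = stats.binomtest(k, n, 0.5).pvalue
            assert binom_two_sided(k, n) == pytest.approx(ref, rel=1e-9)

    def test_vectorised_agrees_with_scalar(self, rng):
        n = rng.integers(0, 300, 200)
        k = np.array([rng.integers(0, m + 1) for m in n])
        vec = binom_two_sided_vec(k, n)
        for ki, ni, pi in zip(k, n, vec):
            assert pi == pytest.approx(binom_two_sided(ki, ni), abs=1e-12)

    def test_doubling_counts_never_increases_p(self):
        # fixed imbalance becomes more significant with depth
        for a, b in [(3, 2), (6, 4), (5, 1), (9, 7)]:
            last = 1.1
            for mult in (1, 2, 4, 8, 16):
                p = binom_two_sided(a * mult, (a + b) * mult)
                assert p <= last + 1e-12
                last = p


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 0, 0, 5), 2 / 252),
            ((10, 10, 10, 10), 1.0),
            ((3, 7, 3, 7), 1.0),
            ((12, 5, 12, 5), 1.0),
            ((0, 0, 3, 4), 1.0),  # zero margin
        ],
    )
    def test_spot_values(self, table, expected):
        assert fisher_two_sided(*table) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_small_totals(self):
        # exhaustive check on all tables with grand total <= 25; the full
        # scan to 60 runs in the acceptance suite
        for n in range(1, 26):
            for r in range(n + 1):
                row1 = [comb(r, x) for x in range(r + 1)]
                row2 = [comb(n - r, x) for x in range(n - r + 1)]
                for col in range(n + 1):
                    lo, hi = max(0, col - (n - r)), min(r, col)
                    if lo > hi:
                        continue
                    weights = [row1[x] * row2[col - x] for x in range(lo, hi + 1)]
                    tot = comb(n, col)
                    for a in range(lo, hi + 1):
                        if r in (0, n) or col in (0, n):
                            want = 1.0
                        else:
                            w_obs = weights[a - lo]
                            want = float(
                                Fraction(sum(w for w in weights if w <= w_obs), tot)
                            )
                        got = fisher_two_sided(a, r - a, col - a, n - r - col + a)
                        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_scipy_large_tables(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 600, 4))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_two_sided(a, b, c, d) == pytest.approx(ref, abs=1e-9)

    def test_row_and_column_swap_invariance(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 80, 4))
            p = fisher_two_sided(a, b, c, d)
            assert fisher_two_sided(c, d, a, b) == pytest.approx(p, abs=1e-12)
            assert fisher_two_sided(b, a, d, c) == pytest.approx(p, abs=1e-12)


def nb_oracle(y_a, y_b, n_a, n_b, phi) -> float:
    """Plain-python enumeration of the conditional NB test via lgamma."""
    t = y_a + y_b
    if t == 0:
        return 1.0
    r_a, r_b = n_a / phi, n_b / phi
    logw = [
        lgamma(k + r_a) - lgamma(k + 1) + lgamma(t - k + r_b) - lgamma(t - k + 1)
        for k in range(t + 1)
    ]
    mx = max(logw)
    w = [math.exp(v - mx) for v in logw]
    w_obs = w[y_a]
    return min(1.0, sum(v for v in w if v <= w_obs * (1 + 1e-7)) / sum(w))


class TestNBConditional:
    def test_balanced_split_is_modal(self):
        assert nb_conditional_pvalue(300, 300, 3, 3, 0.1) == 1.0
        assert nb_conditional_pvalue(0, 0, 3, 3, 0.1) == 1.0

    def test_poisson_limit_reduces_to_binomial(self):
        # dispersion 0, equal group sizes: 15 vs 5 gives the 0.0414 value
        p = nb_conditional_pvalue(15, 5, 3, 3, 0.0)
        assert p == pytest.approx(2 * 21700 / 2**20, abs=1e-12)

    def test_poisson_limit_unequal_sizes(self):
        p = nb_conditional_pvalue(15, 5, 2, 1, 0.0)
        k = np.arange(21)
        pmf = stats.binom.pmf(k, 20, 2 / 3)
        want = pmf[pmf <= pmf[15] * (1 + 1e-7)].sum()
        assert p == pytest.approx(want, rel=1e-9)

    def test_exchangeable_in_groups(self, rng):
        for _ in range(40):
            ya, yb = (int(x) for x in rng.integers(0, 400, 2))
            phi = float(rng.uniform(0.0, 0.3))
            assert nb_conditional_pvalue(ya, yb, 3, 3, phi) == pytest.approx(
                nb_conditional_pvalue(yb, ya, 3, 3, phi), abs=1e-12
            )

    def test_matches_enumeration_totals_to_60(self, rng):
        for _ in range(150):
            t = int(rng.integers(1, 61))
            ya = int(rng.integers(0, t + 1))
            phi = float(rng.uniform(0.01, 0.5))
            na, nb = (int(x) for x in rng.integers(2, 5, 2))
            got = nb_conditional_pvalue(ya, t - ya, na, nb, phi)
            want = nb_oracle(ya, t - ya, na, nb, phi)
            assert got == pytest.approx(want, abs=1e-10)

    def test_dispersion_widens_the_null(self):
        # the same split is less surprising under more biological noise
        p0 = nb_conditional_pvalue(150, 100, 3, 3, 0.0)
        p1 = nb_conditional_pvalue(150, 100, 3, 3, 0.05)
        p2 = nb_conditional_pvalue(150, 100, 3, 3, 0.2)
        assert p0 < p1 < p2


def test_dispersion_estimator_recovers_truth(rng):
    mu = np.exp(rng.normal(5.5, 1.0, 3000))
    phi = 0.08
    size = 1.0 / phi
    counts = np.column_stack(
        [rng.negative_binomial(size, size / (size + mu)) for _ in range(6)]
    )
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    est = estimate_common_dispersion(counts, groups)
    assert est == pytest.approx(phi, rel=0.25)


def test_dispersion_estimator_zero_for_poisson(rng):
    mu = np.exp(rng.normal(5.0, 1.0, 2000))
    counts = np.column_stack([rng.poisson(mu) for _ in range(6)])
    groups = np.array(["a"] * 3 + ["b"] * 3)
    assert estimate_common_dispersion(counts, groups) <= 0.01


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 1.0])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 1.0])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
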