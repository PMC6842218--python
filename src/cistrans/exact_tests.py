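"""Exact tests used throughout the pipeline.

All two-sided p-values follow the method of small probabilities: the
p-value is the total probability of outcomes whose null probability does
not exceed that of the observed outcome.

* ``binom_two_sided`` — equal-allele binomial test at success probability
  1/2.  Symmetry makes the two-sided sum a closed form in the binomial
  CDF, so no tie tolerance is needed.
* ``fisher_two_sided`` — Fisher's exact test on a 2x2 table via
  hypergeometric enumeration.  Small tables (grand total <= 300) are
  evaluated in exact integer arithmetic so tie comparisons are literal;
  larger tables use floating-point enumeration with the conventional
  relative tie gate.
* ``nb_conditional_pvalue`` — conditional negative-binomial exact test of
  equal means between two replicate groups given their pooled total,
  the in-repo engine behind differential-expression calls.  Dispersion 0
  degenerates to the Poisson/binomial case.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np
from scipy import special, stats

_TIE_GATE = 1.0 + 1e-7
_FISHER_EXACT_LIMIT = 300


def binom_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p-value for ``k`` successes in ``n`` at p=1/2."""
    k, n = int(k), int(n)
    if n < 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return 1.0
    m = min(k, n - k)
    if 2 * m == n:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(m, n, 0.5)))


def binom_two_sided_vec(k, n) -> np.ndarray:
    """Vectorised :func:`binom_two_sided`."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    m = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.binom.cdf(m, np.maximum(n, 1), 0.5)
    p = np.minimum(p, 1.0)
    p = np.where((n == 0) | (2 * m == n), 1.0, p)
    return p


@lru_cache(maxsize=512)
def _comb_row(n: int) -> tuple:
    return tuple(comb(n, i) for i in range(n + 1))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    a, b, c, d = (int(x) for x in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    n = a + b + c + d
    r = a + b
    col = a + c
    if r == 0 or col == 0 or r == n or col == n:
        return 1.0
    lo = max(0, col - (n - r))
    hi = min(r, col)
    if n <= _FISHER_EXACT_LIMIT:
        row1 = _comb_row(r)
        row2 = _comb_row(n - r)
        weights = [row1[x] * row2[col - x] for x in range(lo, hi + 1)]
        w_obs = weights[a - lo]
        num = sum(w for w in weights if w <= w_obs)
        return num / comb(n, col)
    # Large tables: enumerate a window around the hypergeometric mode wide
    # enough (40 sd) that the excluded tail mass is negligible at any
    # relevant precision; the observed cell is always included.
    mean = col * r / n
    var = mean * (n - r) / n * (n - col) / (n - 1)
    half = 40.0 * np.sqrt(max(var, 1.0)) + 10.0
    w_lo = max(lo, min(int(np.floor(mean - half)), a))
    w_hi = min(hi, max(int(np.ceil(mean + half)), a))
    k = np.arange(w_lo, w_hi + 1)
    logw = (
        -special.gammaln(k + 1)
        - special.gammaln(r - k + 1)
        - special.gammaln(col - k + 1)
        - special.gammaln(n - r - col + k + 1)
    )
    w = np.exp(logw - logw.max())
    w_obs = w[a - w_lo]
    return float(min(1.0, w[w <= w_obs * _TIE_GATE].sum() / w.sum()))


def nb_conditional_pvalue(
    y_a: int, y_b: int, n_a: int, n_b: int, dispersion: float
) -> float:
    """Conditional exact test of equal per-library means between two groups.

    ``y_a``/``y_b`` are group total counts over ``n_a``/``n_b`` libraries
    on a common scale.  Each library is negative binomial with common
    dispersion, so the group totals are negative binomial with sizes
    ``n/dispersion`` and the split of the pooled total between groups is
    free of the unknown mean under the null.
    """
    y_a, y_b = int(y_a), int(y_b)
    if y_a < 0 or y_b < 0:
        raise ValueError("group totals must be nonnegative")
    if n_a < 1 or n_b < 1:
        raise ValueError("need at least one library per group")
    t = y_a + y_b
    if t == 0:
        return 1.0
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        # Poisson limit: split is binomial with the size share of group A.
        if n_a == n_b:
            return binom_two_sided(y_a, t)
        k = np.arange(t + 1)
        pmf = stats.binom.pmf(k, t, n_a / (n_a + n_b))
        p_obs = pmf[y_a]
        return float(min(1.0, pmf[pmf <= p_obs * _TIE_GATE].sum()))
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    # Conditional on the pooled total the group-A count is beta-binomial
    # (t, r_a, r_b); enumerate a mode window wide enough (40 sd) that the
    # excluded tail mass is negligible, always including the observation.
    s = r_a + r_b
    mean = t * r_a / s
    var = t * r_a * r_b * (s + t) / (s * s * (s + 1.0))
    half = 40.0 * np.sqrt(max(var, 1.0)) + 10.0
    lo = max(0, min(int(np.floor(mean - half)), y_a))
    hi = min(t, max(int(np.ceil(mean + half)), y_a))
    k = np.arange(lo, hi + 1)
    logw = (
        special.gammaln(k + r_a)
        - special.gammaln(k + 1)
        + special.gammaln(t - k + r_b)
        - special.gammaln(t - k + 1)
    )
    w = np.exp(logw - logw.max())
    w_obs = w[y_a - lo]
    return float(min(1.0, w[w <= w_obs * _TIE_GATE].sum() / w.sum()))


def estimate_common_dispersion(matrix: np.ndarray, groups) -> float:
    """Method-of-moments common NB dispersion across genes.

    ``matrix`` is genes x libraries on a common scale; ``groups`` assigns
    each column to a replicate group.  Per gene the pooled within-group
    variance ``s2`` and grand mean ``m`` give ``(s2 - m) / m**2``; the
    median over informative genes, clipped at zero, is returned.
    """
    matrix = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    ss = np.zeros(matrix.shape[0])
    df = 0
    for g in np.unique(groups):
        sub = matrix[:, groups == g]
        if sub.shape[1] < 2:
            continue
        ss += np.sum((sub - sub.mean(axis=1, keepdims=True)) ** 2, axis=1)
        df += sub.shape[1] - 1
    if df == 0:
        return 0.0
    s2 = ss / df
    m = matrix.mean(axis=1)
    ok = m >= 1.0
    if not np.any(ok):
        return 0.0
    phi = (s2[ok] - m[ok]) / m[ok] ** 2
    return float(max(0.0, np.median(phi)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one test family)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
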