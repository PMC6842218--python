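"""TMM between-library normalization and replicate quality control.

The trimmed mean of M-values (TMM) scaling factor assumes most genes are
not differentially expressed: for each library, log2 expression ratios
(M) against a reference library are doubly trimmed — 30% on M and 5% on
log2 abundance (A) — and averaged with inverse asymptotic-variance
weights.  Factors are rescaled to geometric mean 1; the effective library
size is raw size times factor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._naming import library_class


def _pair_factor(obs, ref, n_obs, n_ref, trim_m, trim_a):
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 1.0
    po, pr = obs / n_obs, ref / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # Double trim by value quantiles (inclusive bounds); robust to the
    # heavy M-value ties that arise when libraries share composition.
    m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
    a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
    eps_m = 1e-9 * max(1.0, np.max(np.abs(m)))
    eps_a = 1e-9 * max(1.0, np.max(np.abs(a)))
    keep = (
        (m >= m_lo - eps_m)
        & (m <= m_hi + eps_m)
        & (a >= a_lo - eps_a)
        & (a <= a_hi + eps_a)
    )
    if not np.any(keep) or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    matrix: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference=None,
) -> pd.DataFrame:
    """TMM normalization factors for a genes-by-libraries count matrix.

    Returns a frame indexed by library with columns ``lib_size``,
    ``tmm_factor`` and ``effective_size``.  The reference library is the
    one whose upper-quartile count fraction is closest to the mean of
    those fractions, unless given explicitly (index or label).
    """
    counts = matrix.to_numpy(dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a genes x libraries matrix with >= 2 libraries")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    lib_size = counts.sum(axis=0)
    if np.any(lib_size == 0):
        raise ValueError("library with all-zero counts")
    n_libs = counts.shape[1]
    if counts.shape[0] < 2:
        warnings.warn("single-gene matrix: all TMM factors set to 1", stacklevel=2)
        factors = np.ones(n_libs)
    else:
        if reference is None:
            f75 = np.array(
                [np.quantile(counts[:, j] / lib_size[j], 0.75) for j in range(n_libs)]
            )
            ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
        elif isinstance(reference, (int, np.integer)):
            ref_idx = int(reference)
        else:
            ref_idx = list(matrix.columns).index(reference)
        ref = counts[:, ref_idx]
        factors = np.array(
            [
                _pair_factor(counts[:, j], ref, lib_size[j], lib_size[ref_idx], trim_m, trim_a)
                for j in range(n_libs)
            ]
        )
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.DataFrame(
        {
            "lib_size": lib_size,
            "tmm_factor": factors,
            "effective_size": lib_size * factors,
        },
        index=pd.Index(matrix.columns, name="library"),
    )


def cpm(matrix: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Counts per million on the effective (TMM-scaled) library size."""
    eff = factors.loc[matrix.columns, "effective_size"].to_numpy()
    return matrix / eff * 1e6


def replicate_qc(norm_matrix: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """Within-class replicate concordance on log2(x + 1) expression.

    For each library the squared Pearson correlation with every same-class
    replicate is computed; a library fails when its median within-class R^2
    falls below ``threshold`` (a median exactly at the threshold passes).
    Failing libraries are flagged for exclusion from downstream analysis.
    """
    logged = np.log2(norm_matrix.to_numpy(dtype=float) + 1.0)
    libs = list(norm_matrix.columns)
    classes = [library_class(lib) for lib in libs]
    rows = []
    for j, lib in enumerate(libs):
        peers = [k for k in range(len(libs)) if k != j and classes[k] == classes[j]]
        if not peers:
            warnings.warn(
                f"class {classes[j]} has a single replicate; QC skipped for {lib}",
                stacklevel=2,
            )
            rows.append((lib, classes[j], 0, np.nan, True))
            continue
        r2 = []
        for k in peers:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(logged[:, j], logged[:, k])[0, 1]
            r2.append(r * r if np.isfinite(r) else 0.0)
        med = float(np.median(r2))
        rows.append((lib, classes[j], len(peers), med, med >= threshold))
    return pd.DataFrame(
        rows, columns=["library", "sample_class", "n_peers", "median_r2", "passed"]
    )
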