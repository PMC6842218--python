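"""Cis/trans decomposition and regulatory-category assignment.

In an F1 hybrid the two parental alleles share one trans-acting
environment, so allelic imbalance reads out cis-regulatory divergence:

    parental_div = log2(P1 / P2)          (total parental divergence)
    cis          = log2(F1A1 / F1A2)      (allelic imbalance in the hybrid)
    trans        = parental_div - cis
    %cis         = |cis| / (|cis| + |trans|) * 100

Three exact tests with per-family BH-FDR control drive the category
calls: a binomial test of parental difference (A), a binomial test of
allelic imbalance (B), and a Fisher test of ratio equality between
parents and hybrid alleles (C).  With ``fdr < 0.05`` flags (A, B, C):

    conserved  (-,-,-)   cis_only     (+,+,-)   trans_only  (+,-,+)
    compensatory (-,+,+)
    (+,+,+) -> cis_plus_trans when cis*trans > 0, cis_by_trans when < 0
    every other combination -> ambiguous
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._naming import OWN_ALLELE, count_columns
from .exact_tests import bh_adjust, binom_two_sided_vec, fisher_two_sided

REGULATORY_CATEGORIES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)


def allelic_inputs(
    gene_table: pd.DataFrame, factors: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled pseudo-counts (P1, P2, F1A1, F1A2) per gene.

    Each quantity is the replicate mean of normalized counts (count over
    effective library size), rescaled to the mean effective size across
    libraries and rounded half-to-even to an integer for the exact tests.
    Genes with all four quantities zero are excluded and returned in the
    second frame.
    """
    cols = count_columns(gene_table.columns)
    eff = factors["effective_size"]
    groups = {"P1": [], "P2": [], "F1A1": [], "F1A2": []}
    for lc in cols:
        if lc.sample_class in OWN_ALLELE:
            if lc.allele != OWN_ALLELE[lc.sample_class]:
                continue
            key = "P1" if lc.sample_class == "parent1" else "P2"
        else:
            key = "F1A1" if lc.allele == "a1" else "F1A2"
        groups[key].append(lc)
    mean_eff = float(eff.mean())
    out = {}
    for key, lcs in groups.items():
        norm = np.column_stack(
            [gene_table[lc.name].to_numpy(dtype=float) / eff[lc.library] for lc in lcs]
        )
        out[key] = np.rint(norm.mean(axis=1) * mean_eff).astype(np.int64)
    pooled = pd.DataFrame(out, index=pd.Index(gene_table["gene_id"], name="gene_id"))
    empty = pooled.sum(axis=1) == 0
    excluded = pd.DataFrame(
        {"gene_id": pooled.index[empty], "reason": "all_zero"}
    ).reset_index(drop=True)
    return pooled[~empty], excluded


def cis_trans_decompose(p1, p2, f1a1, f1a2, pseudocount: float = 0.5):
    """(cis, trans, parental_div) in log2 units, with a zero-guard pseudocount."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    f1a1 = np.asarray(f1a1, dtype=float)
    f1a2 = np.asarray(f1a2, dtype=float)
    pc = pseudocount
    parental = np.log2((p1 + pc) / (p2 + pc))
    cis = np.log2((f1a1 + pc) / (f1a2 + pc))
    return cis, parental - cis, parental


def pct_cis(cis, trans):
    """|cis| / (|cis| + |trans|) * 100; NaN where both are exactly zero."""
    cis = np.asarray(cis, dtype=float)
    trans = np.asarray(trans, dtype=float)
    denom = np.abs(cis) + np.abs(trans)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, np.abs(cis) / denom * 100.0, np.nan)
    return out


def binomial_allelic_test(f1a1: int, f1a2: int) -> float:
    """Exact binomial test of balanced allelic expression in the hybrid."""
    from .exact_tests import binom_two_sided

    return binom_two_sided(int(f1a1), int(f1a1) + int(f1a2))


def binomial_parental_test(p1: int, p2: int) -> float:
    """Exact binomial test of equal expression between the parents."""
    from .exact_tests import binom_two_sided

    return binom_two_sided(int(p1), int(p1) + int(p2))


def fisher_trans_test(p1: int, p2: int, f1a1: int, f1a2: int) -> float:
    """Fisher exact test of parental ratio vs hybrid allelic ratio."""
    return fisher_two_sided(int(p1), int(p2), int(f1a1), int(f1a2))


def classify_regulatory(sig_parental, sig_allelic, sig_trans, cis, trans) -> np.ndarray:
    """Vectorised category assignment from the three significance flags."""
    a = np.asarray(sig_parental, dtype=bool)
    b = np.asarray(sig_allelic, dtype=bool)
    c = np.asarray(sig_trans, dtype=bool)
    prod = np.asarray(cis, dtype=float) * np.asarray(trans, dtype=float)
    out = np.full(a.shape, "ambiguous", dtype=object)
    out[~a & ~b & ~c] = "conserved"
    out[a & b & ~c] = "cis_only"
    out[a & ~b & c] = "trans_only"
    out[~a & b & c] = "compensatory"
    abc = a & b & c
    out[abc & (prod > 0)] = "cis_plus_trans"
    out[abc & (prod < 0)] = "cis_by_trans"
    return out


def run_regulatory(
    gene_table: pd.DataFrame,
    factors: pd.DataFrame,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full regulatory analysis: estimates, three tests, FDR, categories.

    The pseudocount enters the log-ratio estimates only, never the test
    counts.  BH adjustment is applied separately within each test family.
    """
    pooled, excluded = allelic_inputs(gene_table, factors)
    p1 = pooled["P1"].to_numpy()
    p2 = pooled["P2"].to_numpy()
    f1a1 = pooled["F1A1"].to_numpy()
    f1a2 = pooled["F1A2"].to_numpy()

    cis, trans, parental = cis_trans_decompose(p1, p2, f1a1, f1a2, pseudocount)
    p_parental = binom_two_sided_vec(p1, p1 + p2)
    p_allelic = binom_two_sided_vec(f1a1, f1a1 + f1a2)
    p_trans = np.array(
        [fisher_two_sided(a, b, c, d) for a, b, c, d in zip(p1, p2, f1a1, f1a2)]
    )
    fdr_parental = bh_adjust(p_parental)
    fdr_allelic = bh_adjust(p_allelic)
    fdr_trans = bh_adjust(p_trans)
    sig_a = fdr_parental < fdr
    sig_b = fdr_allelic < fdr
    sig_c = fdr_trans < fdr
    category = classify_regulatory(sig_a, sig_b, sig_c, cis, trans)
    out = pd.DataFrame(
        {
            "gene_id": pooled.index.to_numpy(),
            "P1": p1,
            "P2": p2,
            "F1A1": f1a1,
            "F1A2": f1a2,
            "cis": cis,
            "trans": trans,
            "parental_div": parental,
            "pct_cis": pct_cis(cis, trans),
            "p_parental": p_parental,
            "p_allelic": p_allelic,
            "p_trans": p_trans,
            "fdr_parental": fdr_parental,
            "fdr_allelic": fdr_allelic,
            "fdr_trans": fdr_trans,
            "sig_parental": sig_a,
            "sig_allelic": sig_b,
            "sig_trans": sig_c,
            "category": category,
        }
    )
    out.attrs["excluded"] = excluded
    return out
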