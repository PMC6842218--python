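"""Differential expression against both parents and inheritance clusters.

Each gene's total expression in the hybrid is tested against each parent
with a conditional negative-binomial exact test on TMM-normalized
pseudo-counts.  A contrast is significant when the BH-adjusted p-value is
below the FDR cutoff and the point-estimate fold change reaches the gate
(default 1.25-fold, with a 0.5 pseudocount in the estimate).  Significant
genes are then placed into the eight inheritance clusters; everything
else is ``no_change``:

* both contrasts significant, opposite directions -> additivity, subtyped
  by whether the female parent out-expresses the male parent;
* exactly one contrast significant -> expression-level dominance toward
  the parent the hybrid matches, up/down by the direction of the
  significant contrast;
* both significant in the same direction -> overdominance (up) or
  underdominance (down), i.e. transgressive expression.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._naming import library_class
from .exact_tests import bh_adjust, estimate_common_dispersion, nb_conditional_pvalue

CONTRASTS = ("f1_vs_parent1", "f1_vs_parent2", "parent1_vs_parent2")


def nb_exact_test(group_a, group_b, dispersion: float) -> tuple[float, float]:
    """(log2 fold change, p-value) for two replicate groups of pseudo-counts.

    Counts must already sit on a common (effective-library) scale.  The
    fold change is ``log2((mean_a + 0.5) / (mean_b + 0.5))``; the p-value
    is the conditional NB exact test on the group totals.
    """
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one replicate")
    l2fc = math.log2((a.mean() + 0.5) / (b.mean() + 0.5))
    if a.sum() == 0 and b.sum() == 0:
        return 0.0, 1.0
    p = nb_conditional_pvalue(int(a.sum()), int(b.sum()), a.size, b.size, dispersion)
    return l2fc, p


def pseudo_counts(totals: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Rescale library counts to the geometric-mean effective size, rounded.

    Rounding is half-to-even so results are deterministic and unbiased.
    """
    eff = factors.loc[totals.columns, "effective_size"].to_numpy()
    scale = float(np.exp(np.mean(np.log(eff))))
    return pd.DataFrame(
        np.rint(totals.to_numpy(dtype=float) / eff * scale).astype(np.int64),
        index=totals.index,
        columns=totals.columns,
    )


def run_contrasts(
    totals: pd.DataFrame,
    factors: pd.DataFrame,
    fc: float = 1.25,
    fdr: float = 0.05,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """All three pairwise contrasts for every gene (long format).

    Returns columns gene_id, contrast, log2fc, pvalue, fdr, significant.
    Common dispersion is estimated by the method of moments across genes
    unless supplied.
    """
    pseudo = pseudo_counts(totals, factors)
    classes = np.array([library_class(c) for c in pseudo.columns])
    cols = {cls: pseudo.loc[:, classes == cls].to_numpy() for cls in np.unique(classes)}
    for cls in ("parent1", "parent2", "f1"):
        if cls not in cols or cols[cls].shape[1] < 2:
            raise ValueError(f"need >= 2 replicates for {cls}")
    phi = (
        estimate_common_dispersion(pseudo.to_numpy(), classes)
        if dispersion is None
        else float(dispersion)
    )
    thr = math.log2(fc) - 1e-12
    pairs = {
        "f1_vs_parent1": ("f1", "parent1"),
        "f1_vs_parent2": ("f1", "parent2"),
        "parent1_vs_parent2": ("parent1", "parent2"),
    }
    frames = []
    genes = pseudo.index.to_numpy()
    for contrast, (ca, cb) in pairs.items():
        a_mat, b_mat = cols[ca], cols[cb]
        l2fc = np.log2((a_mat.mean(axis=1) + 0.5) / (b_mat.mean(axis=1) + 0.5))
        n_a, n_b = a_mat.shape[1], b_mat.shape[1]
        sums_a, sums_b = a_mat.sum(axis=1), b_mat.sum(axis=1)
        pvals = np.array(
            [
                nb_conditional_pvalue(int(ya), int(yb), n_a, n_b, phi)
                if ya + yb > 0
                else 1.0
                for ya, yb in zip(sums_a, sums_b)
            ]
        )
        adj = bh_adjust(pvals)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "contrast": contrast,
                    "log2fc": l2fc,
                    "pvalue": pvals,
                    "fdr": adj,
                    "significant": (adj < fdr) & (np.abs(l2fc) >= thr),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["dispersion"] = phi
    return out


def classify_inheritance(contrasts: pd.DataFrame, female: str = "parent1") -> pd.DataFrame:
    """Per-gene inheritance cluster from the two hybrid-parent contrasts.

    ``female`` names the maternal parent; additivity subtypes and the
    dominance labels are defined relative to it.  The additivity subtype
    (female above or below the male parent) is read off the
    parent1-vs-parent2 fold change.
    """
    if female not in ("parent1", "parent2"):
        raise ValueError("female must be 'parent1' or 'parent2'")
    male = "parent2" if female == "parent1" else "parent1"
    wide_sig = contrasts.pivot(index="gene_id", columns="contrast", values="significant")
    wide_fc = contrasts.pivot(index="gene_id", columns="contrast", values="log2fc")
    sig_f = wide_sig[f"f1_vs_{female}"].to_numpy(dtype=bool)
    sig_m = wide_sig[f"f1_vs_{male}"].to_numpy(dtype=bool)
    d_f = wide_fc[f"f1_vs_{female}"].to_numpy()
    d_m = wide_fc[f"f1_vs_{male}"].to_numpy()
    # log2(female / male) from the parental contrast
    p_fc = wide_fc["parent1_vs_parent2"].to_numpy()
    fem_gt_male = p_fc > 0 if female == "parent1" else p_fc < 0

    cluster = np.full(len(wide_sig), "no_change", dtype=object)
    both = sig_f & sig_m
    opposite = both & (d_f * d_m < 0)
    cluster[opposite & fem_gt_male] = "additivity_f_gt_m"
    cluster[opposite & ~fem_gt_male] = "additivity_f_lt_m"
    same = both & (d_f * d_m > 0)
    cluster[same & (d_f > 0)] = "overdominance"
    cluster[same & (d_f < 0)] = "underdominance"
    only_m = sig_m & ~sig_f  # hybrid matches the female parent
    cluster[only_m & (d_m > 0)] = "female_dominance_up"
    cluster[only_m & (d_m <= 0)] = "female_dominance_down"
    only_f = sig_f & ~sig_m  # hybrid matches the male parent
    cluster[only_f & (d_f > 0)] = "male_dominance_up"
    cluster[only_f & (d_f <= 0)] = "male_dominance_down"
    return pd.DataFrame({"gene_id": wide_sig.index.to_numpy(), "cluster": cluster})


def summarize_inheritance(calls: pd.DataFrame) -> dict:
    """Cluster counts, proportions among DEGs, and the DEG fraction."""
    if len(calls) == 0:
        raise ValueError("empty call set")
    counts = calls["cluster"].value_counts().to_dict()
    n = len(calls)
    n_deg = n - counts.get("no_change", 0)
    out = {
        "n_genes": n,
        "n_deg": n_deg,
        "deg_fraction": n_deg / n,
        "cluster_counts": counts,
    }
    if n_deg > 0:
        out["cluster_proportions"] = {
            k: v / n_deg for k, v in counts.items() if k != "no_change"
        }
    return out
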