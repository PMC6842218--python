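"""Reading, validating, filtering and aggregating SNP-site allele counts.

Tables are tab-separated with a required header (see :mod:`._naming` for
the column convention), counts parsed as nonnegative integers.  The module
implements the max-of-two-mappings merge that corrects allele-mapping
bias, the site quality filters, and within-gene aggregation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._naming import KEY_COLUMNS, OWN_ALLELE, count_columns


class StructuralError(ValueError):
    """Two mapping tables do not describe the same sites/libraries."""


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a SNP count TSV, validating structure and integer counts."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "gene_id": str})
    return validate_counts(df)


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    for key in KEY_COLUMNS:
        if key not in df.columns:
            raise ValueError(f"count table lacks required column {key!r}")
    cols = count_columns(df.columns)
    for lc in cols:
        vals = df[lc.name]
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            as_int = vals.astype(np.int64, errors="raise")
            if not np.allclose(arr.astype(float), as_int.astype(float)):
                raise ValueError(f"column {lc.name} holds non-integer counts")
            df[lc.name] = as_int
        if (df[lc.name] < 0).any():
            raise ValueError(f"column {lc.name} holds negative counts")
    return df


def _f1_columns(df):
    return [lc for lc in count_columns(df.columns) if lc.sample_class == "f1"]


def merge_dual_mappings(mapping1: pd.DataFrame, mapping2: pd.DataFrame) -> pd.DataFrame:
    """Merge two per-pseudo-genome mapping tables of the same cross.

    For each F1 allele count the merged value is the maximum of the two
    mapping results (each pseudo-genome maps its own allele without bias,
    so the maximum recovers the unbiased count); parental counts must
    agree between the tables and are carried through.  The site's F1 total
    is then the sum of the two merged allele counts.
    """
    m1 = validate_counts(mapping1.copy())
    m2 = validate_counts(mapping2.copy())
    if list(m1.columns) != list(m2.columns):
        raise StructuralError("mapping tables have different columns")
    if len(m1) != len(m2) or not (
        m1["site_id"].to_numpy() == m2["site_id"].to_numpy()
    ).all():
        raise StructuralError("mapping tables cover different sites")
    if not (m1["gene_id"].to_numpy() == m2["gene_id"].to_numpy()).all():
        raise StructuralError("mapping tables disagree on site-to-gene assignment")
    merged = m1.copy()
    f1_names = {lc.name for lc in _f1_columns(m1)}
    for lc in count_columns(m1.columns):
        if lc.name in f1_names:
            merged[lc.name] = np.maximum(m1[lc.name], m2[lc.name])
        elif not (m1[lc.name].to_numpy() == m2[lc.name].to_numpy()).all():
            raise StructuralError(f"parental column {lc.name} differs between mappings")
    return merged


def filter_snp_sites(
    counts: pd.DataFrame,
    min_minor: int = 2,
    min_total: int = 20,
    per_replicate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the SNP-site quality filters; returns (retained, rejection log).

    The allele thresholds apply to the F1 counts: the minor parental
    allele must reach ``min_minor`` reads and the site total ``min_total``
    reads.  By default counts are pooled across F1 replicates (matching
    the replicate pooling of the downstream allelic tests); with
    ``per_replicate=True`` every replicate must pass on its own.  Sites
    where a parent shows reads on the other species' allele violate the
    parental-homozygosity assumption and are rejected structurally.
    """
    counts = validate_counts(counts.copy())
    cols = count_columns(counts.columns)
    f1_a1 = [lc.name for lc in cols if lc.sample_class == "f1" and lc.allele == "a1"]
    f1_a2 = [lc.name for lc in cols if lc.sample_class == "f1" and lc.allele == "a2"]
    cross_allele = [
        lc.name
        for lc in cols
        if lc.sample_class in OWN_ALLELE and lc.allele != OWN_ALLELE[lc.sample_class]
    ]

    reasons = pd.Series("", index=counts.index, dtype=object)
    if cross_allele:
        bad = counts[cross_allele].to_numpy().sum(axis=1) > 0
        reasons[bad & (reasons == "")] = "parent_not_homozygous"

    a1 = counts[f1_a1].to_numpy(dtype=np.int64)
    a2 = counts[f1_a2].to_numpy(dtype=np.int64)
    if per_replicate:
        minor = np.minimum(a1, a2)
        total = a1 + a2
        fail_minor = (minor < min_minor).any(axis=1)
        fail_total = (total < min_total).any(axis=1)
    else:
        s1 = a1.sum(axis=1)
        s2 = a2.sum(axis=1)
        fail_minor = np.minimum(s1, s2) < min_minor
        fail_total = (s1 + s2) < min_total
    reasons[fail_minor & (reasons == "")] = "min_minor"
    reasons[fail_total & (reasons == "")] = "min_total"

    rejected = reasons != ""
    log = pd.DataFrame(
        {"site_id": counts.loc[rejected, "site_id"], "reason": reasons[rejected]}
    ).reset_index(drop=True)
    return counts[~rejected].reset_index(drop=True), log


def aggregate_to_genes(filtered: pd.DataFrame) -> pd.DataFrame:
    """Sum retained site counts per gene and library.

    Genes with zero retained sites simply do not appear.  The result has
    one row per gene, the same count columns as the input, plus
    ``n_sites``.
    """
    filtered = validate_counts(filtered.copy())
    value_cols = [lc.name for lc in count_columns(filtered.columns)]
    grouped = filtered.groupby("gene_id", sort=True)
    agg = grouped[value_cols].sum()
    agg.insert(0, "n_sites", grouped.size())
    return agg.reset_index()


def gene_totals_matrix(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Per-library total expression matrix (genes x libraries).

    Parental libraries contribute their own-allele counts; each F1
    library's total is the sum of its two allele counts.
    """
    cols = count_columns(gene_table.columns)
    out = {}
    for lc in cols:
        if lc.sample_class in OWN_ALLELE and lc.allele != OWN_ALLELE[lc.sample_class]:
            continue  # cross-allele parent columns are QC-only
        out.setdefault(lc.library, np.zeros(len(gene_table), dtype=np.int64))
        out[lc.library] = out[lc.library] + gene_table[lc.name].to_numpy()
    mat = pd.DataFrame(out)
    mat.index = pd.Index(gene_table["gene_id"], name="gene_id")
    return mat
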