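"""Cross-level comparative statistics and end-to-end orchestration.

This module turns per-gene regulatory and inheritance calls into the
study-level summaries — magnitude comparisons of cis vs trans divergence,
rank correlations of divergence with each regulatory mode, %cis profiles
by divergence magnitude and by inheritance mode, the regulatory-category
by inheritance-cluster contingency table — and compares two crosses with
Fisher exact tests on class proportions.  ``run_all`` wires the whole
pipeline (simulate/load -> merge -> filter -> aggregate -> normalize ->
QC -> inheritance -> regulatory -> summaries) behind one config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from ._naming import library_class
from .counts import (
    aggregate_to_genes,
    filter_snp_sites,
    gene_totals_matrix,
    merge_dual_mappings,
    read_counts_tsv,
)
from .exact_tests import fisher_two_sided
from .inheritance import classify_inheritance, run_contrasts, summarize_inheritance
from .normalize import cpm, replicate_qc, tmm_factors
from .regulatory import REGULATORY_CATEGORIES, run_regulatory
from .simulate import SimConfig, simulate_cross

log = logging.getLogger("cistrans")

ADDITIVE_CLUSTERS = ("additivity_f_gt_m", "additivity_f_lt_m")
TRANSGRESSIVE_CLUSTERS = ("overdominance", "underdominance")
CLUSTER_GROUPS = {
    "additivity": ADDITIVE_CLUSTERS,
    "female_dominance": ("female_dominance_up", "female_dominance_down"),
    "male_dominance": ("male_dominance_up", "male_dominance_down"),
    "transgressivity": TRANSGRESSIVE_CLUSTERS,
}


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small untied samples,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    exact = max(x.size, y.size) <= 25 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.pvalue)


def compare_magnitudes(reg: pd.DataFrame) -> dict:
    """Median |cis| among allelic-significant genes vs median |trans|
    among trans-significant genes, with a rank-sum p-value."""
    cis_mag = np.abs(reg.loc[reg["sig_allelic"], "cis"].to_numpy())
    trans_mag = np.abs(reg.loc[reg["sig_trans"], "trans"].to_numpy())
    if cis_mag.size == 0 or trans_mag.size == 0:
        raise ValueError("need at least one significant cis and trans gene")
    return {
        "median_abs_cis": float(np.median(cis_mag)),
        "median_abs_trans": float(np.median(trans_mag)),
        "n_cis_sig": int(cis_mag.size),
        "n_trans_sig": int(trans_mag.size),
        "wilcoxon_p": rank_sum_test(cis_mag, trans_mag),
    }


def correlate_divergence(reg: pd.DataFrame) -> dict:
    """Kendall tau-b of parental divergence with cis and with trans."""
    if len(reg) < 10:
        raise ValueError("need >= 10 genes for rank correlation")
    pdv = reg["parental_div"].to_numpy()
    out = {}
    for name in ("cis", "trans"):
        tau, p = stats.kendalltau(pdv, reg[name].to_numpy())
        out[f"tau_{name}"] = float(tau)
        out[f"tau_{name}_p"] = float(p)
    return out


def pct_cis_by_bin(reg: pd.DataFrame, edges=(1.25, 2.0, 4.0)) -> pd.DataFrame:
    """Median %cis within half-open fold-change bins of |parental_div|."""
    if len(reg) == 0:
        raise ValueError("empty call set")
    fold = 2.0 ** np.abs(reg["parental_div"].to_numpy())
    pc = reg["pct_cis"].to_numpy()
    bounds = [1.0, *edges, np.inf]
    rows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        inside = (fold >= lo) & (fold < hi) & np.isfinite(pc)
        if not inside.any():
            continue
        label = f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">= {lo:g}"
        rows.append(
            {
                "bin": label,
                "fold_lo": lo,
                "fold_hi": hi,
                "n": int(inside.sum()),
                "median_pct_cis": float(np.median(pc[inside])),
            }
        )
    return pd.DataFrame(rows)


def pct_cis_by_inheritance(reg: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Median %cis of additively vs non-additively expressed DEGs."""
    merged = reg.merge(calls, on="gene_id")
    deg = merged[merged["cluster"] != "no_change"]
    deg = deg[np.isfinite(deg["pct_cis"])]
    additive = deg[deg["cluster"].isin(ADDITIVE_CLUSTERS)]["pct_cis"].to_numpy()
    non_additive = deg[~deg["cluster"].isin(ADDITIVE_CLUSTERS)]["pct_cis"].to_numpy()
    out = {
        "n_additive": int(additive.size),
        "n_non_additive": int(non_additive.size),
        "median_pct_cis_additive": float(np.median(additive)) if additive.size else None,
        "median_pct_cis_non_additive": (
            float(np.median(non_additive)) if non_additive.size else None
        ),
    }
    out["wilcoxon_p"] = (
        rank_sum_test(additive, non_additive)
        if additive.size and non_additive.size
        else None
    )
    return out


def hybrid_parent_correlation(norm: pd.DataFrame) -> dict:
    """Pearson correlation of hybrid vs parental expression.

    Computed on log2(x + 1) of the class-mean normalized totals; the
    parental reference is the mid-parent mean.
    """
    classes = np.array([library_class(c) for c in norm.columns])
    means = {
        cls: np.log2(norm.loc[:, classes == cls].mean(axis=1).to_numpy() + 1.0)
        for cls in ("parent1", "parent2", "f1")
    }
    mid_parent = (means["parent1"] + means["parent2"]) / 2.0
    out = {}
    for name, ref in (
        ("parent1", means["parent1"]),
        ("parent2", means["parent2"]),
        ("mid_parent", mid_parent),
    ):
        r, p = stats.pearsonr(means["f1"], ref)
        out[f"pearson_r_{name}"] = float(r)
        out[f"pearson_p_{name}"] = float(p)
    return out


def category_by_cluster_table(
    reg: pd.DataFrame, calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulatory-category x inheritance-mode contingency table for DEGs.

    Dominance and transgressive subtypes are merged into their four
    column groups; returns (counts, column percentages).
    """
    merged = reg.merge(calls, on="gene_id")
    deg = merged[merged["cluster"] != "no_change"]
    counts = pd.DataFrame(
        0, index=list(REGULATORY_CATEGORIES), columns=list(CLUSTER_GROUPS), dtype=int
    )
    for group, members in CLUSTER_GROUPS.items():
        sub = deg[deg["cluster"].isin(members)]
        vc = sub["category"].value_counts()
        for cat, n in vc.items():
            counts.loc[cat, group] = int(n)
    col_sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts / col_sums.replace(0, np.nan) * 100.0
    counts.index.name = pct.index.name = "category"
    return counts, pct


@dataclass
class CrossSummary:
    """Study-level summary of one cross."""

    label: str
    n_genes: int
    inheritance: dict
    magnitudes: dict | None
    correlations: dict | None
    pct_cis_bins: pd.DataFrame
    pct_cis_inheritance: dict
    contingency_counts: pd.DataFrame
    contingency_pct: pd.DataFrame
    category_counts: dict = field(default_factory=dict)
    n_cis_sig: int = 0
    n_trans_sig: int = 0
    median_pct_cis_sig: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pct_cis_bins"] = self.pct_cis_bins.to_dict(orient="records")
        d["contingency_counts"] = self.contingency_counts.to_dict()
        d["contingency_pct"] = self.contingency_pct.where(
            np.isfinite(self.contingency_pct), None
        ).to_dict()
        return d


def summarize_cross(label: str, reg: pd.DataFrame, calls: pd.DataFrame) -> CrossSummary:
    counts, pct = category_by_cluster_table(reg, calls)
    sig_any = reg[
        reg["category"].isin(
            ("cis_only", "trans_only", "cis_plus_trans", "cis_by_trans", "compensatory")
        )
    ]
    pc = sig_any["pct_cis"].to_numpy()
    pc = pc[np.isfinite(pc)]
    try:
        magnitudes = compare_magnitudes(reg)
    except ValueError:
        magnitudes = None
    try:
        correlations = correlate_divergence(reg)
    except ValueError:
        correlations = None
    return CrossSummary(
        label=label,
        n_genes=len(reg),
        inheritance=summarize_inheritance(calls),
        magnitudes=magnitudes,
        correlations=correlations,
        pct_cis_bins=pct_cis_by_bin(reg),
        pct_cis_inheritance=pct_cis_by_inheritance(reg, calls),
        contingency_counts=counts,
        contingency_pct=pct,
        category_counts={
            c: int((reg["category"] == c).sum()) for c in REGULATORY_CATEGORIES
        },
        n_cis_sig=int(reg["sig_allelic"].sum()),
        n_trans_sig=int(reg["sig_trans"].sum()),
        median_pct_cis_sig=float(np.median(pc)) if pc.size else None,
    )


def compare_crosses(a: CrossSummary, b: CrossSummary) -> dict:
    """Fisher exact tests for proportion differences between two crosses."""

    def counts_of(s: CrossSummary):
        clus = s.inheritance["cluster_counts"]
        n_deg = s.inheritance["n_deg"]
        additive = sum(clus.get(c, 0) for c in ADDITIVE_CLUSTERS)
        transgressive = sum(clus.get(c, 0) for c in TRANSGRESSIVE_CLUSTERS)
        return {
            "n_genes": s.n_genes,
            "n_deg": n_deg,
            "non_additive": n_deg - additive,
            "transgressive": transgressive,
            "cis_sig": s.n_cis_sig,
            "cis_only": s.category_counts.get("cis_only", 0),
        }

    ca, cb = counts_of(a), counts_of(b)
    out = {"cross_a": a.label, "cross_b": b.label}
    comparisons = [
        ("non_additive_among_degs", "non_additive", "n_deg"),
        ("transgressive_among_degs", "transgressive", "n_deg"),
        ("cis_sig_among_genes", "cis_sig", "n_genes"),
        ("cis_only_among_genes", "cis_only", "n_genes"),
    ]
    for name, num, denom in comparisons:
        out[name] = {
            "fraction_a": ca[num] / ca[denom] if ca[denom] else None,
            "fraction_b": cb[num] / cb[denom] if cb[denom] else None,
            "fisher_p": fisher_two_sided(
                ca[num], ca[denom] - ca[num], cb[num], cb[denom] - cb[num]
            ),
        }
    out["median_pct_cis_sig_a"] = a.median_pct_cis_sig
    out["median_pct_cis_sig_b"] = b.median_pct_cis_sig
    return out


DEFAULT_PARAMS = {
    "min_minor": 2,
    "min_total": 20,
    "fc": 1.25,
    "fdr": 0.05,
    "qc_r2": 0.90,
    "pseudocount": 0.5,
    "bin_edges": [1.25, 2.0, 4.0],
    "female": "parent1",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage label."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze_counts(
    raw: pd.DataFrame,
    params: dict | None = None,
    apply_qc: bool = True,
    label: str = "cross",
) -> dict:
    """Run filter -> aggregate -> normalize -> inheritance -> regulatory
    -> summary on a merged SNP count table, entirely in memory.

    With ``apply_qc`` the replicate QC can exclude libraries; an exclusion
    that would leave a sample class with fewer than two replicates aborts.
    Returns every intermediate table plus the :class:`CrossSummary`.
    """
    params = {**DEFAULT_PARAMS, **(params or {})}
    try:
        kept, rejects = filter_snp_sites(
            raw, min_minor=params["min_minor"], min_total=params["min_total"]
        )
        log.info("[filter] retained %d/%d sites", len(kept), len(raw))
        if len(kept) == 0:
            raise PipelineError("[filter] no sites survive the quality filters")
        gene_table = aggregate_to_genes(kept)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[filter] {exc}") from exc

    try:
        totals = gene_totals_matrix(gene_table)
        factors = tmm_factors(totals)
        norm = cpm(totals, factors)
        qc = replicate_qc(norm, threshold=params["qc_r2"])
        failed: list[str] = []
        if apply_qc:
            failed = qc.loc[~qc["passed"], "library"].tolist()
        if failed:
            log.warning("[qc] excluding libraries: %s", ", ".join(failed))
            keep_libs = [c for c in totals.columns if c not in failed]
            remaining = pd.Series([library_class(c) for c in keep_libs]).value_counts()
            for cls in ("parent1", "parent2", "f1"):
                if remaining.get(cls, 0) < 2:
                    raise PipelineError(
                        f"[qc] class {cls} left with < 2 replicates after exclusion"
                    )
            totals = totals[keep_libs]
            drop_cols = [
                c
                for c in gene_table.columns
                for f in failed
                if str(c).startswith(f + "_")
            ]
            gene_table = gene_table.drop(columns=drop_cols)
            factors = tmm_factors(totals)
            norm = cpm(totals, factors)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[normalize] {exc}") from exc

    try:
        contrasts = run_contrasts(totals, factors, fc=params["fc"], fdr=params["fdr"])
        calls = classify_inheritance(contrasts, female=params["female"])
        log.info(
            "[inheritance] %d/%d DEGs",
            int((calls["cluster"] != "no_change").sum()),
            len(calls),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[inheritance] {exc}") from exc

    try:
        reg = run_regulatory(
            gene_table, factors, fdr=params["fdr"], pseudocount=params["pseudocount"]
        )
        log.info("[regulatory] categories: %s", reg["category"].value_counts().to_dict())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[regulatory] {exc}") from exc

    try:
        summary = summarize_cross(label, reg, calls)
    except Exception as exc:
        raise PipelineError(f"[summary] {exc}") from exc

    return {
        "kept_sites": kept,
        "rejected_sites": rejects,
        "hybrid_parent_correlation": hybrid_parent_correlation(norm),
        "gene_table": gene_table,
        "totals": totals,
        "factors": factors,
        "normalized": norm,
        "qc": qc,
        "excluded_libraries": failed,
        "contrasts": contrasts,
        "inheritance": calls,
        "regulatory": reg,
        "summary": summary,
    }


def run_all(config: dict, out_dir) -> dict:
    """Execute the full pipeline described by ``config``.

    ``config`` holds either a ``simulation`` block (SimConfig fields) or
    an ``inputs`` block (``counts`` path, optional ``mapping2`` for the
    dual-mapping merge), plus optional ``params`` overriding
    :data:`DEFAULT_PARAMS`, a ``seed`` and a ``label``.  All tables are
    written as TSV under ``out_dir`` together with a JSON manifest and a
    plain-text report; the run is deterministic given the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    label = config.get("label", "cross")
    manifest: dict = {
        "label": label,
        "params": params,
        "version": __version__,
        "inputs": {},
        "outputs": [],
    }

    def save(name, df, index=False):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        manifest["outputs"].append(path.name)
        return path

    try:
        if "simulation" in config:
            sim_cfg = dict(config["simulation"])
            if "seed" in config:
                sim_cfg.setdefault("seed", config["seed"])
            if "category_mix" in sim_cfg:
                sim_cfg["category_mix"] = dict(sim_cfg["category_mix"])
            sim = simulate_cross(SimConfig(**sim_cfg))
            log.info("[simulate] %d genes, %d sites", len(sim.truth), len(sim.counts))
            save("truth", sim.truth)
            manifest["seed"] = sim.config.seed
            if sim.mapping1 is not None:
                save("mapping1", sim.mapping1)
                save("mapping2", sim.mapping2)
                raw = merge_dual_mappings(sim.mapping1, sim.mapping2)
            else:
                raw = sim.counts
            save("counts", raw)
        elif "inputs" in config:
            inputs = config["inputs"]
            raw = read_counts_tsv(inputs["counts"])
            manifest["inputs"]["counts"] = _sha256(inputs["counts"])
            if inputs.get("mapping2"):
                second = read_counts_tsv(inputs["mapping2"])
                manifest["inputs"]["mapping2"] = _sha256(inputs["mapping2"])
                raw = merge_dual_mappings(raw, second)
        else:
            raise PipelineError("[config] need a 'simulation' or 'inputs' block")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-labelled by stage
        raise PipelineError(f"[load] {exc}") from exc

    result = analyze_counts(raw, params=params, apply_qc=True, label=label)

    save("rejected_sites", result["rejected_sites"])
    save("gene_counts", result["gene_table"])
    save("qc", result["qc"])
    save("tmm_factors", result["factors"].reset_index())
    save("normalized_cpm", result["normalized"], index=True)
    save("contrasts", result["contrasts"])
    save("inheritance", result["inheritance"])
    save("regulatory", result["regulatory"])
    manifest["excluded_libraries"] = result["excluded_libraries"]

    summary = result["summary"]
    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, default=float) + "\n"
    )
    manifest["outputs"].append("summary.json")
    _write_report(out / "report.txt", summary)
    manifest["outputs"].append("report.txt")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    result["out_dir"] = str(out)
    return result


def _write_report(path, s: CrossSummary) -> None:
    lines = [
        f"Cross: {s.label}",
        f"Genes analysed: {s.n_genes}",
        f"DEG fraction: {s.inheritance['deg_fraction']:.4f}",
        "",
        "Regulatory categories:",
    ]
    for cat in REGULATORY_CATEGORIES:
        n = s.category_counts.get(cat, 0)
        lines.append(f"  {cat:<15s} {n:6d} ({n / max(s.n_genes, 1) * 100:5.2f}%)")
    lines += [
        "",
        f"Genes with significant allelic imbalance (cis): {s.n_cis_sig}",
        f"Genes with significant trans divergence:        {s.n_trans_sig}",
    ]
    if s.magnitudes:
        lines += [
            "",
            f"Median |cis| (significant):   {s.magnitudes['median_abs_cis']:.3f} log2",
            f"Median |trans| (significant): {s.magnitudes['median_abs_trans']:.3f} log2",
            f"Rank-sum p: {s.magnitudes['wilcoxon_p']:.3g}",
        ]
    if s.correlations:
        lines += [
            "",
            f"Kendall tau(parental, cis)   = {s.correlations['tau_cis']:.3f}",
            f"Kendall tau(parental, trans) = {s.correlations['tau_trans']:.3f}",
        ]
    lines += ["", "Median %cis by parental fold-change bin:"]
    for row in s.pct_cis_bins.itertuples():
        lines.append(
            f"  {row.bin:<12s} n={row.n:<6d} median %cis = {row.median_pct_cis:.1f}"
        )
    pci = s.pct_cis_inheritance
    if (
        pci.get("median_pct_cis_additive") is not None
        and pci.get("median_pct_cis_non_additive") is not None
    ):
        lines += [
            "",
            f"Median %cis additive DEGs:     {pci['median_pct_cis_additive']:.1f}"
            f" (n={pci['n_additive']})",
            f"Median %cis non-additive DEGs: {pci['median_pct_cis_non_additive']:.1f}"
            f" (n={pci['n_non_additive']})",
        ]
    Path(path).write_text("\n".join(lines) + "\n")
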