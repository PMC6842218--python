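"""Seeded end-to-end validation benchmarks.

Each function simulates the study condition it probes, runs the relevant
pipeline stages from scratch, and returns the measured quantities as a
plain dict.  They back the acceptance test suite and the standalone
acceptance script, and double as worked examples of how the package's
calibration and recovery behaviour can be audited.
"""

from __future__ import annotations

import bisect
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .counts import aggregate_to_genes, filter_snp_sites, gene_totals_matrix
from .exact_tests import binom_two_sided, fisher_two_sided
from .inheritance import classify_inheritance, run_contrasts
from .normalize import cpm, tmm_factors
from .regulatory import cis_trans_decompose, run_regulatory
from .simulate import SimConfig, inheritance_scenario_specs, simulate_cross, simulate_from_specs
from .summary import analyze_counts, compare_crosses

PARENT_SWAP = {
    "additivity_f_gt_m": "additivity_f_lt_m",
    "additivity_f_lt_m": "additivity_f_gt_m",
    "female_dominance_up": "male_dominance_up",
    "female_dominance_down": "male_dominance_down",
    "male_dominance_up": "female_dominance_up",
    "male_dominance_down": "female_dominance_down",
    "overdominance": "overdominance",
    "underdominance": "underdominance",
    "no_change": "no_change",
}


def decomposition_identity(n: int = 10_000, seed: int = 0) -> dict:
    """Max |cis + trans - parental_div| over random count quadruples."""
    rng = np.random.default_rng(seed)
    quads = rng.integers(0, 100_000, size=(n, 4))
    cis, trans, pdiv = cis_trans_decompose(
        quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    )
    return {"max_abs_error": float(np.max(np.abs(cis + trans - pdiv))), "n": n}


def exact_test_oracle(max_total: int = 60) -> dict:
    """Exhaustive agreement of both exact tests with integer enumeration.

    Covers every binomial outcome and every 2x2 table with grand total up
    to ``max_total``; the oracle uses exact rational/integer arithmetic,
    independent of the implementation's code path.
    """
    binom_max = 0.0
    n_binom = 0
    for n in range(max_total + 1):
        row = [comb(n, i) for i in range(n + 1)]
        tot = 2**n
        for k in range(n + 1):
            want = 1.0 if n == 0 else float(
                Fraction(sum(w for w in row if w <= row[k]), tot)
            )
            binom_max = max(binom_max, abs(binom_two_sided(k, n) - want))
            n_binom += 1

    fisher_max = 0.0
    n_fisher = 0
    for n in range(1, max_total + 1):
        for r in range(n + 1):
            row1 = [comb(r, x) for x in range(r + 1)]
            row2 = [comb(n - r, x) for x in range(n - r + 1)]
            for col in range(n + 1):
                lo, hi = max(0, col - (n - r)), min(r, col)
                if lo > hi:
                    continue
                degenerate = r in (0, n) or col in (0, n)
                weights = [row1[x] * row2[col - x] for x in range(lo, hi + 1)]
                tot = comb(n, col)
                sw = sorted(weights)
                pref = [0]
                for w in sw:
                    pref.append(pref[-1] + w)
                for a in range(lo, hi + 1):
                    if degenerate:
                        want = 1.0
                    else:
                        idx = bisect.bisect_right(sw, weights[a - lo])
                        want = pref[idx] / tot
                    got = fisher_two_sided(a, r - a, col - a, n - r - col + a)
                    fisher_max = max(fisher_max, abs(got - want))
                    n_fisher += 1
    return {
        "binom_max_abs_diff": binom_max,
        "fisher_max_abs_diff": fisher_max,
        "n_binom": n_binom,
        "n_fisher": n_fisher,
        "binom_p_15_of_20": binom_two_sided(15, 20),
        "fisher_p_diagonal_5": fisher_two_sided(5, 0, 0, 5),
    }


def null_calibration(
    n_runs: int = 200,
    n_genes: int = 500,
    depth: float = 200.0,
    dispersion: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict:
    """Regulatory calls under the all-conserved global null.

    Reports the fraction of runs with at least one significant allelic
    (cis) call and the per-gene rate of non-conserved, non-ambiguous
    categories, each under BH-FDR 5% per test family.
    """
    runs_with_allelic = 0
    bad_categories = 0
    genes_total = 0
    for i in range(n_runs):
        cfg = SimConfig(
            n_genes=n_genes,
            category_mix={"conserved": 1.0},
            base_mean=depth,
            base_mean_spread=0.0,
            dispersion=dispersion,
            n_replicates=n_replicates,
            mean_snps_per_gene=1.0,
            seed=seed + i,
        )
        sim = simulate_cross(cfg)
        kept, _ = filter_snp_sites(sim.counts)
        gene_table = aggregate_to_genes(kept)
        factors = tmm_factors(gene_totals_matrix(gene_table))
        reg = run_regulatory(gene_table, factors)
        if reg["sig_allelic"].any():
            runs_with_allelic += 1
        bad = ~reg["category"].isin(["conserved", "ambiguous"])
        bad_categories += int(bad.sum())
        genes_total += len(reg)
    return {
        "runs_with_allelic_call_rate": runs_with_allelic / n_runs,
        "false_category_rate": bad_categories / genes_total,
        "n_runs": n_runs,
        "n_genes_per_run": n_genes,
    }


def category_recovery(
    n_genes: int = 2000,
    depth: float = 1000.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of true regulatory categories from a known mixture."""
    mix = {
        "conserved": 0.70,
        "cis_only": 0.10,
        "trans_only": 0.10,
        "cis_plus_trans": 0.05,
        "cis_by_trans": 0.05,
    }
    cfg = SimConfig(
        n_genes=n_genes,
        category_mix=mix,
        effect_range=(1.0, 2.5),
        base_mean=depth,
        base_mean_spread=0.0,
        dispersion=dispersion,
        mean_snps_per_gene=5.0,
        seed=seed,
    )
    sim = simulate_cross(cfg)
    kept, _ = filter_snp_sites(sim.counts)
    gene_table = aggregate_to_genes(kept)
    factors = tmm_factors(gene_totals_matrix(gene_table))
    reg = run_regulatory(gene_table, factors)
    merged = reg.merge(sim.truth, on="gene_id", suffixes=("_called", "_true"))
    non_conserved = merged[merged["category_true"] != "conserved"]
    recovery = float(
        (non_conserved["category_called"] == non_conserved["category_true"]).mean()
    )
    cis_err = np.abs(merged["cis"] - merged["cis_effect"])
    return {
        "recovery_rate": recovery,
        "median_cis_abs_error": float(np.median(cis_err)),
        "n_non_conserved": int(len(non_conserved)),
        "n_genes": int(len(merged)),
    }


def inheritance_recovery(
    n_per_cluster: int = 60,
    effect: float = 1.0,
    depth: float = 1000.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of the eight inheritance clusters at two-fold effects,
    plus exactness of the parent-relabelling permutation."""
    specs = inheritance_scenario_specs(
        n_per_cluster=n_per_cluster,
        effect=effect,
        base_mean=depth,
        dispersion=dispersion,
    )
    cfg = SimConfig(
        n_genes=len(specs),
        base_mean=depth,
        base_mean_spread=0.0,
        dispersion=dispersion,
        mean_snps_per_gene=1.0,
        seed=seed,
    )
    sim = simulate_from_specs(specs, cfg)
    kept, _ = filter_snp_sites(sim.counts)
    gene_table = aggregate_to_genes(kept)
    totals = gene_totals_matrix(gene_table)
    factors = tmm_factors(totals)
    contrasts = run_contrasts(totals, factors)
    calls = classify_inheritance(contrasts, female="parent1")
    merged = calls.merge(sim.truth[["gene_id", "expected_cluster"]], on="gene_id")
    swapped = classify_inheritance(contrasts, female="parent2")
    swap_exact = all(
        PARENT_SWAP[a] == b for a, b in zip(calls["cluster"], swapped["cluster"])
    )
    return {
        "recovery_rate": float(
            (merged["cluster"] == merged["expected_cluster"]).mean()
        ),
        "parent_swap_exact": bool(swap_exact),
        "n_genes": int(len(merged)),
    }


def tmm_properties(seed: int = 0) -> dict:
    """TMM factor behaviour on composition-identical and contaminated data."""
    rng = np.random.default_rng(seed)
    base = rng.integers(50, 2000, 1000)
    # composition-identical libraries at assorted depths
    ident = pd.DataFrame(
        {"f1_r1": base, "f1_r2": base * 3, "f1_r3": base * 10}
    )
    fac_ident = tmm_factors(ident)["tmm_factor"].to_numpy()
    # one library with 5% of genes inflated eight-fold
    contaminated = base.copy()
    hit = rng.choice(base.size, base.size // 20, replace=False)
    contaminated[hit] = contaminated[hit] * 8
    mat = pd.DataFrame({"parent1_r1": base, "parent1_r2": contaminated})
    fac = tmm_factors(mat)
    norm = cpm(mat, fac)
    unchanged = np.setdiff1d(np.arange(base.size), hit)
    agreement = norm.iloc[unchanged, 1].mean() / norm.iloc[unchanged, 0].mean()
    geo_dev = abs(float(np.exp(np.mean(np.log(fac["tmm_factor"])))) - 1.0)
    return {
        "identical_composition_max_dev": float(np.max(np.abs(fac_ident - 1.0))),
        "geometric_mean_dev": geo_dev,
        "contaminated_factor": float(fac.loc["parent1_r2", "tmm_factor"]),
        "unchanged_gene_agreement_dev": float(abs(agreement - 1.0)),
        "n_genes": int(base.size),
    }


def cross_contrast(n_genes: int = 1500, seed: int = 0) -> dict:
    """Two simulated crosses differing in cis:trans mixture 1:2 vs 2:1.

    Runs the full pipeline on each and compares the cis_only fraction
    and the median %cis among significant genes between the crosses.
    """
    shared = dict(
        n_genes=n_genes,
        effect_range=(1.0, 2.5),
        n_replicates=3,
        mean_snps_per_gene=3.0,
    )
    mix_trans = {
        "conserved": 0.79, "cis_only": 0.05, "trans_only": 0.10,
        "cis_plus_trans": 0.03, "cis_by_trans": 0.03,
    }
    mix_cis = {
        "conserved": 0.79, "cis_only": 0.10, "trans_only": 0.05,
        "cis_plus_trans": 0.03, "cis_by_trans": 0.03,
    }
    sim_a = simulate_cross(SimConfig(category_mix=mix_trans, seed=seed, **shared))
    sim_b = simulate_cross(SimConfig(category_mix=mix_cis, seed=seed + 1, **shared))
    res_a = analyze_counts(sim_a.counts, label="trans_dominant")
    res_b = analyze_counts(sim_b.counts, label="cis_dominant")
    cmp = compare_crosses(res_a["summary"], res_b["summary"])
    return {
        "cis_only_fraction_trans_dominant": cmp["cis_only_among_genes"]["fraction_a"],
        "cis_only_fraction_cis_dominant": cmp["cis_only_among_genes"]["fraction_b"],
        "cis_only_fisher_p": cmp["cis_only_among_genes"]["fisher_p"],
        "median_pct_cis_trans_dominant": cmp["median_pct_cis_sig_a"],
        "median_pct_cis_cis_dominant": cmp["median_pct_cis_sig_b"],
        "n_genes_per_cross": n_genes,
    }


#: (site label, F1 pooled a1, F1 pooled a2, expected rejection reason or None)
FILTER_TOY_SITES = [
    ("ok_boundary", 2, 18, None),
    ("ok_equal", 10, 10, None),
    ("ok_large", 250, 300, None),
    ("ok_minor_exact", 2, 98, None),
    ("ok_total_exact", 5, 15, None),
    ("minor_one", 1, 25, "min_minor"),
    ("minor_zero", 0, 40, "min_minor"),
    ("minor_one_big", 1, 199, "min_minor"),
    ("total_nineteen", 9, 10, "min_total"),
    ("total_two", 1, 1, "min_minor"),
    ("total_zero", 0, 0, "min_minor"),
    ("minor_before_total", 1, 10, "min_minor"),
    ("total_seventeen", 8, 9, "min_total"),
    ("ok_skewed", 3, 500, None),
    ("minor_one_total_low", 1, 5, "min_minor"),
    ("total_eighteen", 2, 16, "min_total"),
    ("ok_mid", 25, 25, None),
    ("total_low_sym", 7, 7, "min_total"),
    ("minor_zero_total_low", 0, 10, "min_minor"),
    ("ok_wide", 2, 20, None),
]


def filter_conformance() -> dict:
    """Boundary behaviour of the SNP-site filters on a 20-site toy table."""
    rows = []
    for name, a1, a2, _ in FILTER_TOY_SITES:
        rows.append(
            {
                "site_id": name,
                "gene_id": name,
                "parent1_r1_a1": 30,
                "parent2_r1_a2": 30,
                "f1_r1_a1": a1,
                "f1_r1_a2": a2,
            }
        )
    table = pd.DataFrame(rows)
    kept, log = filter_snp_sites(table, min_minor=2, min_total=20)
    log_map = dict(zip(log["site_id"], log["reason"]))
    correct = 0
    for name, _, _, reason in FILTER_TOY_SITES:
        if reason is None:
            correct += name in set(kept["site_id"]) and name not in log_map
        else:
            correct += log_map.get(name) == reason
    return {
        "n_sites": len(FILTER_TOY_SITES),
        "n_correct": int(correct),
        "all_correct": bool(correct == len(FILTER_TOY_SITES)),
    }
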