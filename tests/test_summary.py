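"""Comparative statistics and end-to-end orchestration."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import cistrans as ct
from cistrans.summary import (
    PipelineError,
    analyze_counts,
    category_by_cluster_table,
    compare_crosses,
    correlate_divergence,
    pct_cis_by_bin,
    pct_cis_by_inheritance,
    rank_sum_test,
    run_all,
)


def reg_frame(cis, trans, categories=None, sig_allelic=None, sig_trans=None):
    cis = np.asarray(cis, dtype=float)
    trans = np.asarray(trans, dtype=float)
    n = cis.size
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "cis": cis,
            "trans": trans,
            "parental_div": cis + trans,
            "pct_cis": ct.pct_cis(cis, trans),
            "sig_allelic": sig_allelic if sig_allelic is not None else [True] * n,
            "sig_trans": sig_trans if sig_trans is not None else [True] * n,
            "category": categories if categories is not None else ["cis_only"] * n,
        }
    )


class TestRankSum:
    def test_exact_small_sample(self):
        # complete separation of 3 vs 3: two of C(6,3) orderings
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_shift_detected_at_scale(self, rng):
        x = rng.normal(0, 1, 500)
        y = rng.normal(0.5, 1, 500)
        assert rank_sum_test(x, y) < 0.01


class TestCorrelateDivergence:
    def test_pure_trans_gives_tau_one(self):
        trans = np.linspace(-2, 2, 30)
        reg = reg_frame(np.zeros(30), trans)
        out = correlate_divergence(reg)
        assert out["tau_trans"] == pytest.approx(1.0)

    def test_sign_reversal_negates_tau(self, rng):
        cis = rng.normal(size=60)
        trans = rng.normal(size=60)
        out = correlate_divergence(reg_frame(cis, trans))
        flipped = correlate_divergence(reg_frame(-cis, trans + 2 * cis))
        # parental_div is unchanged; cis sign flipped
        assert flipped["tau_cis"] == pytest.approx(-out["tau_cis"], abs=1e-12)

    def test_independent_cis_tau_near_zero(self, rng):
        # parental divergence drawn independently of the cis estimate
        n = 400
        reg = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "cis": rng.normal(size=n),
                "trans": np.zeros(n),
                "parental_div": rng.normal(size=n) * 3,
            }
        )
        out = correlate_divergence(reg)
        assert abs(out["tau_cis"]) < 0.1


class TestPctCisByBin:
    def test_constant_pct_cis(self):
        reg = reg_frame(np.full(40, 0.5), np.full(40, 0.5))
        out = pct_cis_by_bin(reg)
        assert (out["median_pct_cis"] == 50.0).all()

    def test_single_bin(self):
        reg = reg_frame([0.05] * 5, [0.05] * 5)  # all folds ~1.07, first bin
        out = pct_cis_by_bin(reg)
        assert len(out) == 1
        assert out.loc[0, "n"] == 5

    def test_declining_cis_share_with_divergence(self):
        # trans grows with divergence while cis stays constant
        trans = np.repeat([0.1, 1.0, 2.0, 3.0], 20)
        cis = np.full(80, 0.2)
        out = pct_cis_by_bin(reg_frame(cis, trans))
        med = out["median_pct_cis"].to_numpy()
        assert np.all(np.diff(med) < 0)


def calls_frame(clusters):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(len(clusters))], "cluster": clusters}
    )


class TestPctCisByInheritance:
    def test_contrast_between_strata(self):
        # additive genes trans-driven, non-additive genes cis-driven
        reg = reg_frame(
            np.r_[np.full(30, 0.05), np.full(30, 1.5)],
            np.r_[np.full(30, 1.5), np.full(30, 0.05)],
        )
        calls = calls_frame(["additivity_f_gt_m"] * 30 + ["overdominance"] * 30)
        out = pct_cis_by_inheritance(reg, calls)
        assert out["median_pct_cis_non_additive"] > out["median_pct_cis_additive"]
        assert out["wilcoxon_p"] < 0.01

    def test_absent_stratum_reported(self):
        reg = reg_frame([1.0, 0.5], [0.2, 0.1])
        calls = calls_frame(["overdominance", "female_dominance_up"])
        out = pct_cis_by_inheritance(reg, calls)
        assert out["n_additive"] == 0
        assert out["median_pct_cis_additive"] is None
        assert out["wilcoxon_p"] is None


class TestCategoryByCluster:
    def test_single_gene_cell(self):
        reg = reg_frame([1.0], [0.0], categories=["cis_only"])
        calls = calls_frame(["additivity_f_gt_m"])
        counts, pct = category_by_cluster_table(reg, calls)
        assert counts.loc["cis_only", "additivity"] == 1
        assert pct.loc["cis_only", "additivity"] == 100.0

    def test_column_percentages_sum_to_100(self, rng):
        n = 200
        cats = rng.choice(list(ct.REGULATORY_CATEGORIES), n)
        clus = rng.choice([c for c in ct.CLUSTERS if c != "no_change"], n)
        counts, pct = category_by_cluster_table(
            reg_frame(rng.normal(size=n), rng.normal(size=n), categories=cats),
            calls_frame(clus),
        )
        sums = pct.sum(axis=0).to_numpy()
        assert np.allclose(sums, 100.0, atol=0.1)
        assert (counts.sum(axis=1).sum()) == n


class TestCompareCrosses:
    def _summary(self, label, cis_only, n_genes, nonadd, trans, ndeg, cis_sig=50):
        return ct.CrossSummary(
            label=label,
            n_genes=n_genes,
            inheritance={
                "n_genes": n_genes,
                "n_deg": ndeg,
                "deg_fraction": ndeg / n_genes,
                "cluster_counts": {
                    "additivity_f_gt_m": ndeg - nonadd,
                    "overdominance": trans,
                    "female_dominance_up": nonadd - trans,
                },
            },
            magnitudes=None,
            correlations=None,
            pct_cis_bins=pd.DataFrame(),
            pct_cis_inheritance={},
            contingency_counts=pd.DataFrame(),
            contingency_pct=pd.DataFrame(),
            category_counts={"cis_only": cis_only},
            n_cis_sig=cis_sig,
            median_pct_cis_sig=50.0,
        )

    def test_identical_crosses_p_one(self):
        a = self._summary("a", 30, 1000, 40, 10, 100)
        out = compare_crosses(a, a)
        assert out["cis_only_among_genes"]["fisher_p"] == 1.0
        assert out["transgressive_among_degs"]["fisher_p"] == 1.0

    def test_symmetry_under_swap(self):
        a = self._summary("a", 30, 1000, 40, 10, 100)
        b = self._summary("b", 80, 1000, 70, 30, 120)
        ab, ba = compare_crosses(a, b), compare_crosses(b, a)
        for key in ("cis_only_among_genes", "non_additive_among_degs"):
            assert ab[key]["fisher_p"] == pytest.approx(ba[key]["fisher_p"], abs=1e-12)

    def test_diagonal_toy_counts(self):
        a = self._summary("a", 5, 5, 0, 0, 5, cis_sig=5)
        b = self._summary("b", 0, 5, 0, 0, 5, cis_sig=0)
        out = compare_crosses(a, b)
        assert out["cis_only_among_genes"]["fisher_p"] == pytest.approx(2 / 252)


class TestRunAll:
    def test_smoke_emits_all_declared_files(self, tmp_path):
        config = {
            "simulation": {"n_genes": 200, "mean_snps_per_gene": 2.0},
            "seed": 77,
            "label": "toy",
        }
        res = run_all(config, tmp_path)
        for name in (
            "counts.tsv",
            "truth.tsv",
            "rejected_sites.tsv",
            "gene_counts.tsv",
            "qc.tsv",
            "tmm_factors.tsv",
            "normalized_cpm.tsv",
            "contrasts.tsv",
            "inheritance.tsv",
            "regulatory.tsv",
            "summary.json",
            "report.txt",
            "manifest.json",
        ):
            assert (tmp_path / name).exists(), name
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 77
        assert res["summary"].n_genes > 0
        report = (tmp_path / "report.txt").read_text()
        assert "Regulatory categories" in report

    def test_deterministic_given_seed(self, tmp_path):
        config = {"simulation": {"n_genes": 120}, "seed": 5, "label": "det"}
        run_all(config, tmp_path / "a")
        run_all(config, tmp_path / "b")
        for name in ("summary.json", "regulatory.tsv", "inheritance.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_dual_mapping_route(self, tmp_path):
        config = {
            "simulation": {"n_genes": 80, "mapping_bias": 0.3},
            "seed": 13,
        }
        run_all(config, tmp_path)
        assert (tmp_path / "mapping1.tsv").exists()
        merged = pd.read_csv(tmp_path / "counts.tsv", sep="\t")
        m1 = pd.read_csv(tmp_path / "mapping1.tsv", sep="\t")
        a2 = [c for c in merged.columns if c.startswith("f1") and c.endswith("a2")]
        assert merged[a2].to_numpy().sum() >= m1[a2].to_numpy().sum()

    def test_missing_input_block_aborts_with_stage(self, tmp_path):
        with pytest.raises(PipelineError, match=r"\[config\]"):
            run_all({}, tmp_path)

    def test_file_input_route(self, tmp_path, small_sim):
        counts_path = tmp_path / "counts.tsv"
        ct.write_counts_tsv(small_sim.counts, counts_path)
        res = run_all({"inputs": {"counts": str(counts_path)}}, tmp_path / "out")
        assert res["summary"].n_genes > 0
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert "counts" in manifest["inputs"]


def test_hybrid_parent_correlation_is_strong_on_shared_signal(small_sim):
    res = analyze_counts(small_sim.counts, apply_qc=False)
    corr = res["hybrid_parent_correlation"]
    # hybrid expression tracks the mid-parent closely in a mostly
    # conserved transcriptome
    assert corr["pearson_r_mid_parent"] > 0.9
    assert corr["pearson_r_parent1"] > 0.8


def test_gene_universes_reconcile_across_outputs(small_sim):
    res = analyze_counts(small_sim.counts, apply_qc=False)
    reg_genes = set(res["regulatory"]["gene_id"])
    inh_genes = set(res["inheritance"]["gene_id"])
    table_genes = set(res["gene_table"]["gene_id"])
    assert inh_genes == table_genes
    assert reg_genes <= table_genes
    assert res["regulatory"]["gene_id"].is_unique
    assert res["inheritance"]["gene_id"].is_unique
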