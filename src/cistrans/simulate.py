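"""Seeded simulator for parent/F1 allele-specific read-count tables.

The generative model mirrors how cis- and trans-acting regulatory
divergence shapes read counts.  For a gene with cis effect ``c`` and trans
effect ``t`` (both log2 units), base mean ``mu`` and library factor ``s``:

* parent-1 libraries draw negative-binomial counts with mean
  ``mu * 2**((c+t)/2) * s`` and parent-2 with ``mu * 2**(-(c+t)/2) * s``,
  so the expected parental log2 ratio is exactly ``c + t`` and total
  expression magnitude is decoupled from divergence;
* F1 libraries draw a negative-binomial total with mean
  ``mu * 2**f1_shift * s`` (``f1_shift = 0`` places the hybrid at the
  geometric mid-parent) and split it binomially between the two alleles
  with allele-1 share ``2**c / (1 + 2**c)`` — only cis divergence moves
  the allelic ratio, whose expected log2 value is ``c``;
* each gene's count is then partitioned across its diagnostic SNP sites
  with a symmetric multinomial, so site counts sum exactly to the gene
  count;
* optional allele-mapping bias emits two per-pseudo-genome mapping tables
  in which the non-matching allele's reads are binomially thinned; the
  downstream max-rule merge recovers the unbiased counts.

Negative-binomial dispersion follows the usual RNA-seq convention
``var = mu + dispersion * mu**2``; dispersion 0 degenerates to Poisson.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._naming import LibraryColumn

CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
)

#: Inheritance-cluster labels (female parent = parent1 by convention).
CLUSTERS = (
    "additivity_f_gt_m",
    "additivity_f_lt_m",
    "female_dominance_up",
    "female_dominance_down",
    "male_dominance_up",
    "male_dominance_down",
    "overdominance",
    "underdominance",
    "no_change",
)

_DEFAULT_MIX = {
    "conserved": 0.80,
    "cis_only": 0.05,
    "trans_only": 0.07,
    "cis_plus_trans": 0.03,
    "cis_by_trans": 0.03,
    "compensatory": 0.02,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimGeneSpec:
    """True regulatory state of one simulated gene.

    ``f1_shift`` (log2) moves the F1 total away from the geometric
    mid-parent and is used to simulate non-additive inheritance.
    """

    gene_id: str
    category: str
    cis_effect: float
    trans_effect: float
    base_mean: float
    dispersion: float
    n_snps: int
    f1_shift: float = 0.0

    def validate(self) -> None:
        c, t = self.cis_effect, self.trans_effect
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {self.category!r}")
        if self.base_mean <= 0:
            raise ConfigurationError("base_mean must be > 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        ok = {
            "conserved": c == 0 and t == 0,
            "cis_only": t == 0 and abs(c) > 0,
            "trans_only": c == 0 and abs(t) > 0,
            "cis_plus_trans": c * t > 0,
            "cis_by_trans": c * t < 0 and c + t != 0,
            "compensatory": t == -c and c != 0,
        }[self.category]
        if not ok:
            raise ConfigurationError(
                f"effects (cis={c}, trans={t}) inconsistent with category {self.category!r}"
            )


@dataclass
class SimConfig:
    """Configuration of one simulated cross.

    ``library_size_factors`` may be a flat sequence over the libraries in
    order (parent1 replicates, parent2 replicates, F1 replicates) or
    ``None`` for all ones.  ``base_mean`` is the geometric-mean expected
    reads per gene per library; per-gene means scatter around it
    log-normally with log2 standard deviation ``base_mean_spread``
    (set 0 for equal depth at every gene).  ``effect_range`` bounds the
    |log2| effect sizes drawn uniformly for non-conserved genes.
    """

    n_genes: int = 2000
    category_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    effect_range: tuple = (0.5, 2.5)
    n_replicates: int = 3
    base_mean: float = 500.0
    base_mean_spread: float = 2.5
    dispersion: float = 0.05
    mean_snps_per_gene: float = 5.0
    library_size_factors: tuple | None = None
    mapping_bias: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.base_mean <= 0:
            raise ConfigurationError("base_mean must be > 0")
        if self.base_mean_spread < 0:
            raise ConfigurationError("base_mean_spread must be >= 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.mean_snps_per_gene < 1:
            raise ConfigurationError("mean_snps_per_gene must be >= 1")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9 or min(self.category_mix.values()) < 0:
            raise ConfigurationError("category_mix must be nonnegative and sum to 1")
        lo, hi = self.effect_range
        if not (0 < lo <= hi):
            raise ConfigurationError("effect_range must satisfy 0 < low <= high")
        if self.library_size_factors is not None:
            fac = np.asarray(self.library_size_factors, dtype=float)
            if fac.shape != (3 * self.n_replicates,):
                raise ConfigurationError(
                    "library_size_factors must have one entry per library "
                    f"(expected {3 * self.n_replicates})"
                )
            if np.any(fac <= 0):
                raise ConfigurationError("library_size_factors must be > 0")
        if self.mapping_bias is not None and not (0 <= self.mapping_bias < 1):
            raise ConfigurationError("mapping_bias must lie in [0, 1)")

    def size_factors(self) -> np.ndarray:
        if self.library_size_factors is None:
            return np.ones(3 * self.n_replicates)
        return np.asarray(self.library_size_factors, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["library_size_factors"] is not None:
            d["library_size_factors"] = list(d["library_size_factors"])
        d["effect_range"] = list(d["effect_range"])
        return d


@dataclass
class SimResult:
    """Simulation output bundle.

    ``counts`` is the unbiased site-level table; ``mapping1``/``mapping2``
    are the two per-pseudo-genome mapping versions (present only when
    mapping bias is simulated).  ``gene_counts`` holds the drawn per-gene
    library counts before site partitioning, for conservation checks.
    ``truth`` carries per-gene regulatory effects, their implied expected
    ratios, and the expected inheritance cluster.
    """

    counts: pd.DataFrame
    truth: pd.DataFrame
    gene_counts: pd.DataFrame
    config: SimConfig
    mapping1: pd.DataFrame | None = None
    mapping2: pd.DataFrame | None = None

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("counts", self.counts),
            ("truth", self.truth),
            ("gene_counts", self.gene_counts),
            ("mapping1", self.mapping1),
            ("mapping2", self.mapping2),
        ]:
            if df is None:
                continue
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[name] = str(p)
        cfg = out / "config.json"
        cfg.write_text(json.dumps(self.config.to_dict(), indent=2) + "\n")
        paths["config"] = str(cfg)
        return paths


def _library_columns(n_replicates: int) -> list[LibraryColumn]:
    cols = []
    for cls in ("parent1", "parent2"):
        for r in range(1, n_replicates + 1):
            cols.append(LibraryColumn(cls, r, "a1" if cls == "parent1" else "a2"))
    for r in range(1, n_replicates + 1):
        cols.append(LibraryColumn("f1", r, "a1"))
        cols.append(LibraryColumn("f1", r, "a2"))
    return cols


def draw_gene_specs(config: SimConfig, rng: np.random.Generator) -> list[SimGeneSpec]:
    """Draw per-gene regulatory states from the configured mixture."""
    cats = [c for c in CATEGORIES if config.category_mix.get(c, 0) > 0]
    probs = np.array([config.category_mix[c] for c in cats])
    probs = probs / probs.sum()
    lo, hi = config.effect_range
    width = len(str(config.n_genes))
    specs = []
    for i in range(config.n_genes):
        cat = cats[rng.choice(len(cats), p=probs)]
        c = t = 0.0
        if cat != "conserved":
            m1 = rng.uniform(lo, hi)
            m2 = rng.uniform(lo, hi)
            s = 1.0 if rng.random() < 0.5 else -1.0
            if cat == "cis_only":
                c = s * m1
            elif cat == "trans_only":
                t = s * m1
            elif cat == "cis_plus_trans":
                c, t = s * m1, s * m2
            elif cat == "cis_by_trans":
                while m1 == m2:  # c + t must not vanish exactly
                    m2 = rng.uniform(lo, hi)
                c, t = s * m1, -s * m2
            elif cat == "compensatory":
                c, t = s * m1, -s * m1
        n_snps = 1
        if config.mean_snps_per_gene > 1:
            n_snps = 1 + int(rng.poisson(config.mean_snps_per_gene - 1))
        mu = config.base_mean
        if config.base_mean_spread > 0:
            mu = mu * 2.0 ** rng.normal(0.0, config.base_mean_spread)
        spec = SimGeneSpec(
            gene_id=f"g{i + 1:0{width}d}",
            category=cat,
            cis_effect=c,
            trans_effect=t,
            base_mean=mu,
            dispersion=config.dispersion,
            n_snps=n_snps,
        )
        spec.validate()
        specs.append(spec)
    return specs


def expected_cluster(spec: SimGeneSpec, fc: float = 1.25) -> str:
    """Inheritance cluster implied by the expected means and the DEG gate.

    A hybrid-parent contrast counts as expected-differential when the
    expected fold change reaches ``fc``.  Genes whose expected ratios fall
    inside the gate are expected ``no_change``.
    """
    d = spec.cis_effect + spec.trans_effect
    r_f = spec.f1_shift - d / 2.0  # log2 (F1 / parent1), parent1 = female
    r_m = spec.f1_shift + d / 2.0  # log2 (F1 / parent2)
    thr = math.log2(fc) - 1e-12
    sig_f, sig_m = abs(r_f) >= thr, abs(r_m) >= thr
    if not sig_f and not sig_m:
        return "no_change"
    if sig_f and sig_m:
        if r_f * r_m < 0:
            return "additivity_f_gt_m" if d > 0 else "additivity_f_lt_m"
        return "overdominance" if r_f > 0 else "underdominance"
    if sig_m:  # F1 matches the female parent
        return "female_dominance_up" if r_m > 0 else "female_dominance_down"
    return "male_dominance_up" if r_f > 0 else "male_dominance_down"


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_from_specs(specs: list[SimGeneSpec], config: SimConfig) -> SimResult:
    """Simulate count tables for explicit gene specs (seeded by the config)."""
    config.validate()
    for s in specs:
        s.validate()
    rng = np.random.default_rng(config.seed)
    return _simulate(specs, config, rng)


def simulate_cross(config: SimConfig) -> SimResult:
    """Draw gene states from the mixture and simulate the full cross."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = draw_gene_specs(config, rng)
    return _simulate(specs, config, rng)


def _simulate(specs, config: SimConfig, rng: np.random.Generator) -> SimResult:
    n_rep = config.n_replicates
    n_genes = len(specs)
    s_fac = config.size_factors()
    s_p1, s_p2, s_f1 = s_fac[:n_rep], s_fac[n_rep:2 * n_rep], s_fac[2 * n_rep:]

    c = np.array([s.cis_effect for s in specs])
    t = np.array([s.trans_effect for s in specs])
    mu = np.array([s.base_mean for s in specs])
    phi = np.array([s.dispersion for s in specs])
    shift = np.array([s.f1_shift for s in specs])
    n_snps = np.array([s.n_snps for s in specs])

    d = c + t
    mean_p1 = mu * 2.0 ** (d / 2.0)
    mean_p2 = mu * 2.0 ** (-d / 2.0)
    mean_f1 = mu * 2.0 ** shift
    share_a1 = 2.0 ** c / (1.0 + 2.0 ** c)

    def draw_matrix(means_by_lib):
        # one NB vector per library, gene-wise dispersion handled by grouping
        cols = []
        for m in means_by_lib:
            if np.all(phi == phi[0]):
                cols.append(_nb_draw(rng, m, float(phi[0])))
            else:
                out = np.empty(n_genes, dtype=np.int64)
                for ph in np.unique(phi):
                    idx = phi == ph
                    out[idx] = _nb_draw(rng, m[idx], float(ph))
                cols.append(out)
        return np.column_stack(cols)

    p1 = draw_matrix([mean_p1 * s for s in s_p1])
    p2 = draw_matrix([mean_p2 * s for s in s_p2])
    f1_tot = draw_matrix([mean_f1 * s for s in s_f1])
    f1_a1 = np.column_stack(
        [rng.binomial(f1_tot[:, j], share_a1) for j in range(n_rep)]
    )
    f1_a2 = f1_tot - f1_a1

    lib_cols = _library_columns(n_rep)
    gene_mat = np.hstack([p1, p2])
    f1_interleaved = np.empty((n_genes, 2 * n_rep), dtype=np.int64)
    f1_interleaved[:, 0::2] = f1_a1
    f1_interleaved[:, 1::2] = f1_a2
    gene_mat = np.hstack([gene_mat, f1_interleaved])

    gene_ids = [s.gene_id for s in specs]
    gene_counts = pd.DataFrame(gene_mat, columns=[lc.name for lc in lib_cols])
    gene_counts.insert(0, "gene_id", gene_ids)

    # Partition each gene's counts across its SNP sites (multinomial, equal
    # site weights); order of draws is fixed: by gene, then by column.
    site_rows = []
    site_ids, site_genes = [], []
    n_cols = gene_mat.shape[1]
    for gi in range(n_genes):
        k = int(n_snps[gi])
        if k == 1:
            block = gene_mat[gi].reshape(1, n_cols)
        else:
            w = np.full(k, 1.0 / k)
            block = np.empty((k, n_cols), dtype=np.int64)
            for j in range(n_cols):
                block[:, j] = rng.multinomial(gene_mat[gi, j], w)
        site_rows.append(block)
        site_ids.extend(f"{gene_ids[gi]}_s{si + 1}" for si in range(k))
        site_genes.extend([gene_ids[gi]] * k)
    counts = pd.DataFrame(np.vstack(site_rows), columns=[lc.name for lc in lib_cols])
    counts.insert(0, "gene_id", site_genes)
    counts.insert(0, "site_id", site_ids)

    mapping1 = mapping2 = None
    if config.mapping_bias is not None and config.mapping_bias > 0:
        keep = 1.0 - config.mapping_bias
        mapping1 = counts.copy()
        mapping2 = counts.copy()
        for lc in lib_cols:
            if lc.sample_class != "f1":
                continue
            vals = counts[lc.name].to_numpy()
            if lc.allele == "a2":  # thinned when mapped to the parent-1 genome
                mapping1[lc.name] = rng.binomial(vals, keep)
            else:  # thinned when mapped to the parent-2 genome
                mapping2[lc.name] = rng.binomial(vals, keep)
    elif config.mapping_bias == 0:
        mapping1 = counts.copy()
        mapping2 = counts.copy()

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": [s.category for s in specs],
            "cis_effect": c,
            "trans_effect": t,
            "f1_shift": shift,
            "base_mean": mu,
            "dispersion": phi,
            "n_snps": n_snps,
            "expected_parental_log2": c + t,
            "expected_f1_allelic_log2": c,
            "expected_cluster": [expected_cluster(s) for s in specs],
        }
    )
    return SimResult(
        counts=counts,
        truth=truth,
        gene_counts=gene_counts,
        config=config,
        mapping1=mapping1,
        mapping2=mapping2,
    )


def inheritance_scenario_specs(
    n_per_cluster: int = 50,
    effect: float = 1.0,
    base_mean: float = 1000.0,
    dispersion: float = 0.05,
    n_snps: int = 1,
) -> list[SimGeneSpec]:
    """Gene specs spanning the eight inheritance clusters.

    ``effect`` is the log2 magnitude of every expected-differential
    hybrid-parent contrast (1.0 = two-fold).  Parental divergence is
    realised through the trans effect so the allelic ratio stays balanced.
    Returned specs carry the intended cluster in ``expected_cluster``.
    """
    # (trans effect multiplier of `effect`, f1_shift multiplier of `effect`)
    layout = [
        ("additivity_f_gt_m", 2.0, 0.0),
        ("additivity_f_lt_m", -2.0, 0.0),
        ("female_dominance_up", 1.0, 0.5),
        ("female_dominance_down", -1.0, -0.5),
        ("male_dominance_up", -1.0, 0.5),
        ("male_dominance_down", 1.0, -0.5),
        ("overdominance", 0.0, 1.0),
        ("underdominance", 0.0, -1.0),
    ]
    specs = []
    for cluster, t_mult, f_mult in layout:
        for i in range(n_per_cluster):
            tval = t_mult * effect
            spec = SimGeneSpec(
                gene_id=f"{cluster}_{i + 1:03d}",
                category="trans_only" if tval != 0 else "conserved",
                cis_effect=0.0,
                trans_effect=tval,
                base_mean=base_mean,
                dispersion=dispersion,
                n_snps=n_snps,
                f1_shift=f_mult * effect,
            )
            spec.validate()
            assert expected_cluster(spec) == cluster
            specs.append(spec)
    return specs
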