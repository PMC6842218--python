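# Methods

This note documents the statistical model behind `cistrans`, the
decisions taken where the design was genuinely open, what the simulator
does and does not emulate, and the known limitations of the classical
testing scheme the package implements.

## Cis/trans decomposition

For each gene, let `P1`, `P2` be parental expression levels and `F1A1`,
`F1A2` the allele-specific levels in the F1 hybrid, each the arithmetic
mean over biological replicates of normalized counts (counts divided by
the TMM effective library size), rescaled to the mean effective library
size and rounded half-to-even to integers. Rounding half-to-even keeps
pooling deterministic and unbiased; the integer pseudo-counts feed the
exact tests. Estimates use a pseudocount of 0.5 inside the log ratios so
they stay finite at zero counts — the pseudocount never enters the test
counts, which would bias the exact null distributions:

* `parental_div = log2((P1+½)/(P2+½))`
* `cis = log2((F1A1+½)/(F1A2+½))`
* `trans = parental_div − cis` (the identity is exact by construction)
* `%cis = |cis|/(|cis|+|trans|)·100`, undefined (reported absent) when
  both estimates are exactly zero.

The logic: both alleles in the hybrid share one trans environment, so
allelic imbalance isolates cis divergence, and the residual parental
divergence is attributed to trans.

### Significance and categories

Three families of exact two-sided tests are run per gene, each with
Benjamini–Hochberg FDR control at 5% applied separately within its
family (parental binomial A, allelic binomial B, trans Fisher C). All
two-sided p-values use the method of small probabilities: the p-value is
the total null probability of outcomes no more probable than the one
observed. The flag triple maps onto seven categories; three of the eight
flag combinations — those where the single significant signal cannot be
coherently attributed — fall into `ambiguous`, as does the
measure-zero case of a significant three-way call with a cis or trans
estimate of exactly 0 (direction undefined).

Implementation notes for the exact tests:

* The binomial tests are at success probability ½, where symmetry makes
  the two-sided sum a closed form in the CDF (no tie tolerance needed).
* Fisher's test enumerates the hypergeometric support. Tables with grand
  total ≤ 300 are evaluated in exact integer arithmetic, so probability
  ties are decided exactly; larger tables use floating-point enumeration
  with the conventional `1 + 1e-7` relative tie gate, restricted to a
  ±40 SD window around the mode (the excluded tail mass is negligible at
  any usable precision; the observed cell is always included).
* The differential-expression engine is a conditional negative-binomial
  exact test: with common dispersion φ, each group total over n
  libraries is NB with size n/φ, and the split of the pooled total
  between groups is, under the null, beta-binomial — free of the unknown
  mean. φ = 0 degenerates to the Poisson/binomial case. The common
  dispersion is estimated by the method of moments (median over genes of
  `(s² − m)/m²` from pooled within-group variances), which recovers
  simulated dispersions well at a few thousand genes. The engine is
  pluggable: `run_contrasts` accepts a supplied dispersion.

### Inheritance classification

A gene is a DEG for a contrast when the BH-adjusted p-value is < 0.05
**and** the point-estimate fold change (with a 0.5 pseudocount) reaches
1.25. The two hybrid–parent contrasts then classify: neither significant
→ `no_change`; both, in opposite directions → additivity, subtyped by
whether the female parent out-expresses the male parent (read off the
parental contrast); exactly one significant → expression-level dominance
toward the parent the hybrid matches, with up/down taken from the sign
of the significant contrast (the verbal convention does not fix this; we
declare it); both in the same direction → over-/underdominance.
Relabelling which parent is female applies an exact permutation to the
clusters (additivity subtypes swap, female/male dominance swap,
transgressive clusters are fixed points).

## Normalization and QC

TMM scaling factors follow the published trimmed-mean-of-M-values
definition: M (log2 expression ratio) and A (average log2 abundance)
against a reference library (the one whose upper-quartile count fraction
is closest to the mean), genes with zero counts in either library
dropped, double trim of 30% on M and 5% on A, and an
inverse-asymptotic-variance weighted mean of the surviving M values;
factors are rescaled to geometric mean 1. One deliberate departure from
rank-based trimming: trimming is done on **value quantiles** with
inclusive bounds, which is equivalent on continuous data but robust to
the massive M-value ties produced by composition-identical libraries
(where tied average ranks can otherwise fall entirely outside the trim
window). An edgeR cross-check on continuous data agrees to ~0.5%.
Because the weights are depth-dependent, factors are only approximately
invariant to rescaling a single library (exactly invariant when M-values
are unaffected); this matches the reference implementation's behaviour.

Normalized expression is counts per million on the effective library
size. Whether normalization runs before or after aggregating SNP sites
to genes is immaterial here: the factors are per-library scalars, so
scaling commutes with within-gene summation; factors are computed on the
aggregated gene totals.

Replicate QC computes, per library, the squared Pearson correlation of
log2(CPM+1) with every same-class replicate; a library fails when its
median within-class R² is below 0.90 (boundary inclusive). Failing
libraries are excluded and factors recomputed, mirroring the practice of
dropping discordant replicates; exclusion that would leave a class with
fewer than two replicates aborts the run rather than silently degrading.

## The simulator

Per gene with cis effect c, trans effect t (log2), base mean μ, library
factor s, and F1 shift f (log2, default 0):

* parent-1 libraries ~ NB(μ·2^{(c+t)/2}·s, φ), parent-2 libraries ~
  NB(μ·2^{−(c+t)/2}·s, φ): the parental means are placed symmetrically
  about μ on the log2 scale so that expression magnitude is decoupled
  from divergence, and the expected parental log2 ratio is exactly c+t;
* F1 total ~ NB(μ·2^f·s, φ), split between alleles binomially with
  allele-1 share 2^c/(1+2^c); f = 0 puts the hybrid at the geometric
  mid-parent (additive baseline), and the inheritance scenarios set f
  per gene to produce dominance and transgressive patterns;
* the gene count is partitioned across its n SNP sites by a symmetric
  multinomial — sites share the gene's regulatory state and sum exactly
  to the gene count;
* variance = μ + φμ²; φ = 0 is Poisson. Default φ = 0.05 (typical for
  bulk RNA-seq biological replicates); calibration and recovery
  benchmarks state their own φ;
* per-gene base means scatter log-normally around the configured
  `base_mean` with log2 SD `base_mean_spread` (default 2.5, a realistic
  between-gene dynamic range; this is what gives replicate correlations
  their meaning — with equal means across genes, replicate R² is pure
  noise). Benchmarks that specify one fixed depth per gene set the
  spread to 0;
* default mixture: 80% conserved, 5% cis-only, 7% trans-only, 3% + 3%
  for the two interaction classes, 2% compensatory — of the order of the
  category frequencies reported for real interspecific crosses; effect
  magnitudes uniform in [0.5, 2.5] log2 with random sign (constrained to
  the category's sign structure);
* mapping bias b thins the non-matching allele's reads binomially (keep
  probability 1−b) in each per-pseudo-genome mapping; the
  max-of-two-mappings merge provably recovers the unbiased counts, and
  b = 0 yields byte-identical mapping copies.

Everything is driven by one `numpy` Generator seeded from the config, so
identical configs give byte-identical tables.

What the simulator does **not** emulate: read-level errors and mapping
ambiguity (bias enters only as binomial thinning), within-gene
heterogeneity of regulatory effects across SNP sites, isoforms,
correlated dispersion structure, GC/length biases, and genuinely
discordant replicates. Passing recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions, not robustness
to every artefact of real sequencing data.

## Calibration behaviour and known limitations

The allelic (cis) binomial family is conservative: the replicate-mean
pseudo-count halves-to-thirds the sampling variance relative to a single
binomial draw of the same size, and in an all-conserved global null at
depth 200, dispersion 0.1, none of 200 simulated runs produce a single
significant allelic call at BH 5%.

The parental binomial and trans Fisher families are **anti-conservative
under biological overdispersion**: they model the pooled pseudo-counts
as binomial/hypergeometric, but with NB dispersion φ the parental
log-ratio has variance ≈ 2(1/μ + φ)/n_rep, a ~2.6-fold SD inflation
over the binomial SE at μ = 200, φ = 0.1. Under the global null this
sends a substantial fraction of conserved genes into `ambiguous`
(parental flag alone) and ~5–6% into `trans_only` (parental + Fisher
flags). This is an inherent property of the classical binomial/Fisher
allele-specific-expression scheme, which ignores replicate variance in
those two tests; it is reproduced here deliberately, quantified by the
`null_calibration` benchmark, and should be kept in mind when
interpreting trans-heavy category counts. Approaches that would fix it
(overdispersed beta-binomial allelic models, GLM-based trans tests) are
out of scope.

Benchmark problem sizes (chosen to make the statistics stable at a few
seconds to tens of seconds per benchmark): 10 000 quadruples for the
decomposition identity; all ~635 000 2×2 tables with total ≤ 60 for the
Fisher oracle; 200 runs × 500 genes for the null calibration; 2 000
genes for category recovery; 60 genes per cluster for inheritance
recovery; 1 500 genes per cross for the two-cross contrast.

## Numerical details

* Rounding of pooled pseudo-counts: half-to-even (`np.rint`).
* Degenerate inputs: genes with all four pooled quantities zero are
  excluded from the regulatory analysis and logged; both-groups-all-zero
  DE contrasts return p = 1, log2FC = 0; zero-margin Fisher tables and
  zero-total binomials return p = 1.
* Site filters (minor allele ≥ 2, total ≥ 20 in the F1) are applied to
  counts pooled across F1 replicates by default — consistent with the
  replicate pooling of the allelic tests — with a per-replicate mode
  available; rejection reasons are logged per site, with the minor-allele
  reason taking precedence when both fail.
* Wilcoxon rank-sum comparisons use the exact distribution for untied
  samples of at most 25, otherwise the tie-corrected normal
  approximation without continuity correction (so identical samples give
  p = 1); rank correlations are Kendall τ-b.
* The fold-change gate compares the linear-scale point estimate against
  the threshold with a 1e-12 guard so that exact threshold equality
  counts as reaching the gate.
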