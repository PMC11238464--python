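# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the limits of what the test suite shows.

## Association model

Per gene, expression is modeled as

    y = X b + δ·s + u + e,   u ~ N(0, G σ²_u),   e ~ N(0, I σ²_e)

with `y` the TMM-normalized CPM on the natural scale, `X` an intercept plus
batch indicator(s), `s` the SNP dosage (copies of A1, mean-imputed where
missing) and `G` the per-SNP-standardized genomic relationship matrix built
from all QC-surviving SNPs with in-sample allele frequencies.

**Trait scale.** The model is fit on CPM directly, not log CPM — this
matches the analysis convention the pipeline reproduces. A `log1p_cpm`
option exists but is off by default. Natural-scale CPM is right-skewed, so
Wald tests lean on n = 100 asymptotics; the null-simulation test verifies
the resulting type-I error stays within [0.04, 0.06] at nominal 0.05.

**REML.** Variance components are estimated once per gene under the null
(no-SNP) model. `G` is eigendecomposed once per run and cached; in the
eigenbasis V is diagonal, and the restricted likelihood is profiled down to
a 1-D bounded search over log λ, λ = σ²_u/σ²_e ∈ [1e-6, 1e6], tolerance
1e-8, with explicit comparison against both boundaries. Boundary solutions
(σ²_u = 0) are permitted and flagged. If `G` is numerically a multiple of
the identity the split is not identifiable; the total variance is returned
as residual with `identifiable=False` rather than failing.

**Scan.** Each SNP is tested by GLS with V fixed at the null REML
estimates (the MLMA convention of mixed-model association tools — per-SNP
REML would be computationally disproportionate and changes little).
In the eigenbasis this reduces to weighted block regression; β, its
standard error from (WᵀV⁻¹W)⁻¹, and a Wald p against the standard normal
(not t: the difference at ~97 residual df is below 0.003 in the tail
fraction and matches the reference-tool convention). SNPs collinear with
the covariates (including monomorphic ones) yield NA statistics with a
reason code. The tested SNP stays in the GRM (no leave-one-chromosome-out);
the resulting slight proximal contamination is accepted and visible only as
conservatism at this scale.

REML boundary behaviour worth knowing: for an *unrelated* sample of
n = 100, the restricted likelihood is nearly flat in h² near zero, so null
traits give a diffuse estimate distribution (median ≈ 0.14, not 0). Median
recovery at true h² = 0.5 is within ±0.15 over 50 replicates; family
structure, which real studies have, would sharpen both.

## Genotype QC

Filters, in fixed order, each SNP attributed to the first filter it fails:
chromosome (Y, scaffolds/unplaced dropped; X kept and treated as autosomal
— the emulated study population is all female), missingness (> 10%
removed), MAF (< 0.01 removed, = 0.01 kept), HWE (exact conditional test,
Wigginton-style recurrence, no mid-p; p ≤ 1e-12 removed). The order is a
convention: it fixes the per-filter counts in the QC log, not the surviving
set. Samples are never removed. Coordinates are 1-based throughout; all
interval logic uses closed intervals; BED export converts to 0-based
half-open.

## Normalization

TMM follows the trimmed-mean-of-M-values definition exactly as the
reference implementation computes it: reference sample = the one whose
75th percentile of library-scaled counts is closest to the mean of those
percentiles; genes with zero counts in either sample excluded; 30% trim on
M, 5% on A (average ranks for ties); inverse-delta-method precision
weights; factors rescaled to geometric mean 1. Agreement with
edgeR::calcNormFactors is tested to 1e-6. Note the precision weights
depend on count depth, so factors are only approximately (≪ 1%) invariant
to rescaling one sample's counts.

CPM uses effective library sizes (column sum × TMM factor). Genes with
mean CPM across **all** samples ≥ 1 are kept. A gene is tissue-specific if
its mean CPM in the focal tissue is > 0 and ≥ 4× the mean in **each** other
tissue (the strictest reading of "4 times higher than the other tissues";
comparing against the pooled rest would be laxer).

## eQTL calling

BH q-values are computed over one family per run: all gene × SNP tests.
This genome-wide-per-tissue family is the most conservative defensible
scope consistent with a single q threshold; a per-gene option exists and
the scope is recorded in output metadata. NA p-values are excluded from
the ranking and carry NA q.

Regions: per gene and chromosome, sorted significant SNPs are split
wherever a consecutive gap is ≥ 10 Mb ("shorter than 10 Mb" merges, exact
10 Mb splits); runs of < 3 SNPs are discarded but counted, so significant
associations always partition into merged + discarded. The region span is
the closed interval of member SNP positions. The top SNP is the member
with smallest q (ties: smallest p, then smallest position).

Classification uses the top SNP's distance to the strand-aware TSS
(annotation start for +, end for −): cis ≤ 1 Mb inclusive; trans-I > 1 Mb
same chromosome; trans-II different chromosome; genes lacking TSS
annotation are left unclassified and excluded from class tallies.

LD within a region is the squared Pearson correlation of dosage vectors
(zero-variance members give NA pairs); a seeded helper samples k = 5
regions per run for the LD report.

The class–significance comparison runs a one-way ANOVA of −log10(top q)
across classes with Fisher's LSD pairwise tests on the pooled MSE
(α = 0.05). −log10 q rather than raw q: q is bounded in [0,1] and heavily
skewed, which would make the mean comparison meaningless; this transform
choice is a documented judgment call since only "ANOVA on q-values" is
specified by the workflow being reproduced. Classes with < 2 regions are
excluded with a warning; identical-within-group degenerate inputs return
F = ∞ (or 0 when groups also coincide).

## Hotspots

Cross-gene locus identity is single-linkage clustering of regions by
interval overlap on the same chromosome — the weakest assumption that
produces the vertical bands an eQTL map shows. An alternative
shared-top-SNP mode is available; the mode used is recorded in output
metadata. Loci with ≥ 10 distinct genes are hotspots. Candidate regulators
are the hotspot's cis-classified member genes, optionally intersected with
a user-supplied TF gene-id file (no live database queries; the pipeline is
self-contained). The eQTL map table places each region at (top-SNP
cumulative genome coordinate, gene-TSS cumulative coordinate) given a
chromosome-length table.

## Synthetic data generator

The generator emulates a 100-animal, array-genotyped, bulk-RNA-seq tissue
study at desk scale. Defaults (all overridable):

| parameter | default | why |
|---|---|---|
| n_samples | 100 | the emulated study size |
| batch_sizes | (53, 47) | two slaughter-day batches |
| n_snps / n_chromosomes / chrom_length_bp | 5000 / 5 / 20 Mb | 20 kb spacing, a scaled-down array panel |
| maf_range | (0.05, 0.5) | post-QC array MAF spectrum |
| ld_decay_bp | 150 kb | adjacent-SNP r² ≈ 0.75, array-like local LD |
| n_genes | 80 | keeps a full scan to seconds |
| n_cis_eqtl / cis_beta_sd | 20 / 1.0 | planted cis architecture, 1 trait-SD per genotype-SD |
| n_hotspots / hotspot_n_targets / hotspot_beta_sd | 1 / 15 / 0.8 | one detectable (≥ 10-target) regulator |
| σ²_u / σ²_e | 0.1 / 0.1 | log-scale variances; h² = 0.5, per-gene CV ≈ 45%, typical bulk inter-individual variability |
| batch_effect_sd | 0.2 | modest log-scale batch shift |
| nb_dispersion | 0.1 | typical bulk RNA-seq overdispersion |
| library sizes | lognormal, median 20 M, sd 0.1 (log) | sequencing-depth spread |

**Genotypes.** Two haplotypes per individual per chromosome, built by
Markov copying: at each SNP the previous allele is copied with probability
exp(−d / ld_decay_bp), else drawn fresh at that SNP's frequency. One
parameter, monotone distance-decaying r², exact independence at decay 0,
exact marginals for a constant frequency. Frequencies are smoothed
geometrically along the chain, so empirical MAFs concentrate inside (not
uniformly over) `maf_range`. Missing genotypes default to 0% and are
configurable to exercise QC.

**Expression.** Per gene, a log-scale latent trait: baseline + batch shift
+ planted effects (fixed magnitude, random sign, applied to standardized
causal dosage) + polygenic draw from N(0, G σ²_u) + N(0, I σ²_e). Counts
are gamma-Poisson around exp(latent) × library size. Planted cis SNPs lie
within 1 Mb of their gene's TSS; hotspot targets are chosen > 1 Mb away or
on other chromosomes from the regulator. The full truth (assignments,
latent matrix, batch) is returned for recovery tests.

**What it does not emulate** — hence what passing tests do *not* show
about real data: family/litter structure and admixture (samples are
unrelated, so the GRM is weakly informative and REML h² estimates are more
diffuse than in a pedigreed study); gene–gene co-expression beyond the
shared polygenic term; realistic gene length/GC biases (irrelevant to TMM
at this level); sequence reads (counts are drawn directly); sex
chromosomes' dosage compensation; multi-breed structure.

## Determinism and problem sizes

Every stochastic step takes a seed; fixed seed + config reproduces every
output byte for byte. The test suite and the acceptance script use
scaled-down problem sizes chosen so a full run stays in seconds-to-minutes
on one CPU: 5,000-SNP × 80-gene end-to-end replicates, a 2,000-SNP ×
100-gene null calibration (200,000 tests), and a 10,000-SNP GRM for
variance-component recovery. These sizes are the package's own test
design; all thresholds are the pipeline defaults above.

## Known limitations

- Natural-scale CPM with a normal Wald reference is asymptotic; at n ≪ 100
  or for extremely skewed genes a log or rank-normal transform (available
  via `log1p_cpm`) is safer.
- No conditional/stepwise secondary signals, fine-mapping or
  colocalization; regions are marginal-scan artifacts.
- No genotype imputation or liftover; inputs are assumed on one assembly.
- The locus-identity rule (interval overlap) is one of several defensible
  conventions; hotspot counts depend on it, which is why it is recorded in
  the run metadata.
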