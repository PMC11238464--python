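# egwas

An expression genome-wide association (eGWAS / eQTL-mapping) pipeline for
bulk RNA-seq studies with array genotypes, built around the workflow used
in livestock functional genomics: SNP quality control, TMM/CPM expression
normalization, a per-gene linear mixed model with a genomic relationship
matrix, Benjamini–Hochberg significance, eQTL interval construction,
cis/trans classification, and trans-eQTL hotspot detection. A synthetic-data
generator with a known, planted eQTL architecture makes every stage
testable end to end without access to animal data.

## Who this is for

Quantitative geneticists and computational biologists who have, per tissue:

- genotypes in PLINK `.bed/.bim/.fam` (biallelic SNPs, 1-based positions),
- a gene × sample raw count matrix (TSV),
- gene annotation (chromosome, TSS, strand, biotype) as TSV or GFF3,
- a sample covariate table with a batch label,

and want gene-level eQTL regions, their cis/trans annotation, and candidate
hotspot loci, with every threshold explicit and every stage reproducible.

## The model

Each gene's expression (TMM-normalized CPM) is analyzed with the
single-SNP linear mixed model

    y = μ + Batch_j + δ·SNP_i + u + e,   u ~ N(0, G σ²_u),   e ~ N(0, I σ²_e)

where `SNP_i` is the dosage (0/1/2) of the tested variant, δ its additive
effect, and `G` the genomic relationship matrix

    G_jk = (1/N) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i))

built from all QC-surviving SNPs. Variance components are estimated once
per gene by REML under the null (no-SNP) model in the eigenbasis of `G`;
each SNP is then tested by generalized least squares with V = σ²_u G + σ²_e I
held fixed, with a Wald p-value against the standard normal.

Downstream of the scan:

- **significance**: BH step-up q ≤ 0.05 over all gene × SNP tests of a run;
- **regions**: per gene and chromosome, significant SNPs with consecutive
  gaps < 10 Mb are merged; intervals with < 3 significant SNPs are dropped;
- **classification**: by the distance of the region's most significant SNP
  to the gene TSS — *cis* (≤ 1 Mb, same chromosome), *trans-I* (> 1 Mb,
  same chromosome), *trans-II* (different chromosome);
- **hotspots**: regions are clustered across genes by interval overlap;
  loci associated with ≥ 10 distinct genes are called hotspots, and their
  cis-classified member genes are flagged as candidate regulators
  (optionally intersected with a transcription-factor list).

Default thresholds: MAF ≥ 0.01, HWE exact p > 1e-12, missingness ≤ 10%,
Y/scaffold SNPs dropped, mean CPM ≥ 1, q ≤ 0.05, 10 Mb gap, ≥ 3 SNPs,
1 Mb cis window, ≥ 10 genes per hotspot.

## Worked example

Simulate a 100-sample, 5,000-SNP, 80-gene dataset with 20 planted cis
effects and one 15-target trans regulator, then run the full pipeline:

```bash
egwas simulate --out-dir demo/data --seed 11
cat > demo/config.yaml <<EOF
plink_prefix: demo/data/geno
counts: demo/data/counts.tsv
annotation: demo/data/annotation.tsv
covariates: demo/data/covariates.tsv
chrom_lengths: demo/data/chrom_lengths.tsv
out_dir: demo/run
EOF
egwas run-all --config demo/config.yaml
```

The manifest printed at the end reports, per stage (abridged):

```
"qc":        {"n_input": 5000, "n_output": 5000}
"normalize": {"n_input": 80, "n_kept": 80}
"scan":      {"n_tests": 400000}
"call":      {"n_significant": 298, "n_merged": 298, "n_discarded": 0,
              "n_regions": 34,
              "class_counts": {"cis": 19, "trans-II": 14, "trans-I": 1}}
"hotspots":  {"n_loci": 20, "n_single_gene": 19, "n_multi_gene": 1,
              "n_hotspot": 1}
```

Reading: all 400,000 gene × SNP tests produced 298 BH-significant
associations, all of which merged into 34 eQTL regions (none discarded by
the ≥ 3-SNP rule); 19 regions are cis. The 34 regions collapse into 20
loci, one of which — the planted regulator — is a hotspot. Its row in
`demo/run/hotspots.tsv`:

```
chrom  start_bp  end_bp   n_genes  genes
5      740047    913453   15       gene000,gene002,gene010,...
```

`demo/run/eqtl_regions.tsv` holds one row per region, e.g. a planted cis
gene recovered with its top SNP 11.9 kb from the TSS:

```
gene001  1  14917599  14997046  11  snp753  14983742  8.8e-13  2.7e-08  cis  11872
```

Stages can also be run individually (`egwas qc / normalize / grm / scan /
call / hotspots`), or from Python via `egwas.pipeline.analyze_dataset`.

## Layout

```
src/egwas/
  simulate.py    synthetic genotypes + NB expression with planted eQTLs
  plink.py       PLINK 1 binary reader/writer (SNP-major)
  genotype.py    GenotypeDataset, HWE exact test, SNP QC filters
  normalize.py   TMM factors, CPM, expression + tissue-specificity filters
  grm.py         genomic relationship matrix + PSD stabilization
  lmm.py         per-gene REML + GLS single-SNP scan
  eqtl.py        BH, interval merging, cis/trans classes, LD, q-value ANOVA
  hotspots.py    cross-gene loci, hotspot calling, eQTL map table
  pipeline.py    end-to-end orchestration with manifest + checkpoints
  cli.py         command-line interface
```

See `docs/methods.md` for the statistical details, simulator design and
known limitations.
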