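"""Synthetic genotype + expression data with a known eQTL architecture.

The generator emulates, at desk scale, the structure of a bulk eQTL study:
array-density SNP genotypes with distance-decaying LD, negative-binomial
RNA-seq counts with planted cis effects and trans hotspot regulators, a
GRM-structured polygenic component u ~ N(0, G sigma_u^2) on the
log-expression scale, and a two-level slaughter-day batch effect (batches
of 53 and 47 animals by default).

LD model
    Each individual carries two haplotypes per chromosome.  Along a
    chromosome the haplotype is built by Markov copying: at each SNP the
    previous SNP's allele is copied with probability exp(-d / ld_decay_bp)
    (d the inter-SNP distance), otherwise a fresh allele is drawn at that
    SNP's frequency.  This yields monotone distance-decaying r^2 with a
    single parameter and exact independence when ld_decay_bp = 0.

Expression model
    Per gene, a log-scale latent trait
        eta = mu_g + batch shift + sum(beta * standardized dosage) + u + e
    with u ~ N(0, G sigma_u2), e ~ N(0, I sigma_e2); planted effects are
    fixed magnitude (cis_beta_sd / hotspot_beta_sd) with random sign on the
    standardized causal dosage.  Counts are gamma-Poisson (negative
    binomial) around exp(eta) scaled by a lognormal per-sample library
    size, so CPM recovers exp(eta) up to compositional rescaling.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plink
from .genotype import GenotypeDataset
from .grm import build_grm, stabilize
from .normalize import ExpressionDataset


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Effect sizes are on the log-expression scale per standard deviation of
    dosage; variances likewise on the log scale.
    """

    n_samples: int = 100
    n_snps: int = 5000
    n_chromosomes: int = 5
    chrom_length_bp: int = 20_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_bp: float = 150_000.0
    n_genes: int = 80
    n_cis_eqtl: int = 20
    cis_beta_sd: float = 1.0
    n_hotspots: int = 1
    hotspot_n_targets: int = 15
    hotspot_beta_sd: float = 0.8
    sigma_u2: float = 0.1
    sigma_e2: float = 0.1
    batch_effect_sd: float = 0.2
    batch_sizes: tuple[int, int] = (53, 47)
    nb_dispersion: float = 0.1
    missing_rate: float = 0.0
    mean_library_size: float = 20e6
    library_size_log_sd: float = 0.1
    baseline_log_cpm_mean: float = np.log(50.0)
    baseline_log_cpm_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5]: {self.maf_range}")
        if sum(self.batch_sizes) != self.n_samples:
            raise ValueError(
                f"batch_sizes {self.batch_sizes} must sum to n_samples {self.n_samples}"
            )
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        if min(self.sigma_u2, self.sigma_e2, self.nb_dispersion) < 0:
            raise ValueError("variances and dispersion must be >= 0")
        if self.hotspot_n_targets > self.n_genes:
            raise ValueError("hotspot_n_targets exceeds n_genes")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of the planted architecture, for recovery tests."""

    cis_assignments: pd.DataFrame            # gene_id, snp_id, chrom, pos, beta
    hotspot_assignments: list[dict]          # {snp_id, chrom, pos, targets, betas}
    sigma_u2: float
    sigma_e2: float
    latent: np.ndarray = field(repr=False, default=None)  # gene x sample log traits
    batch: pd.Series = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": "cis",
                "gene_id": r.gene_id,
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "beta": r.beta,
            }
            for r in self.cis_assignments.itertuples()
        ]
        for h in self.hotspot_assignments:
            for gene, beta in zip(h["targets"], h["betas"]):
                rows.append(
                    {
                        "kind": "hotspot",
                        "gene_id": gene,
                        "snp_id": h["snp_id"],
                        "chrom": h["chrom"],
                        "pos": h["pos"],
                        "beta": beta,
                    }
                )
        return pd.DataFrame(rows, columns=["kind", "gene_id", "snp_id", "chrom", "pos", "beta"])


def _chrom_snp_counts(config: SimConfig) -> list[int]:
    base = config.n_snps // config.n_chromosomes
    rem = config.n_snps % config.n_chromosomes
    return [base + (1 if c < rem else 0) for c in range(config.n_chromosomes)]


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeDataset:
    """Simulate the genotype panel (dosages in {0,1,2}, positions sorted
    within chromosome, MAF drawn from ``maf_range``)."""
    rng = rng or np.random.default_rng(config.seed)
    n_hap = 2 * config.n_samples
    chroms, ids, positions, freqs = [], [], [], []
    dosage_blocks = []
    snp_counter = 0
    for c, m_c in enumerate(_chrom_snp_counts(config), start=1):
        pos = np.sort(
            rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m_c, replace=False)
        )
        p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m_c)
        H = np.empty((n_hap, m_c), dtype=np.int8)
        H[:, 0] = rng.random(n_hap) < p[0]
        if m_c > 1:
            d = np.diff(pos).astype(float)
            copy_p = (
                np.exp(-d / config.ld_decay_bp)
                if config.ld_decay_bp > 0
                else np.zeros(m_c - 1)
            )
            copy_draw = rng.random((n_hap, m_c - 1)) < copy_p[None, :]
            fresh = rng.random((n_hap, m_c - 1)) < p[None, 1:]
            for j in range(1, m_c):
                H[:, j] = np.where(copy_draw[:, j - 1], H[:, j - 1], fresh[:, j - 1])
        dosage_blocks.append((H[::2] + H[1::2]).astype(float))
        chroms.extend([str(c)] * m_c)
        positions.extend(pos.tolist())
        freqs.extend(p.tolist())
        ids.extend([f"snp{snp_counter + j}" for j in range(m_c)])
        snp_counter += m_c
    dosages = np.concatenate(dosage_blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    snp_map = pd.DataFrame(
        {
            "chrom": chroms,
            "snp_id": ids,
            "pos": np.asarray(positions, dtype=int),
            "a1": "A",
            "a2": "G",
        }
    )
    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    return GenotypeDataset(sample_ids=sample_ids, snp_map=snp_map, dosages=dosages)


def _place_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom = rng.integers(1, config.n_chromosomes + 1, size=config.n_genes)
    tss = rng.integers(1, config.chrom_length_bp + 1, size=config.n_genes)
    strand = rng.choice(["+", "-"], size=config.n_genes)
    return pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "tss_pos": tss,
            "strand": strand,
            "biotype": "protein_coding",
        },
        index=[f"gene{g:03d}" for g in range(config.n_genes)],
    ).rename_axis("gene_id")


def _standardized_dosage(geno: GenotypeDataset, snp_idx: int) -> np.ndarray:
    x = geno.dosages[:, snp_idx].astype(float)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_expression(
    geno: GenotypeDataset, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionDataset, SimTruth]:
    """Simulate counts for ``config.n_genes`` genes on top of the genotypes.

    Planted cis SNPs are chosen within 1 Mb of their gene's TSS; hotspot
    regulator SNPs drive ``hotspot_n_targets`` genes chosen to lie > 1 Mb
    away or on other chromosomes.  Effects have magnitude cis_beta_sd /
    hotspot_beta_sd with random sign, applied to standardized dosage.
    """
    rng = rng or np.random.default_rng(config.seed + 1 if config.seed is not None else None)
    n, n_genes = config.n_samples, config.n_genes
    annot = _place_genes(config, rng)
    gene_ids = annot.index.tolist()

    G = stabilize(build_grm(geno))
    try:
        L = np.linalg.cholesky(config.sigma_u2 * G.values) if config.sigma_u2 > 0 else None
    except np.linalg.LinAlgError as err:
        raise ValueError(f"GRM is not positive definite after stabilization: {err}") from None

    batch_labels = np.repeat(
        [f"B{i + 1}" for i in range(len(config.batch_sizes))], config.batch_sizes
    )
    batch = pd.Series(batch_labels, index=geno.sample_ids, name="batch")
    batch_shifts = rng.normal(0.0, config.batch_effect_sd, size=len(config.batch_sizes))
    batch_term = batch_shifts[np.searchsorted(np.unique(batch_labels), batch_labels)]

    snp_pos = geno.snp_map["pos"].to_numpy()
    snp_chrom = geno.snp_map["chrom"].to_numpy()

    # plant cis effects: one causal SNP within 1 Mb of the gene's TSS
    cis_genes = rng.choice(n_genes, size=config.n_cis_eqtl, replace=False) if config.n_cis_eqtl else np.array([], dtype=int)
    cis_rows = []
    effects: dict[int, list[tuple[int, float]]] = {}
    for g in cis_genes:
        chrom = annot.iloc[g]["chrom"]
        tss = int(annot.iloc[g]["tss_pos"])
        near = np.flatnonzero((snp_chrom == chrom) & (np.abs(snp_pos - tss) <= 1_000_000))
        if near.size == 0:
            on_chrom = np.flatnonzero(snp_chrom == chrom)
            near = on_chrom[[np.argmin(np.abs(snp_pos[on_chrom] - tss))]]
            annot.iloc[g, annot.columns.get_loc("tss_pos")] = int(snp_pos[near[0]])
            tss = int(snp_pos[near[0]])
        snp = int(rng.choice(near))
        beta = float(config.cis_beta_sd * rng.choice([-1.0, 1.0]))
        effects.setdefault(g, []).append((snp, beta))
        cis_rows.append(
            {
                "gene_id": gene_ids[g],
                "snp_id": geno.snp_map.iloc[snp]["snp_id"],
                "chrom": snp_chrom[snp],
                "pos": int(snp_pos[snp]),
                "beta": beta,
            }
        )

    # plant trans hotspot regulators
    hotspot_rows = []
    taken = set(cis_genes.tolist())
    for _ in range(config.n_hotspots):
        snp = int(rng.integers(geno.n_snps))
        far = [
            g
            for g in range(n_genes)
            if g not in taken
            and (
                annot.iloc[g]["chrom"] != snp_chrom[snp]
                or abs(int(annot.iloc[g]["tss_pos"]) - int(snp_pos[snp])) > 1_000_000
            )
        ]
        targets = rng.choice(far, size=min(config.hotspot_n_targets, len(far)), replace=False)
        taken.update(targets.tolist())
        betas = config.hotspot_beta_sd * rng.choice([-1.0, 1.0], size=len(targets))
        for g, b in zip(targets, betas):
            effects.setdefault(int(g), []).append((snp, float(b)))
        hotspot_rows.append(
            {
                "snp_id": geno.snp_map.iloc[snp]["snp_id"],
                "chrom": snp_chrom[snp],
                "pos": int(snp_pos[snp]),
                "targets": [gene_ids[g] for g in targets],
                "betas": betas.tolist(),
            }
        )

    # latent log-scale traits
    mu = rng.normal(config.baseline_log_cpm_mean, config.baseline_log_cpm_sd, size=n_genes)
    latent = np.empty((n_genes, n))
    std_dosage_cache: dict[int, np.ndarray] = {}
    for g in range(n_genes):
        eta = mu[g] + batch_term.copy()
        for snp, beta in effects.get(g, []):
            if snp not in std_dosage_cache:
                std_dosage_cache[snp] = _standardized_dosage(geno, snp)
            eta = eta + beta * std_dosage_cache[snp]
        if L is not None:
            eta = eta + L @ rng.standard_normal(n)
        if config.sigma_e2 > 0:
            eta = eta + rng.normal(0.0, np.sqrt(config.sigma_e2), size=n)
        latent[g] = eta

    # counts: gamma-Poisson around exp(latent) scaled by library size
    lib = np.exp(
        rng.normal(np.log(config.mean_library_size), config.library_size_log_sd, size=n)
    )
    mean_counts = np.exp(latent) * lib[None, :] / 1e6
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        gamma = rng.gamma(shape, scale=1.0 / shape, size=mean_counts.shape)
        mean_counts = mean_counts * gamma
    counts = rng.poisson(mean_counts)

    expr = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=list(geno.sample_ids),
        counts=counts.astype(np.int64),
        gene_annot=annot,
    )
    truth = SimTruth(
        cis_assignments=pd.DataFrame(
            cis_rows, columns=["gene_id", "snp_id", "chrom", "pos", "beta"]
        ),
        hotspot_assignments=hotspot_rows,
        sigma_u2=config.sigma_u2,
        sigma_e2=config.sigma_e2,
        latent=latent,
        batch=batch,
    )
    return expr, truth


def simulate_polygenic_traits(
    G, h2: float, n_traits: int, seed: int = 0, total_var: float = 1.0
) -> np.ndarray:
    """Gaussian traits y = u + e with u ~ N(0, h2 G) and e ~ N(0, (1-h2) I),
    for variance-component recovery checks.  Returns (n_traits, n)."""
    rng = np.random.default_rng(seed)
    n = G.n
    su2 = h2 * total_var
    se2 = (1.0 - h2) * total_var
    L = np.linalg.cholesky(su2 * G.values + 1e-10 * np.eye(n)) if su2 > 0 else None
    Y = np.empty((n_traits, n))
    for t in range(n_traits):
        y = rng.normal(0.0, np.sqrt(se2), size=n) if se2 > 0 else np.zeros(n)
        if L is not None:
            y = y + L @ rng.standard_normal(n)
        Y[t] = y
    return Y


def simulate_dataset(config: SimConfig):
    """Genotypes, expression and truth in one call with a single seed."""
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, rng=rng)
    expr, truth = simulate_expression(geno, config, rng=rng)
    return geno, expr, truth


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(
    geno: GenotypeDataset,
    expr: ExpressionDataset,
    truth: SimTruth,
    out_dir,
    config: SimConfig | None = None,
) -> dict:
    """Write the dataset in the pipeline's input formats and return a
    manifest of files with checksums.

    Emits PLINK .bed/.bim/.fam, counts TSV, gene-annotation TSV, covariate
    TSV, chromosome-length TSV and truth TSV; every file round-trips
    through the pipeline's readers.
    """
    os.makedirs(out_dir, exist_ok=True)
    prefix = os.path.join(out_dir, "geno")
    plink.write_plink(prefix, geno.sample_ids, geno.snp_map, geno.dosages)
    files = [prefix + ext for ext in (".bed", ".bim", ".fam")]

    counts_path = os.path.join(out_dir, "counts.tsv")
    expr.counts_frame().rename_axis("gene_id").to_csv(counts_path, sep="\t")
    files.append(counts_path)

    annot_path = os.path.join(out_dir, "annotation.tsv")
    expr.gene_annot.reset_index().to_csv(annot_path, sep="\t", index=False)
    files.append(annot_path)

    covar_path = os.path.join(out_dir, "covariates.tsv")
    truth.batch.rename_axis("sample_id").reset_index().to_csv(covar_path, sep="\t", index=False)
    files.append(covar_path)

    if config is not None:
        lengths_path = os.path.join(out_dir, "chrom_lengths.tsv")
        pd.DataFrame(
            {
                "chrom": [str(c) for c in range(1, config.n_chromosomes + 1)],
                "length_bp": config.chrom_length_bp,
            }
        ).to_csv(lengths_path, sep="\t", index=False)
        files.append(lengths_path)

    truth_path = os.path.join(out_dir, "truth.tsv")
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    files.append(truth_path)

    manifest = {
        "files": [
            {"path": os.path.basename(f), "sha256": _sha256(f), "bytes": os.path.getsize(f)}
            for f in files
        ],
        "n_samples": geno.n_samples,
        "n_snps": geno.n_snps,
        "n_genes": len(expr.gene_ids),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
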