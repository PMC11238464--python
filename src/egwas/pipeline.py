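"""End-to-end orchestration: qc -> normalize -> grm -> scan -> call -> hotspots.

Driven by a declarative YAML config; every stage writes its outputs under
the run directory, and a manifest records the config hash, package version,
per-stage row counts and seeds so that identical config + inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .eqtl import (
    DEFAULT_ALPHA,
    DEFAULT_CIS_WINDOW_BP,
    DEFAULT_GAP_BP,
    DEFAULT_MIN_SNPS,
    bh_adjust,
    call_eqtl_regions,
    class_qvalue_anova,
    ld_within_region,
    regions_frame,
    sample_regions_for_ld,
)
from .genotype import QCThresholds, apply_qc, qc_report, read_plink
from .grm import build_grm, stabilize, write_grm_tsv
from .hotspots import (
    DEFAULT_HOTSPOT_MIN_GENES,
    aggregate_loci,
    call_hotspots,
    cis_regulator_candidates,
    eqtl_map_table,
    hotspot_frame,
)
from .lmm import egwas_all_genes
from .normalize import (
    DEFAULT_MIN_MEAN_CPM,
    ExpressionDataset,
    filter_expressed,
    normalize,
    read_counts_tsv,
    read_gene_annotation,
)


@dataclass
class PipelineConfig:
    plink_prefix: str
    counts: str
    annotation: str
    covariates: str
    chrom_lengths: str | None = None
    tf_list: str | None = None
    out_dir: str = "egwas_run"
    maf_min: float = 0.01
    hwe_p_min: float = 1e-12
    max_missing_rate: float = 0.10
    min_mean_cpm: float = DEFAULT_MIN_MEAN_CPM
    bh_alpha: float = DEFAULT_ALPHA
    gap_bp: int = DEFAULT_GAP_BP
    min_snps: int = DEFAULT_MIN_SNPS
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP
    hotspot_min_genes: int = DEFAULT_HOTSPOT_MIN_GENES
    locus_mode: str = "overlap"
    log1p_cpm: bool = False
    n_ld_regions: int = 5
    seed: int = 0
    checkpoint: bool = True

    def __post_init__(self):
        for name in ("min_mean_cpm", "bh_alpha", "gap_bp", "min_snps",
                     "cis_window_bp", "hotspot_min_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        for ext in (".bed", ".bim", ".fam"):
            if not os.path.exists(self.plink_prefix + ext):
                raise FileNotFoundError(f"missing input: {self.plink_prefix + ext}")
        for p in (self.counts, self.annotation, self.covariates,
                  self.chrom_lengths, self.tf_list):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"missing input: {p}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def analyze_dataset(
    geno,
    expr,
    covariates: pd.DataFrame,
    bh_alpha: float = DEFAULT_ALPHA,
    gap_bp: int = DEFAULT_GAP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP,
    hotspot_min_genes: int = DEFAULT_HOTSPOT_MIN_GENES,
    min_mean_cpm: float = DEFAULT_MIN_MEAN_CPM,
    qc_thresholds: QCThresholds | None = None,
) -> dict:
    """In-memory end-to-end analysis of a loaded dataset.

    Runs QC, normalization, GRM, the mixed-model scan, BH, region calling
    and hotspot detection, returning all intermediate products in a dict
    (keys: geno, expr, grm, associations, regions, accounting, loci,
    hotspots, tally).
    """
    geno = apply_qc(geno.sort_by_position(), qc_thresholds or QCThresholds())
    expr = filter_expressed(normalize(expr), min_mean_cpm=min_mean_cpm)
    G = stabilize(build_grm(geno))
    assoc = bh_adjust(egwas_all_genes(expr, geno, G, covariates), alpha=bh_alpha)
    regions, accounting = call_eqtl_regions(
        assoc, expr.gene_annot, gap_bp=gap_bp, min_snps=min_snps,
        cis_window_bp=cis_window_bp,
    )
    loci = aggregate_loci(regions)
    hs, tally = call_hotspots(loci, min_genes=hotspot_min_genes)
    for h in hs:
        cis_regulator_candidates(h, None)
    return {
        "geno": geno,
        "expr": expr,
        "grm": G,
        "associations": assoc,
        "regions": regions,
        "accounting": accounting,
        "loci": loci,
        "hotspots": hs,
        "tally": tally,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    config.validate_paths()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "stages": {},
    }

    # resumable scans key on the config hash: refuse stale checkpoints
    hash_file = os.path.join(out, "config_hash.txt")
    if os.path.exists(hash_file):
        prev = open(hash_file).read().strip()
        if prev != config.content_hash():
            raise RuntimeError(
                "output directory holds results from a different config "
                f"(hash {prev} != {config.content_hash()}); refusing to resume"
            )
    else:
        with open(hash_file, "w") as fh:
            fh.write(config.content_hash())

    # --- qc
    geno = read_plink(config.plink_prefix)
    thr = QCThresholds(
        maf_min=config.maf_min,
        hwe_p_min=config.hwe_p_min,
        max_missing_rate=config.max_missing_rate,
    )
    geno = apply_qc(geno.sort_by_position(), thr)
    qc_report(geno).to_csv(os.path.join(out, "qc_report.tsv"), sep="\t", index=False)
    manifest["stages"]["qc"] = dict(geno.qc_log)

    # --- normalize
    gene_ids, sample_ids, counts = read_counts_tsv(config.counts)
    annot = read_gene_annotation(config.annotation)
    expr = ExpressionDataset(
        gene_ids=gene_ids, sample_ids=sample_ids, counts=counts, gene_annot=annot
    )
    expr = filter_expressed(normalize(expr), min_mean_cpm=config.min_mean_cpm)
    if not expr.gene_ids:
        raise RuntimeError("no gene passes the mean-CPM expression filter")
    expr.cpm_frame().rename_axis("gene_id").to_csv(
        os.path.join(out, "cpm.tsv"), sep="\t"
    )
    manifest["stages"]["normalize"] = expr.log["expressed_filter"]

    # --- grm
    G = stabilize(build_grm(geno))
    write_grm_tsv(G, os.path.join(out, "grm.tsv"))
    manifest["stages"]["grm"] = {
        "n_snps_used": G.n_snps_used, **G.stabilization,
    }

    # --- scan
    covar = pd.read_csv(config.covariates, sep="\t", dtype={"sample_id": str})
    ckpt = os.path.join(out, "checkpoints") if config.checkpoint else None
    assoc = egwas_all_genes(
        expr, geno, G, covar, log1p_cpm=config.log1p_cpm, checkpoint_dir=ckpt
    )
    manifest["stages"]["scan"] = {
        "n_tests": int(assoc["p_value"].notna().sum()),
        "n_records": len(assoc),
    }

    # --- call
    assoc = bh_adjust(assoc, alpha=config.bh_alpha)
    assoc.to_csv(os.path.join(out, "associations.tsv"), sep="\t", index=False)
    sig = assoc[assoc["significant"]]
    sig.to_csv(os.path.join(out, "significant_associations.tsv"), sep="\t", index=False)
    regions, accounting = call_eqtl_regions(
        assoc,
        expr.gene_annot,
        gap_bp=config.gap_bp,
        min_snps=config.min_snps,
        cis_window_bp=config.cis_window_bp,
    )
    regions_frame(regions).to_csv(os.path.join(out, "eqtl_regions.tsv"), sep="\t", index=False)
    manifest["stages"]["call"] = accounting

    if regions:
        ld_rows = []
        for reg in sample_regions_for_ld(regions, k=config.n_ld_regions, seed=config.seed):
            _, summary = ld_within_region(reg, geno)
            ld_rows.append({"gene_id": reg.gene_id, "chrom": reg.chrom,
                            "start_bp": reg.start_bp, "end_bp": reg.end_bp, **summary})
        pd.DataFrame(ld_rows).to_csv(os.path.join(out, "ld_report.tsv"), sep="\t", index=False)
        try:
            anova = class_qvalue_anova(regions)
            anova["lsd_pairs"].to_csv(os.path.join(out, "class_anova_lsd.tsv"), sep="\t", index=False)
            manifest["stages"]["anova"] = {
                k: v for k, v in anova.items() if k != "lsd_pairs"
            }
        except ValueError as err:
            manifest["stages"]["anova"] = {"skipped": str(err)}

    # --- hotspots
    loci = aggregate_loci(regions, mode=config.locus_mode)
    hs, tally = call_hotspots(loci, min_genes=config.hotspot_min_genes)
    tf = None
    if config.tf_list:
        tf = {line.strip() for line in open(config.tf_list) if line.strip()}
    for h in hs:
        cis_regulator_candidates(h, tf)
    hotspot_frame(hs).to_csv(os.path.join(out, "hotspots.tsv"), sep="\t", index=False)
    manifest["stages"]["hotspots"] = tally
    if config.chrom_lengths:
        lengths = pd.read_csv(config.chrom_lengths, sep="\t", dtype={"chrom": str}).set_index("chrom")["length_bp"]
        mt = eqtl_map_table(regions, expr.gene_annot, lengths)
        mt.to_csv(os.path.join(out, "eqtl_map.tsv"), sep="\t", index=False)

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
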