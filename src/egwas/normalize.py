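"""Expression normalization: TMM factors, CPM, expression filters.

TMM (trimmed mean of M-values) corrects between-sample composition bias in
bulk RNA-seq counts.  For each sample against a reference sample, genes with
zero counts in either are excluded, M is the log2 ratio of library-scaled
proportions and A the average log2 proportion; the top and bottom 30% of M
and 5% of A are trimmed and the factor is 2 to the precision-weighted mean
of the remaining M values.  Factors are rescaled to geometric mean 1.  The
reference sample is the one whose 75th percentile of scaled counts is
closest to the mean of those percentiles across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

M_TRIM = 0.30
A_TRIM = 0.05
DEFAULT_MIN_MEAN_CPM = 1.0
TISSUE_SPECIFIC_FOLD = 4.0


@dataclass
class ExpressionDataset:
    """Gene x sample counts with normalization products and annotation.

    ``gene_annot`` (optional) carries per-gene chrom, tss_pos (1-based),
    strand and biotype, indexed like ``gene_ids``.
    """

    gene_ids: list
    sample_ids: list
    counts: np.ndarray
    tmm_factors: np.ndarray | None = None
    cpm: np.ndarray | None = None
    gene_annot: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        g, s = self.counts.shape
        if g != len(self.gene_ids) or s != len(self.sample_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def cpm_frame(self) -> pd.DataFrame:
        if self.cpm is None:
            raise ValueError("CPM not computed; call normalize() first")
        return pd.DataFrame(self.cpm, index=self.gene_ids, columns=self.sample_ids)


def _choose_reference(counts: np.ndarray) -> int:
    lib = counts.sum(axis=0).astype(float)
    q75 = np.array([np.quantile(counts[:, s] / lib[s], 0.75) for s in range(counts.shape[1])])
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """TMM factor of one sample against the reference (log2 scale returns 2^f)."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        warnings.warn("sample shares no expressed gene with the reference; factor set to 1")
        return 1.0
    o = obs[ok] / n_obs
    r = ref[ok] / n_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # delta-method precision weights
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m = np.floor(n * M_TRIM) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * A_TRIM) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: np.ndarray) -> np.ndarray:
    """Per-sample TMM normalization factors, geometric mean 1."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("TMM needs a gene x sample matrix with >= 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have positive total counts")
    ref = _choose_reference(counts)
    f = np.array(
        [
            _tmm_pair(counts[:, s], counts[:, ref], lib[s], lib[ref])
            for s in range(counts.shape[1])
        ]
    )
    return f / np.exp(np.mean(np.log(f)))


def cpm(counts: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Counts per million on TMM-effective library sizes:
    cpm[g, s] = counts[g, s] / (library_size[s] * factor[s]) * 1e6."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0) * np.asarray(factors, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("zero effective library size")
    return counts / lib[None, :] * 1e6


def normalize(expr: ExpressionDataset) -> ExpressionDataset:
    """Compute TMM factors and CPM, returning a new dataset."""
    f = tmm_factors(expr.counts)
    return replace(expr, tmm_factors=f, cpm=cpm(expr.counts, f))


def filter_expressed(
    expr: ExpressionDataset, min_mean_cpm: float = DEFAULT_MIN_MEAN_CPM
) -> ExpressionDataset:
    """Keep genes whose mean CPM across all samples is >= the threshold."""
    if expr.cpm is None:
        raise ValueError("CPM not computed; call normalize() first")
    keep = expr.cpm.mean(axis=1) >= min_mean_cpm
    log = dict(expr.log)
    log["expressed_filter"] = {
        "min_mean_cpm": min_mean_cpm,
        "n_input": int(len(keep)),
        "n_kept": int(keep.sum()),
    }
    annot = expr.gene_annot
    gene_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    if annot is not None:
        annot = annot.loc[annot.index.intersection(gene_ids)].reindex(gene_ids)
    return replace(
        expr,
        gene_ids=gene_ids,
        counts=expr.counts[keep],
        cpm=expr.cpm[keep],
        gene_annot=annot,
        log=log,
    )


def tissue_specific_genes(
    expr_by_tissue: dict[str, ExpressionDataset], fold: float = TISSUE_SPECIFIC_FOLD
) -> dict[str, list]:
    """Genes with ``fold``-times higher mean CPM in one tissue than in every
    other tissue (focal mean required > 0)."""
    if len(expr_by_tissue) < 2:
        raise ValueError("tissue specificity needs at least two tissues")
    tissues = list(expr_by_tissue)
    universe = expr_by_tissue[tissues[0]].gene_ids
    for t in tissues[1:]:
        if list(expr_by_tissue[t].gene_ids) != list(universe):
            raise ValueError("all tissues must share the same gene universe")
    means = {}
    for t in tissues:
        e = expr_by_tissue[t]
        if e.cpm is None:
            raise ValueError(f"tissue {t}: CPM not computed")
        means[t] = e.cpm.mean(axis=1)
    out: dict[str, list] = {}
    for t in tissues:
        others = [means[o] for o in tissues if o != t]
        spec = means[t] > 0
        for o in others:
            spec &= means[t] >= fold * o
        out[t] = [g for g, s in zip(universe, spec) if s]
    return out


def read_counts_tsv(path) -> tuple[list, list, np.ndarray]:
    """Read a gene x sample counts TSV (first column gene ids, header row
    sample ids); returns (gene_ids, sample_ids, counts)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in counts matrix")
    return df.index.tolist(), df.columns.tolist(), counts.astype(np.int64)


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, chrom, tss_pos, strand,
    biotype (tss_pos 1-based), or a GFF3 file (Ensembl dialect) from which
    the strand-aware TSS is derived (start for +, end for -)."""
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or (head.startswith("#") and "gff" in head.lower()):
        return _annotation_from_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "tss_pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    if "biotype" not in df.columns:
        df["biotype"] = "unknown"
    return df.set_index("gene_id")


def _annotation_from_gff3(path) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    gff = pd.read_csv(path, sep="\t", comment="#", names=cols, dtype={"seqid": str})
    genes = gff[gff["type"] == "gene"].copy()
    attr = genes["attributes"].str.extract(r"ID=(?:gene:)?([^;]+)")[0]
    biotype = genes["attributes"].str.extract(r"biotype=([^;]+)")[0].fillna("unknown")
    tss = np.where(genes["strand"] == "-", genes["end"], genes["start"])
    return pd.DataFrame(
        {
            "gene_id": attr.to_numpy(),
            "chrom": genes["seqid"].to_numpy(),
            "tss_pos": tss.astype(int),
            "strand": genes["strand"].to_numpy(),
            "biotype": biotype.to_numpy(),
        }
    ).set_index("gene_id")
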