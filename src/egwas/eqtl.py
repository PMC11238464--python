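"""From association statistics to eQTL regions and cis/trans annotation.

Significance is Benjamini-Hochberg q <= 0.05 over one family per tissue run
(all gene x SNP tests).  Per gene and chromosome, significant SNPs whose
consecutive distances are shorter than 10 Mb form one eQTL interval; a gap
of exactly 10 Mb or more splits.  Intervals with fewer than 3 significant
SNPs are discarded (counted, so significant associations always partition
into merged plus discarded).  Each region is classified by the distance of
its most significant SNP to the gene's TSS: cis (<= 1 Mb, same chromosome),
trans-I (> 1 Mb, same chromosome) or trans-II (different chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_GAP_BP = 10_000_000
DEFAULT_MIN_SNPS = 3
DEFAULT_CIS_WINDOW_BP = 1_000_000

CLASS_CIS = "cis"
CLASS_TRANS_I = "trans-I"
CLASS_TRANS_II = "trans-II"
CLASS_UNKNOWN = "unclassified"


@dataclass
class EQTLRegion:
    """A merged interval of significant SNPs for one gene.

    Coordinates are 1-based and closed; the span is defined by the member
    significant SNP positions.  ``distance_bp`` is |top SNP - TSS| when the
    region and gene share a chromosome, else None.
    """

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    top_snp_id: str
    top_snp_pos: int
    top_p: float
    top_q: float
    member_snps: pd.DataFrame = field(repr=False)
    eqtl_class: str = CLASS_UNKNOWN
    distance_bp: int | None = None

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "start_bp": self.start_bp,
            "end_bp": self.end_bp,
            "n_snps": self.n_snps,
            "top_snp_id": self.top_snp_id,
            "top_snp_pos": self.top_snp_pos,
            "top_p": self.top_p,
            "top_q": self.top_q,
            "eqtl_class": self.eqtl_class,
            "distance_bp": self.distance_bp,
        }


def bh_adjust(assoc: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Add BH step-up q-values over all tests in the table.

    Rows with NA p-values (untestable SNPs) are excluded from the ranking
    and carry NA q; ``significant`` is q <= alpha.
    """
    out = assoc.copy()
    p = out["p_value"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    q = np.full(len(p), np.nan)
    if ok.any():
        _, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
    out["q_value"] = q
    out["significant"] = ok & (q <= alpha)
    return out


def top_snp(members: pd.DataFrame) -> pd.Series:
    """Most significant member: smallest q, ties by smallest p, then
    smallest position."""
    if len(members) < 1:
        raise ValueError("empty member list")
    ordered = members.sort_values(["q_value", "p_value", "pos"], kind="stable")
    return ordered.iloc[0]


def merge_intervals(
    sig_snps: pd.DataFrame,
    gap_bp: int = DEFAULT_GAP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> tuple[list[EQTLRegion], int]:
    """Merge one gene's significant SNPs into eQTL regions.

    Returns (regions, n_discarded_associations): SNPs falling in runs
    shorter than ``min_snps`` are discarded but counted, so
    len(sig_snps) == sum(region n_snps) + n_discarded.
    """
    regions: list[EQTLRegion] = []
    n_discarded = 0
    if len(sig_snps) == 0:
        return regions, 0
    gene_ids = sig_snps["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError("merge_intervals operates on a single gene at a time")
    gene = gene_ids[0]
    df = sig_snps.sort_values(["chrom", "pos"], kind="stable")
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp) + 1
        for block in np.split(np.arange(len(pos)), breaks):
            members = sub.iloc[block]
            if len(members) < min_snps:
                n_discarded += len(members)
                continue
            top = top_snp(members)
            regions.append(
                EQTLRegion(
                    gene_id=gene,
                    chrom=str(chrom),
                    start_bp=int(members["pos"].min()),
                    end_bp=int(members["pos"].max()),
                    n_snps=len(members),
                    top_snp_id=str(top["snp_id"]),
                    top_snp_pos=int(top["pos"]),
                    top_p=float(top["p_value"]),
                    top_q=float(top["q_value"]),
                    member_snps=members.reset_index(drop=True),
                )
            )
    return regions, n_discarded


def classify_eqtl(
    region: EQTLRegion,
    gene_tss: tuple[str, int] | None,
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> str:
    """Three-way classification on the top SNP's distance to the gene TSS:
    cis (same chromosome, <= 1 Mb, inclusive), trans-I (same chromosome,
    > 1 Mb) or trans-II (different chromosome).  Genes without TSS
    annotation stay unclassified."""
    if gene_tss is None:
        region.eqtl_class = CLASS_UNKNOWN
        region.distance_bp = None
        return region.eqtl_class
    tss_chrom, tss_pos = gene_tss
    if str(tss_chrom) != str(region.chrom):
        region.eqtl_class = CLASS_TRANS_II
        region.distance_bp = None
    else:
        dist = abs(int(region.top_snp_pos) - int(tss_pos))
        region.distance_bp = dist
        region.eqtl_class = CLASS_CIS if dist <= cis_window_bp else CLASS_TRANS_I
    return region.eqtl_class


def call_eqtl_regions(
    assoc_with_q: pd.DataFrame,
    gene_annot: pd.DataFrame,
    gap_bp: int = DEFAULT_GAP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> tuple[list[EQTLRegion], dict]:
    """Merge and classify regions for every gene in a q-annotated table.

    Returns the classified regions and an accounting dict whose totals
    reconcile: n_significant == n_merged + n_discarded.
    """
    sig = assoc_with_q[assoc_with_q["significant"]]
    regions: list[EQTLRegion] = []
    n_discarded = 0
    for gene, sub in sig.groupby("gene_id", sort=True):
        regs, disc = merge_intervals(sub, gap_bp=gap_bp, min_snps=min_snps)
        n_discarded += disc
        if gene in gene_annot.index:
            tss = (str(gene_annot.loc[gene, "chrom"]), int(gene_annot.loc[gene, "tss_pos"]))
        else:
            tss = None
        for r in regs:
            classify_eqtl(r, tss, cis_window_bp=cis_window_bp)
        regions.extend(regs)
    accounting = {
        "n_tests": int(assoc_with_q["p_value"].notna().sum()),
        "n_significant": int(sig.shape[0]),
        "n_merged": int(sum(r.n_snps for r in regions)),
        "n_discarded": int(n_discarded),
        "n_regions": len(regions),
        "class_counts": regions_frame(regions)["eqtl_class"].value_counts().to_dict()
        if regions
        else {},
    }
    return regions, accounting


def regions_frame(regions: list[EQTLRegion]) -> pd.DataFrame:
    cols = [
        "gene_id", "chrom", "start_bp", "end_bp", "n_snps", "top_snp_id",
        "top_snp_pos", "top_p", "top_q", "eqtl_class", "distance_bp",
    ]
    if not regions:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_dict() for r in regions])[cols]


def regions_to_bed(regions: list[EQTLRegion]) -> pd.DataFrame:
    """Regions as BED (0-based half-open), converted from the internal
    1-based closed coordinates."""
    df = regions_frame(regions)
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start_bp"] - 1,
            "end": df["end_bp"],
            "name": df["gene_id"] + ":" + df["top_snp_id"],
            "score": 0,
            "strand": ".",
        }
    )


def ld_within_region(region: EQTLRegion, geno) -> tuple[pd.DataFrame, dict]:
    """Pairwise r^2 (squared Pearson correlation of dosages) among the
    region's member SNPs, with min/median/max summary.  Zero-variance
    members give NA pairs; missing dosages are mean-imputed."""
    ids = region.member_snps["snp_id"].tolist()
    idx = [geno.snp_map.index[geno.snp_map["snp_id"] == s][0] for s in ids]
    X = geno.dosages[:, idx].astype(float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu[None, :], X)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    r2 = np.asarray(C, dtype=float) ** 2
    bad = sd == 0
    r2[bad, :] = np.nan
    r2[:, bad] = np.nan
    np.fill_diagonal(r2, np.where(bad, np.nan, 1.0))
    table = pd.DataFrame(r2, index=ids, columns=ids)
    iu = np.triu_indices(len(ids), k=1)
    vals = r2[iu]
    vals = vals[np.isfinite(vals)]
    summary = {
        "n_snps": len(ids),
        "min_r2": float(np.min(vals)) if vals.size else np.nan,
        "median_r2": float(np.median(vals)) if vals.size else np.nan,
        "max_r2": float(np.max(vals)) if vals.size else np.nan,
    }
    return table, summary


def sample_regions_for_ld(
    regions: list[EQTLRegion], k: int = 5, seed: int = 0
) -> list[EQTLRegion]:
    """Draw k regions at random (without replacement) for the LD check."""
    rng = np.random.default_rng(seed)
    if len(regions) <= k:
        return list(regions)
    idx = rng.choice(len(regions), size=k, replace=False)
    return [regions[i] for i in sorted(idx)]


def class_qvalue_anova(regions: list[EQTLRegion], alpha: float = 0.05) -> dict:
    """One-way ANOVA of -log10(top q) across eQTL classes, with Fisher's
    LSD pairwise comparisons on the pooled MSE.

    Classes with fewer than 2 regions are excluded with a warning entry.
    Returns F, p, per-class means and the pairwise LSD table.
    """
    df = regions_frame(regions)
    df = df[df["eqtl_class"] != CLASS_UNKNOWN].copy()
    df["neglog_q"] = -np.log10(np.clip(df["top_q"].to_numpy(dtype=float), 1e-300, None))
    counts = df["eqtl_class"].value_counts()
    excluded = sorted(counts[counts < 2].index)
    groups = {c: df.loc[df["eqtl_class"] == c, "neglog_q"].to_numpy() for c in counts[counts >= 2].index}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two classes with >= 2 regions")
    names = sorted(groups)
    arrays = [groups[c] for c in names]
    N = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.mean(np.concatenate(arrays))
    ss_between = sum(len(a) * (np.mean(a) - grand) ** 2 for a in arrays)
    ss_within = sum(np.sum((a - np.mean(a)) ** 2) for a in arrays)
    df_within = N - k
    mse = ss_within / df_within if df_within > 0 else np.nan
    if ss_within == 0:
        # degenerate: identical values within every group
        F, p = (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
    else:
        F, p = stats.f_oneway(*arrays)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            diff = float(np.mean(a) - np.mean(b))
            if mse > 0:
                se = float(np.sqrt(mse * (1 / len(a) + 1 / len(b))))
                t = diff / se
                p_pair = float(2 * stats.t.sf(abs(t), df_within))
            else:
                se, t = 0.0, 0.0
                p_pair = 0.0 if diff != 0 else 1.0
            pairs.append(
                {
                    "class_a": names[i],
                    "class_b": names[j],
                    "mean_diff": diff,
                    "se": se,
                    "p_value": p_pair,
                    "significant": p_pair < alpha,
                }
            )
    return {
        "F": float(F),
        "p_value": float(p),
        "df_between": k - 1,
        "df_within": df_within,
        "group_means": {c: float(np.mean(groups[c])) for c in names},
        "group_sizes": {c: int(len(groups[c])) for c in names},
        "excluded_classes": excluded,
        "lsd_pairs": pd.DataFrame(pairs),
    }
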