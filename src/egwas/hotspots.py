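"""Cross-gene eQTL loci, trans-eQTL hotspots and candidate cis regulators.

Gene-level eQTL regions are clustered into shared genomic loci by
single-linkage interval overlap on the same chromosome (two regions join a
locus when their closed [start, end] spans intersect).  A locus associated
with ten or more distinct genes is called a hotspot — the signature of a
shared regulator.  Within a hotspot, member genes whose own region is
cis-classified are candidate regulators, optionally intersected with a
user-supplied transcription-factor gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eqtl import CLASS_CIS, EQTLRegion, regions_frame

DEFAULT_HOTSPOT_MIN_GENES = 10


@dataclass
class Locus:
    """Union span of overlapping eQTL regions on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    member_regions: list[EQTLRegion] = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return sorted({r.gene_id for r in self.member_regions})

    @property
    def n_genes(self) -> int:
        return len({r.gene_id for r in self.member_regions})


@dataclass
class Hotspot(Locus):
    """A locus with at least the hotspot threshold of distinct genes."""

    cis_genes: list[str] = field(default_factory=list)
    candidate_regulators: list[str] = field(default_factory=list)


def aggregate_loci(
    regions: list[EQTLRegion], mode: str = "overlap"
) -> list[Locus]:
    """Single-linkage clustering of regions into loci.

    ``mode='overlap'`` (default) joins regions whose intervals intersect;
    ``mode='shared_top_snp'`` joins regions with an identical top SNP.
    """
    if mode == "shared_top_snp":
        by_snp: dict[str, list[EQTLRegion]] = {}
        for r in regions:
            by_snp.setdefault(r.top_snp_id, []).append(r)
        loci = [
            Locus(
                chrom=members[0].chrom,
                start_bp=min(m.start_bp for m in members),
                end_bp=max(m.end_bp for m in members),
                member_regions=sorted(members, key=lambda m: (m.gene_id, m.start_bp)),
            )
            for members in by_snp.values()
        ]
        return sorted(loci, key=lambda l: (l.chrom, l.start_bp, l.end_bp))
    if mode != "overlap":
        raise ValueError(f"unknown locus-identity mode: {mode}")

    loci: list[Locus] = []
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start_bp, r.end_bp, r.gene_id))
    current: list[EQTLRegion] = []
    cur_end = None
    cur_chrom = None
    for r in ordered:
        if current and r.chrom == cur_chrom and r.start_bp <= cur_end:
            current.append(r)
            cur_end = max(cur_end, r.end_bp)
        else:
            if current:
                loci.append(_make_locus(current))
            current = [r]
            cur_chrom = r.chrom
            cur_end = r.end_bp
    if current:
        loci.append(_make_locus(current))
    return loci


def _make_locus(members: list[EQTLRegion]) -> Locus:
    return Locus(
        chrom=members[0].chrom,
        start_bp=min(m.start_bp for m in members),
        end_bp=max(m.end_bp for m in members),
        member_regions=list(members),
    )


def call_hotspots(
    loci: list[Locus], min_genes: int = DEFAULT_HOTSPOT_MIN_GENES
) -> tuple[list[Hotspot], dict]:
    """Label loci with >= min_genes distinct genes as hotspots, and tally
    loci by gene multiplicity (1 gene / > 1 gene / >= min_genes genes; the
    last group is a subset of the second)."""
    hotspots = [
        Hotspot(
            chrom=l.chrom,
            start_bp=l.start_bp,
            end_bp=l.end_bp,
            member_regions=l.member_regions,
        )
        for l in loci
        if l.n_genes >= min_genes
    ]
    tally = {
        "n_loci": len(loci),
        "n_single_gene": sum(1 for l in loci if l.n_genes == 1),
        "n_multi_gene": sum(1 for l in loci if l.n_genes > 1),
        "n_hotspot": len(hotspots),
        "min_genes": min_genes,
    }
    return hotspots, tally


def cis_regulator_candidates(
    hotspot: Hotspot, tf_list: set[str] | None = None
) -> Hotspot:
    """Fill in the hotspot's cis genes and, when a TF list is supplied,
    the candidate regulators (cis genes annotated as TFs)."""
    hotspot.cis_genes = sorted(
        {r.gene_id for r in hotspot.member_regions if r.eqtl_class == CLASS_CIS}
    )
    if tf_list:
        hotspot.candidate_regulators = sorted(set(hotspot.cis_genes) & set(tf_list))
    else:
        hotspot.candidate_regulators = []
    return hotspot


def hotspot_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = [
        {
            "chrom": h.chrom,
            "start_bp": h.start_bp,
            "end_bp": h.end_bp,
            "n_genes": h.n_genes,
            "genes": ",".join(h.gene_ids),
            "cis_genes": ",".join(h.cis_genes),
            "candidate_regulators": ",".join(h.candidate_regulators),
        }
        for h in hotspots
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "n_genes", "genes", "cis_genes",
            "candidate_regulators",
        ],
    )


def cumulative_offsets(chrom_lengths: pd.Series) -> pd.Series:
    """Genome-wide coordinate offset per chromosome, in the sorted label
    order of the length table."""
    ordered = chrom_lengths.sort_index(key=lambda ix: [_chrom_sort_key(c) for c in ix])
    return pd.Series(
        np.concatenate([[0], np.cumsum(ordered.to_numpy())[:-1]]),
        index=ordered.index,
    )


def _chrom_sort_key(c) -> tuple:
    c = str(c).upper().removeprefix("CHR")
    return (0, int(c)) if c.isdigit() else (1, c)


def eqtl_map_table(
    regions: list[EQTLRegion],
    gene_annot: pd.DataFrame,
    chrom_lengths: pd.Series,
) -> pd.DataFrame:
    """Map-table of top-SNP genome coordinate vs associated-gene TSS genome
    coordinate, one row per classified region (the input for an eQTL map
    scatter: cis on the diagonal, hotspots as vertical bands)."""
    df = regions_frame(regions)
    if df.empty:
        return pd.DataFrame(
            columns=["gene_id", "snp_coord", "gene_coord", "eqtl_class", "chrom", "gene_chrom"]
        )
    offsets = cumulative_offsets(chrom_lengths)
    missing = sorted(
        set(df["chrom"].astype(str)) | set(gene_annot.loc[gene_annot.index.intersection(df["gene_id"]), "chrom"].astype(str))
    )
    missing = [c for c in missing if c not in offsets.index.astype(str).tolist()]
    if missing:
        raise ValueError(f"chromosomes missing from length table: {missing}")
    off = offsets.copy()
    off.index = off.index.astype(str)
    rows = []
    for _, r in df.iterrows():
        gene = r["gene_id"]
        if gene not in gene_annot.index:
            continue
        g_chrom = str(gene_annot.loc[gene, "chrom"])
        g_tss = int(gene_annot.loc[gene, "tss_pos"])
        rows.append(
            {
                "gene_id": gene,
                "snp_coord": int(off[str(r["chrom"])] + r["top_snp_pos"]),
                "gene_coord": int(off[g_chrom] + g_tss),
                "eqtl_class": r["eqtl_class"],
                "chrom": str(r["chrom"]),
                "gene_chrom": g_chrom,
            }
        )
    return pd.DataFrame(rows)


def plot_eqtl_map(map_table: pd.DataFrame, path) -> None:
    """Render the eQTL map scatter to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    colors = {"cis": "tab:red", "trans-I": "tab:blue", "trans-II": "tab:gray"}
    for cls, sub in map_table.groupby("eqtl_class"):
        ax.scatter(
            sub["snp_coord"], sub["gene_coord"], s=6,
            c=colors.get(cls, "black"), label=cls, alpha=0.6,
        )
    ax.set_xlabel("top SNP genome position (bp)")
    ax.set_ylabel("associated gene TSS genome position (bp)")
    ax.legend(frameon=False, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
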