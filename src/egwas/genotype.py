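"""Genotype container and SNP quality control.

The QC filters reproduce the standard array-genotyping cleanup for an eQTL
study: drop SNPs on the Y chromosome / scaffolds / unplaced contigs, SNPs
with more than 10% missing calls, minor allele frequency below 0.01, and
strong Hardy-Weinberg disequilibrium (exact-test p <= 1e-12).  Samples are
never removed.  Filters are applied in a fixed order (chromosome ->
missingness -> MAF -> HWE) so that the per-filter removal counts in
``qc_log`` are deterministic; each SNP is attributed to the first filter it
fails, and the order does not change the surviving set.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import plink

#: chromosome labels removed by default: Y plus anything that looks like a
#: scaffold or unplaced contig (non-numeric, non-X label)
DEFAULT_EXCLUDED_CHROMS = frozenset({"Y"})

QC_FILTER_ORDER = ("chromosome", "missingness", "maf", "hwe")


class EmptyPanelError(ValueError):
    """Raised when no SNP survives quality control."""


@dataclass
class QCThresholds:
    """SNP filter thresholds.

    Boundary semantics are literal: remove if MAF < ``maf_min`` (a SNP at
    exactly 0.01 is kept), remove if HWE exact p <= ``hwe_p_min``, remove if
    missing rate > ``max_missing_rate``.
    """

    maf_min: float = 0.01
    hwe_p_min: float = 1e-12
    max_missing_rate: float = 0.10
    excluded_chroms: frozenset = DEFAULT_EXCLUDED_CHROMS
    drop_scaffolds: bool = True

    def __post_init__(self):
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError(f"maf_min out of range: {self.maf_min}")
        if not (0 <= self.hwe_p_min <= 1):
            raise ValueError(f"hwe_p_min out of range: {self.hwe_p_min}")
        if not (0 <= self.max_missing_rate <= 1):
            raise ValueError(f"max_missing_rate out of range: {self.max_missing_rate}")


@dataclass
class GenotypeDataset:
    """Sample x SNP dosage matrix with its SNP map and QC provenance.

    ``dosages`` is float with values in {0, 1, 2, NaN}, counting copies of
    the A1 allele.  ``snp_map`` is a DataFrame with columns
    (chrom, snp_id, pos, a1, a2), positions 1-based.
    """

    sample_ids: list
    snp_map: pd.DataFrame
    dosages: np.ndarray
    qc_log: dict = field(default_factory=dict)

    def __post_init__(self):
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"dosage rows ({n}) != number of samples ({len(self.sample_ids)})"
            )
        if m != len(self.snp_map):
            raise ValueError(
                f"dosage columns ({m}) != number of SNPs ({len(self.snp_map)})"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages outside {{0,1,2,missing}}: {bad[:5]}")
        if self.snp_map["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in snp_map")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def sort_by_position(self) -> "GenotypeDataset":
        order = self.snp_map.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        return replace(
            self,
            snp_map=self.snp_map.iloc[order].reset_index(drop=True),
            dosages=self.dosages[:, order],
        )

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP A1 allele frequency p = sum(dosage) / (2 * n_nonmissing).

        All-missing columns yield NaN.
        """
        with np.errstate(invalid="ignore"):
            n_called = np.sum(~np.isnan(self.dosages), axis=0)
            total = np.nansum(self.dosages, axis=0)
            return np.where(n_called > 0, total / (2.0 * np.maximum(n_called, 1)), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


def allele_freq(dosage_column: np.ndarray) -> float:
    """A1 allele frequency of one SNP; NaN entries are ignored."""
    d = np.asarray(dosage_column, dtype=float)
    called = d[~np.isnan(d)]
    if called.size == 0:
        return float("nan")
    return float(called.sum() / (2.0 * called.size))


def read_plink(prefix: str | os.PathLike) -> GenotypeDataset:
    """Load a .bed/.bim/.fam fileset into a :class:`GenotypeDataset`."""
    prefix = os.fspath(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing PLINK file: {prefix + ext}")
    bim = plink.read_bim(prefix + ".bim")
    fam = plink.read_fam(prefix + ".fam")
    dosages = plink.read_bed(prefix + ".bed", n_samples=len(fam), n_snps=len(bim))
    snp_map = bim[["chrom", "snp_id", "pos", "a1", "a2"]].copy()
    return GenotypeDataset(
        sample_ids=fam["iid"].tolist(), snp_map=snp_map, dosages=dosages
    )


def write_plink(geno: GenotypeDataset, prefix: str | os.PathLike) -> None:
    plink.write_plink(prefix, geno.sample_ids, geno.snp_map, geno.dosages)


def _is_scaffold(chrom: str) -> bool:
    """Heuristic for scaffold/unplaced labels: anything that is not a plain
    autosome number or X."""
    c = chrom.upper().removeprefix("CHR")
    return not (c.isdigit() or c == "X")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count (Wigginton-style, no mid-p correction).  Monomorphic
    tables return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # probabilities over all heterozygote counts with the same parity,
    # built by the standard two-directional recurrence from the mode
    het_obs = n_Aa
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    hets = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    probs = {mid: 1.0}
    # downward from the mode: P(h-2)/P(h) = h(h-1) / ((hom_rare+1)(hom_common+1))
    h = mid
    while h - 2 >= hets[0]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    # upward: P(h+2)/P(h) = 4 hom_rare hom_common / ((h+2)(h+1))
    h = mid
    while h + 2 <= hets[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs[het_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def _hwe_pvalues(geno: GenotypeDataset, cols: np.ndarray) -> np.ndarray:
    out = np.ones(len(cols))
    for i, j in enumerate(cols):
        d = geno.dosages[:, j]
        n_AA = int(np.sum(d == 2))
        n_Aa = int(np.sum(d == 1))
        n_aa = int(np.sum(d == 0))
        if n_AA + n_Aa + n_aa == 0:
            out[i] = 0.0  # all-missing: force removal here as undefined
        else:
            out[i] = hwe_exact_test(n_AA, n_Aa, n_aa)
    return out


def apply_qc(geno: GenotypeDataset, thr: QCThresholds | None = None) -> GenotypeDataset:
    """Apply the SNP filters and return the surviving panel.

    Each removed SNP is attributed to the first filter it fails, in the
    fixed order chromosome -> missingness -> MAF -> HWE; counts are stored
    in ``qc_log`` together with the input/output sizes.  Samples are kept.
    """
    thr = thr or QCThresholds()
    m = geno.n_snps
    alive = np.ones(m, dtype=bool)
    log: dict = {"n_input": m, "filters": {}, "thresholds": {
        "maf_min": thr.maf_min,
        "hwe_p_min": thr.hwe_p_min,
        "max_missing_rate": thr.max_missing_rate,
    }}

    chroms = geno.snp_map["chrom"].astype(str).to_numpy()
    excluded = np.array(
        [c.upper().removeprefix("CHR") in {x.upper() for x in thr.excluded_chroms}
         or (thr.drop_scaffolds and _is_scaffold(c))
         for c in chroms]
    )
    bad = alive & excluded
    log["filters"]["chromosome"] = int(bad.sum())
    alive &= ~bad

    miss = geno.missing_rate()
    bad = alive & (miss > thr.max_missing_rate)
    log["filters"]["missingness"] = int(bad.sum())
    alive &= ~bad

    maf = geno.maf()
    bad = alive & (np.isnan(maf) | (maf < thr.maf_min))
    log["filters"]["maf"] = int(bad.sum())
    alive &= ~bad

    idx_alive = np.flatnonzero(alive)
    hwe_p = _hwe_pvalues(geno, idx_alive)
    bad_alive = hwe_p <= thr.hwe_p_min
    log["filters"]["hwe"] = int(bad_alive.sum())
    alive[idx_alive[bad_alive]] = False

    log["n_output"] = int(alive.sum())
    if log["n_output"] == 0:
        raise EmptyPanelError("no SNP survives quality control")

    keep = np.flatnonzero(alive)
    return GenotypeDataset(
        sample_ids=list(geno.sample_ids),
        snp_map=geno.snp_map.iloc[keep].reset_index(drop=True),
        dosages=geno.dosages[:, keep].copy(),
        qc_log=log,
    )


def qc_report(geno: GenotypeDataset) -> pd.DataFrame:
    """QC log as a tidy table (filter, n_removed)."""
    filters = geno.qc_log.get("filters", {})
    return pd.DataFrame(
        {"filter": list(filters.keys()), "n_removed": list(filters.values())}
    )
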