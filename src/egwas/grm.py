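"""Genomic relationship matrix (GRM) construction.

G is the VanRaden/GCTA per-SNP-standardized estimator:

    G_jk = (1/N) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the N SNPs polymorphic in the sample, with allele frequencies p_i
estimated from the sample itself and missing dosages mean-imputed to 2 p_i.
For outbred samples the diagonal is near 1 in expectation.  A single GRM is
built from all surviving SNPs (no leave-one-chromosome-out), so the scanned
SNP contributes to the polygenic covariance; this proximal contamination is
accepted and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeDataset


@dataclass
class GRMMatrix:
    """n x n genomic relationship matrix with its eigendecomposition cache."""

    sample_ids: list
    values: np.ndarray
    n_snps_used: int
    stabilization: dict = field(default_factory=dict)
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("GRM must be square and match sample_ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached (eigenvalues, eigenvectors); computed once per matrix."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.values)
            self._eig = (d, U)
        return self._eig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def build_grm(geno: GenotypeDataset) -> GRMMatrix:
    """Build the GRM from QC-filtered genotypes.

    SNPs monomorphic in the sample (p = 0 or 1) are skipped; missing
    dosages are imputed to the SNP mean 2 p.
    """
    p = geno.allele_freqs()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    n_used = int(poly.sum())
    if n_used == 0:
        raise ValueError("no polymorphic SNP available for the GRM")
    X = geno.dosages[:, poly].astype(float)
    pp = p[poly]
    # mean-impute missing to 2p, then standardize per SNP
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, 2.0 * pp[None, :], X)
    Z = (X - 2.0 * pp[None, :]) / np.sqrt(2.0 * pp * (1.0 - pp))[None, :]
    G = (Z @ Z.T) / n_used
    G = 0.5 * (G + G.T)
    return GRMMatrix(sample_ids=list(geno.sample_ids), values=G, n_snps_used=n_used)


def stabilize(G: GRMMatrix, eps: float = 1e-6) -> GRMMatrix:
    """Raise the smallest eigenvalue to ``eps`` by a diagonal shift if the
    matrix is not positive definite at that level; the adjustment is logged."""
    d = np.linalg.eigvalsh(G.values)
    lam_min = float(d[0])
    if lam_min >= eps:
        return GRMMatrix(
            sample_ids=list(G.sample_ids),
            values=G.values,
            n_snps_used=G.n_snps_used,
            stabilization={"adjusted": False, "lambda_min": lam_min},
        )
    shift = eps - lam_min
    return GRMMatrix(
        sample_ids=list(G.sample_ids),
        values=G.values + shift * np.eye(G.n),
        n_snps_used=G.n_snps_used,
        stabilization={"adjusted": True, "lambda_min": lam_min, "shift": shift},
    )


def write_grm_tsv(G: GRMMatrix, path) -> None:
    G.to_frame().to_csv(path, sep="\t")


def read_grm_tsv(path) -> GRMMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRMMatrix(sample_ids=df.index.tolist(), values=df.to_numpy(), n_snps_used=0)


def write_grm_gcta(G: GRMMatrix, prefix: str) -> None:
    """Export in GCTA grm.bin layout (float32 lower triangle row-wise, plus
    a grm.id file) for interoperability with external tools."""
    n = G.n
    tri = G.values[np.tril_indices(n)]
    tri.astype(np.float32).tofile(prefix + ".grm.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for s in G.sample_ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_gcta(prefix: str) -> GRMMatrix:
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32).astype(float)
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin: size does not match {n} samples")
    G = np.zeros((n, n))
    G[np.tril_indices(n)] = tri
    G = G + np.tril(G, -1).T
    return GRMMatrix(sample_ids=ids, values=G, n_snps_used=0)
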