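"""Per-gene linear mixed model and single-SNP association scan.

Each gene's expression (CPM on the natural scale by default) is modeled as

    y = X b + delta * snp + u + e,     u ~ N(0, G sigma_u^2),  e ~ N(0, I sigma_e^2)

with X an intercept plus batch indicator(s).  Variance components are
estimated once per gene by REML under the null model (no SNP term) and then
held fixed while every SNP is tested by generalized least squares, the
convention of mixed-model association tools: for W = [X | snp],
beta_hat = (W' V^-1 W)^-1 W' V^-1 y with V = sigma_u^2 G + sigma_e^2 I, and
a Wald p-value of beta_hat / se against the standard normal.

Everything is computed in the eigenbasis of G (decomposed once and shared
across genes), which turns V into a diagonal weight matrix and makes the
per-SNP GLS a set of small weighted regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype import GenotypeDataset
from .grm import GRMMatrix

#: REML search bounds on the variance ratio lambda = sigma_u^2 / sigma_e^2
LAMBDA_BOUNDS = (1e-6, 1e6)
REML_XTOL = 1e-8

NA_REASON_COLLINEAR = "collinear_with_covariates"


@dataclass
class VarianceComponents:
    gene_id: str
    sigma_u2: float
    sigma_e2: float
    reml_converged: bool
    loglik: float
    identifiable: bool = True

    @property
    def heritability(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0


def make_design(batch: pd.Series, sample_ids: list) -> np.ndarray:
    """Intercept + batch indicator columns (first level as baseline),
    aligned to ``sample_ids``; raises if any sample lacks a batch label."""
    batch = batch.reindex(sample_ids)
    if batch.isna().any():
        missing = [s for s, b in zip(sample_ids, batch.isna()) if b]
        raise ValueError(f"samples without batch label: {missing[:5]}")
    levels = sorted(pd.unique(batch.astype(str)))
    X = [np.ones(len(sample_ids))]
    for lev in levels[1:]:
        X.append((batch.astype(str) == lev).to_numpy(dtype=float))
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


class RotatedDesign:
    """Genotypes, covariates and GRM eigen-structure rotated once and shared
    across all per-gene fits."""

    def __init__(self, geno: GenotypeDataset, G: GRMMatrix, X: np.ndarray):
        if list(geno.sample_ids) != list(G.sample_ids):
            raise ValueError("genotype and GRM sample orders differ")
        self.d, self.U = G.eigendecompose()
        self.X = X
        self.Xr = self.U.T @ X
        S = geno.dosages.astype(float)
        nan_mask = np.isnan(S)
        if nan_mask.any():
            p = geno.allele_freqs()
            S = np.where(nan_mask, 2.0 * p[None, :], S)
        self.snp_sd = S.std(axis=0)
        self.Sr = self.U.T @ S
        self.snp_map = geno.snp_map

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.U.T @ y


def _reml_neg_loglik(log_lam: float, d: np.ndarray, Xr: np.ndarray, yr: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    n, p = Xr.shape
    XtWX = Xr.T @ (w[:, None] * Xr)
    XtWy = Xr.T @ (w * yr)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(np.sum(w * r * r))
    sigma_e2 = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0 or sigma_e2 <= 0:
        return np.inf
    logdet_H = float(-np.sum(np.log(w)))
    return 0.5 * ((n - p) * np.log(sigma_e2) + logdet_H + logdet_xwx + (n - p))


def reml_fit(y: np.ndarray, X: np.ndarray, G: GRMMatrix, gene_id: str = "") -> VarianceComponents:
    """REML variance components under the null (no SNP) model.

    A bounded scalar search over log(lambda), lambda = sigma_u2/sigma_e2,
    on data rotated into G's eigenbasis.  Boundary solutions (sigma_u2
    effectively 0) are permitted.  When G is (numerically) a multiple of
    the identity the two components are not separately identifiable; the
    total variance is then returned as residual with ``identifiable=False``.
    """
    d, U = G.eigendecompose()
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"too few samples ({n}) for {p} fixed effects")
    yr = U.T @ np.asarray(y, dtype=float)
    Xr = U.T @ X

    if np.ptp(d) < 1e-10 * max(1.0, abs(d[-1])):
        beta, _, _, _ = np.linalg.lstsq(Xr, yr, rcond=None)
        r = yr - Xr @ beta
        tot = float(r @ r) / (n - p)
        return VarianceComponents(gene_id, 0.0, tot, True, np.nan, identifiable=False)

    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(lo, hi),
        args=(d, Xr, yr),
        method="bounded",
        options={"xatol": REML_XTOL},
    )
    log_lam = float(res.x)
    # prefer the boundary if it is as good (flat or boundary-optimal likelihood)
    for cand in (lo, hi):
        if _reml_neg_loglik(cand, d, Xr, yr) < res.fun - 1e-10:
            log_lam = cand
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    XtWX = Xr.T @ (w[:, None] * Xr)
    beta = np.linalg.solve(XtWX, Xr.T @ (w * yr))
    r = yr - Xr @ beta
    sigma_e2 = float(np.sum(w * r * r)) / (n - p)
    sigma_u2 = lam * sigma_e2
    if log_lam <= lo + 1e-9:
        sigma_u2 = 0.0
    converged = bool(res.success)
    return VarianceComponents(
        gene_id, sigma_u2, sigma_e2, converged, -float(res.fun), identifiable=True
    )


def snp_scan(
    y: np.ndarray,
    design: RotatedDesign,
    vc: VarianceComponents,
    gene_id: str = "",
) -> pd.DataFrame:
    """GLS association of one gene's trait with every SNP, V fixed at the
    null REML estimates.  Returns one row per SNP with beta (per A1 copy),
    se, p_value, and a reason code for SNPs that cannot be tested
    (zero variance / collinear with the covariates)."""
    yr = design.rotate(np.asarray(y, dtype=float))
    w = 1.0 / (vc.sigma_u2 * design.d + vc.sigma_e2)
    Xr, Sr = design.Xr, design.Sr

    A = Xr.T @ (w[:, None] * Xr)                   # p x p
    Ainv = np.linalg.inv(A)
    b = Xr.T @ (w * yr)                            # p
    C = Xr.T @ (w[:, None] * Sr)                   # p x m
    q = np.einsum("ij,i,ij->j", Sr, w, Sr)         # m
    t = Sr.T @ (w * yr)                            # m

    AinvC = Ainv @ C
    denom = q - np.einsum("ij,ij->j", C, AinvC)    # s' V^-1 s | X
    num = t - C.T @ (Ainv @ b)

    scale = np.maximum(q, 1.0)
    ok = denom > 1e-10 * scale
    ok &= design.snp_sd > 0
    beta = np.full(len(q), np.nan)
    se = np.full(len(q), np.nan)
    pval = np.full(len(q), np.nan)
    beta[ok] = num[ok] / denom[ok]
    se[ok] = np.sqrt(1.0 / denom[ok])
    z = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.norm.sf(np.abs(z))
    pval[ok] = np.clip(pval[ok], np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "gene_id": gene_id or vc.gene_id,
            "snp_id": design.snp_map["snp_id"].to_numpy(),
            "chrom": design.snp_map["chrom"].to_numpy(),
            "pos": design.snp_map["pos"].to_numpy(),
            "a1": design.snp_map["a1"].to_numpy()
            if "a1" in design.snp_map
            else "",
            "beta": beta,
            "se": se,
            "p_value": pval,
            "reason": np.where(ok, "", NA_REASON_COLLINEAR),
        }
    )
    return out


def egwas_all_genes(
    expr,
    geno: GenotypeDataset,
    G: GRMMatrix,
    covariates: pd.DataFrame,
    log1p_cpm: bool = False,
    checkpoint_dir=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Full scan: every expressed gene against every SNP.

    Samples are aligned by ID across expression, genotypes, GRM and
    covariates; a hard error lists any mismatch.  Output rows are ordered
    by (gene, chrom, pos).  With ``checkpoint_dir`` set, per-gene results
    are written as TSVs and finished genes are skipped on resume.
    """
    import os

    sample_ids = list(geno.sample_ids)
    missing = [s for s in sample_ids if s not in set(expr.sample_ids)]
    extra = [s for s in expr.sample_ids if s not in set(sample_ids)]
    if missing or extra:
        raise ValueError(
            f"sample mismatch between expression and genotypes: "
            f"missing from expression {missing[:5]}, extra {extra[:5]}"
        )
    if expr.cpm is None:
        raise ValueError("expression must be normalized before the scan")

    col_order = [expr.sample_ids.index(s) for s in sample_ids]
    Y = expr.cpm[:, col_order]
    if log1p_cpm:
        Y = np.log1p(Y)

    covar = covariates.set_index("sample_id") if "sample_id" in covariates.columns else covariates
    X = make_design(covar["batch"], sample_ids)
    design = RotatedDesign(geno, G, X)

    chunks = []
    gene_iter = list(enumerate(expr.gene_ids))
    if progress:
        from tqdm import tqdm  # pragma: no cover

        gene_iter = tqdm(gene_iter)  # pragma: no cover
    for gi, gene in gene_iter:
        if checkpoint_dir is not None:
            ckpt = os.path.join(checkpoint_dir, f"{gene}.scan.tsv")
            if os.path.exists(ckpt):
                chunks.append(pd.read_csv(ckpt, sep="\t", dtype={"chrom": str}))
                continue
        y = Y[gi]
        vc = reml_fit(y, X, G, gene_id=gene)
        tab = snp_scan(y, design, vc, gene_id=gene)
        tab = tab.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if checkpoint_dir is not None:
            os.makedirs(checkpoint_dir, exist_ok=True)
            tab.to_csv(ckpt, sep="\t", index=False)
        chunks.append(tab)
    return pd.concat(chunks, ignore_index=True)
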