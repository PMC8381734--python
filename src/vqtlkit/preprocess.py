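"""Covariate residualization, MAF filtering, ancestry PCA and LD tools.

The trait is adjusted once, globally, by ordinary least squares on the
covariates and the residuals are the phenotype carried into every
downstream test.  Ancestry PCs come from the SVD of the standardized
(LD-pruned) dosage matrix.  Pairwise LD is the squared Pearson
correlation of dosage vectors on pairwise-complete samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataio import GenotypeMatrix, PhenotypeTable

log = logging.getLogger(__name__)

__all__ = ["ResidualTrait", "PcaResult", "residualize", "ancestry_pca",
           "ld_r2", "ld_prune", "maf_filter"]


@dataclass
class ResidualTrait:
    """Covariate-adjusted trait residuals for the complete-case samples."""

    samples: list[str]
    values: np.ndarray
    covariates: list[str]
    coefficients: pd.Series
    r_squared: float

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.samples))


@dataclass
class PcaResult:
    """Top ancestry principal components of a genotype matrix."""

    scores: np.ndarray        # (n_samples, n_pcs)
    eigenvalues: np.ndarray   # descending
    variant_ids: list[str]    # variants the decomposition used
    loadings: np.ndarray      # (n_variants_used, n_pcs)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in exact linear dependence (via QR)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def residualize(pheno: PhenotypeTable, trait: str | None = None,
                covariates: list[str] | None = None) -> ResidualTrait:
    """OLS of the trait on intercept + covariates; residuals for complete
    rows only.  Residuals are exactly orthogonal to every covariate used.
    """
    trait = trait or pheno.trait
    covariates = covariates if covariates is not None else pheno.covariates
    if trait is None:
        raise ValueError("no trait specified")
    cols = [trait] + list(covariates)
    data = pheno.table[cols].dropna()
    if len(data) < 10:
        raise ValueError(f"need >= 10 complete rows, got {len(data)}")
    y = data[trait].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(dtype=float) for c in covariates])
    names = ["intercept"] + list(covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate design; collinear "
                         f"column(s): {bad}")
    fit = sm.OLS(y, X).fit()
    return ResidualTrait(samples=list(data.index),
                         values=np.asarray(fit.resid),
                         covariates=list(covariates),
                         coefficients=pd.Series(fit.params, index=names),
                         r_squared=float(fit.rsquared) if covariates else 0.0)


def maf_filter(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain variants with MAF >= ``min_maf`` on non-missing calls.

    Discovery-style scans use 0.2; replication-style scans 0.1.
    """
    if min_maf <= 0:
        return G
    return G.take_variants(np.flatnonzero(G.maf() >= min_maf))


def ld_r2(G: GenotypeMatrix, i: int | str, j: int | str) -> float:
    """Squared Pearson correlation of two dosage vectors,
    pairwise-complete; NaN when a variant is monomorphic on the shared
    samples."""
    a, b = G.dosage(i), G.dosage(j)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    # computed symmetrically so ld_r2(G, i, j) == ld_r2(G, j, i) exactly
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac @ bc) ** 2 / ((ac @ ac) * (bc @ bc)))


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """r^2 matrix for a (n, m) dosage matrix with NaNs, pairwise complete."""
    r = pd.DataFrame(d).corr(min_periods=2).to_numpy()
    return r * r


def ld_prune(G: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_threshold: float = 0.2) -> np.ndarray:
    """Sliding-window greedy LD pruning; returns sorted retained indices.

    Within each window of ``window`` SNPs (advanced by ``step``), while
    any retained pair exceeds the r^2 threshold the member with the lower
    MAF is dropped (ties drop the larger index); the offending pair with
    the largest r^2 is resolved first.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    m = G.n_variants
    maf = G.maf()
    retained = np.ones(m, dtype=bool)
    d_all = np.where(G.calls == -1, np.nan, G.calls).astype(float)
    for start in range(0, max(m - 1, 1), step):
        idx = np.flatnonzero(retained[start:start + window]) + start
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(d_all[:, idx])
        np.fill_diagonal(r2, 0.0)
        r2 = np.nan_to_num(r2)
        local = np.ones(idx.size, dtype=bool)
        while True:
            sub = np.where(np.outer(local, local), r2, 0.0)
            if sub.max() <= r2_threshold:
                break
            a, b = np.unravel_index(np.argmax(sub), sub.shape)
            ia, ib = idx[a], idx[b]
            if maf[ia] < maf[ib] or (maf[ia] == maf[ib] and ia > ib):
                drop = a
            else:
                drop = b
            local[drop] = False
        retained[idx[~local]] = False
    return np.flatnonzero(retained)


def ancestry_pca(G: GenotypeMatrix, n_pcs: int = 4,
                 prune: bool = True, prune_window: int = 50,
                 prune_step: int = 5, prune_r2: float = 0.2) -> PcaResult:
    """Ancestry PCs from the standardized (optionally LD-pruned) dosages.

    Each SNP is standardized as (g - 2p) / sqrt(2p(1-p)) with missing
    calls set to 0 after centering (mean imputation).  Scores are the top
    left singular structure; each component's sign is fixed so that its
    largest-|loading| variant has a positive loading.
    """
    idx = ld_prune(G, prune_window, prune_step, prune_r2) if prune \
        else np.arange(G.n_variants)
    Gp = G.take_variants(idx)
    maf = Gp.maf()
    poly = np.flatnonzero((maf > 0) & np.isfinite(maf))
    n_mono = Gp.n_variants - poly.size
    if n_mono:
        log.info("ancestry_pca: excluded %d monomorphic variants", n_mono)
    Gp = Gp.take_variants(poly)
    if Gp.n_variants < n_pcs:
        raise ValueError(f"need >= {n_pcs} polymorphic SNPs after pruning, "
                         f"got {Gp.n_variants}")
    d = np.where(Gp.calls == -1, np.nan, Gp.calls).astype(float)
    p = np.nanmean(d, axis=0) / 2.0
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    loadings = vt[:n_pcs].T
    for k in range(n_pcs):
        top = np.argmax(np.abs(loadings[:, k]))
        if loadings[top, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    eigenvalues = s ** 2 / (Gp.n_samples - 1)
    return PcaResult(scores=scores, eigenvalues=eigenvalues[:n_pcs],
                     variant_ids=Gp.variants["id"].tolist(),
                     loadings=loadings)
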