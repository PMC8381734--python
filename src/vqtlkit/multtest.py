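"""Effective number of independent tests and replication thresholds.

A window of correlated SNPs supports fewer independent tests than its
SNP count.  The eigenvalue-based estimate used here sums
f(|lambda_i|) = 1[|lambda_i| >= 1] + (|lambda_i| - floor(|lambda_i|))
over the eigenvalues of the variant-by-variant Pearson correlation
matrix; the rounded integer feeds product-rule Bonferroni thresholds
(alpha divided by the product of the Meff of each region under test).
LD-proxy selection for unavailable target SNPs lives here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix
from .preprocess import _pairwise_r2  # noqa: F401  (same LD conventions)

log = logging.getLogger(__name__)

__all__ = ["MeffResult", "meff_from_eigenvalues", "meff_from_correlation",
           "meff_li_ji", "bonferroni_threshold", "select_proxies"]


@dataclass
class MeffResult:
    """Effective-test count for one region."""

    m: int                   # variants considered
    eigenvalues: np.ndarray  # descending
    meff: float              # real-valued sum
    meff_int: int            # round-half-up integer used for thresholds


def _f(x: np.ndarray) -> np.ndarray:
    x = np.abs(x)
    return (x >= 1).astype(float) + (x - np.floor(x))


def meff_from_eigenvalues(eigenvalues: np.ndarray) -> MeffResult:
    eig = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    meff = float(np.sum(_f(eig)))
    return MeffResult(m=eig.size, eigenvalues=eig, meff=meff,
                      meff_int=int(math.floor(meff + 0.5)))


def meff_from_correlation(R: np.ndarray) -> MeffResult:
    """Meff from a correlation matrix (symmetrized; tiny negative
    eigenvalues clipped to zero)."""
    R = np.asarray(R, dtype=float)
    R = (R + R.T) / 2.0
    eig = np.linalg.eigvalsh(R)
    eig[(eig < 0) & (eig > -1e-8)] = 0.0
    return meff_from_eigenvalues(eig)


def meff_li_ji(G_region: GenotypeMatrix) -> MeffResult:
    """Meff of a genotype region from its pairwise-complete dosage
    correlations; monomorphic variants are excluded (logged)."""
    maf = G_region.maf()
    poly = np.flatnonzero(maf > 0)
    n_mono = G_region.n_variants - poly.size
    if n_mono:
        log.info("meff_li_ji: excluded %d monomorphic variants", n_mono)
    if poly.size < 2:
        raise ValueError("need >= 2 polymorphic variants")
    d = np.where(G_region.calls[:, poly] == -1, np.nan,
                 G_region.calls[:, poly]).astype(float)
    R = pd.DataFrame(d).corr(min_periods=2).to_numpy()
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    return meff_from_correlation(R)


def bonferroni_threshold(alpha: float,
                         meff_list: list[int | MeffResult]) -> float:
    """alpha divided by the product of the (integer) Meff values.

    An empty list returns alpha unchanged (no correction, logged).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not meff_list:
        log.warning("bonferroni_threshold: empty Meff list, no correction")
        return alpha
    prod = 1
    for m in meff_list:
        v = m.meff_int if isinstance(m, MeffResult) else int(m)
        if v < 1:
            raise ValueError("Meff values must be >= 1")
        prod *= v
    return alpha / prod


def select_proxies(G: GenotypeMatrix, target_id: str, min_r2: float = 0.8,
                   max_n: int | None = None) -> pd.DataFrame:
    """LD proxies for a target SNP: variants with r^2 >= min_r2, sorted
    by descending r^2 with ties broken by physical distance."""
    jt = G.index_of(target_id)  # raises KeyError when absent
    d = G.dosage(jt)
    if np.nanstd(d) == 0:
        raise ValueError(f"target {target_id!r} is monomorphic")
    tpos = int(G.variants.at[jt, "pos"])
    rows = []
    for j in range(G.n_variants):
        if j == jt:
            continue
        from .preprocess import ld_r2
        r2 = ld_r2(G, jt, j)
        if np.isfinite(r2) and r2 >= min_r2:
            rows.append({"ID": G.variants.at[j, "id"],
                         "CHR": G.variants.at[j, "chrom"],
                         "POS": int(G.variants.at[j, "pos"]),
                         "R2": r2,
                         "DIST": abs(int(G.variants.at[j, "pos"]) - tpos)})
    table = pd.DataFrame(rows, columns=["ID", "CHR", "POS", "R2", "DIST"])
    table = table.sort_values(["R2", "DIST"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    if max_n is not None:
        table = table.head(max_n)
    return table
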