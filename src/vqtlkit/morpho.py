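"""Generalized Procrustes analysis of 2D landmark configurations and
genotype association with a derived width measure.

Configurations are translated to the origin, scaled to unit centroid
size and iteratively rotated to the evolving consensus by the 2D
orthogonal Procrustes solution with the determinant constrained to +1
(labelled biological landmarks must not be mirrored).  A bilateral
inter-landmark distance on the aligned coordinates gives the width
measure, whose mean is tested by linear regression on allele dose
(adjusting for centroid size and litter) and whose variance by the
median-based Levene test on covariate-adjusted residuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import LandmarkTable
from .vqtl import VqtlRecord, levene_median_test

log = logging.getLogger(__name__)

__all__ = ["ProcrustesResult", "MeanTestRecord", "centroid_size", "gpa",
           "interlandmark_distance", "genotype_morph_test"]

_TOL = 1e-10
_MAX_ITER = 100


@dataclass
class ProcrustesResult:
    """Superimposed configurations at unit centroid size."""

    aligned: np.ndarray        # (n, k, 2), centered, unit centroid size
    centroid_sizes: np.ndarray  # original units, per specimen
    consensus: np.ndarray      # (k, 2), unit centroid size
    n_iter: int
    converged: bool
    objective: float           # summed squared distance to consensus


@dataclass
class MeanTestRecord:
    """Wald test of the allele-dose coefficient in the width regression."""

    n: int
    beta: float
    se: float
    stat: float
    df: int
    p: float
    covariates: list[str]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to their
    centroid — the standard configuration scale measure."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need a k x 2 matrix with k >= 3")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered ** 2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks identical")
    return cs


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||a R - b||_F."""
    u, _, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _as_coords(configs) -> np.ndarray:
    if isinstance(configs, LandmarkTable):
        return configs.coords
    return np.asarray(configs, dtype=float)


def gpa(configs) -> ProcrustesResult:
    """Generalized Procrustes superimposition to unit centroid size.

    Iterates rotation-to-consensus and consensus re-estimation (the mean
    of the aligned configurations, renormalized to unit size) until the
    summed squared Procrustes distance changes by < 1e-10 or 100
    iterations.  The global rotational ambiguity is fixed by rotating
    everything onto the first specimen's principal axes.
    """
    coords = _as_coords(configs)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("need >= 2 configurations of shape (k, 2)")
    n = coords.shape[0]
    csizes = np.empty(n)
    shapes = np.empty_like(coords)
    for i in range(n):
        centered = coords[i] - coords[i].mean(axis=0)
        cs = float(np.sqrt(np.sum(centered ** 2)))
        if cs == 0.0 or np.linalg.matrix_rank(centered) < 2:
            raise ValueError(f"degenerate configuration at specimen {i} "
                             "(zero size or collinear landmarks)")
        csizes[i] = cs
        shapes[i] = centered / cs
    consensus = shapes.mean(axis=0)
    consensus /= np.sqrt(np.sum(consensus ** 2))
    aligned = shapes.copy()
    prev_obj = np.inf
    converged = False
    for it in range(1, _MAX_ITER + 1):
        for i in range(n):
            aligned[i] = shapes[i] @ _rotation_to(shapes[i], consensus)
        consensus = aligned.mean(axis=0)
        consensus /= np.sqrt(np.sum(consensus ** 2))
        obj = float(np.sum((aligned - consensus) ** 2))
        if abs(prev_obj - obj) < _TOL:
            converged = True
            break
        prev_obj = obj
    # fix the global rotation: principal axes of the first aligned specimen
    w, v = np.linalg.eigh(aligned[0].T @ aligned[0])
    v = v[:, ::-1]  # descending variance
    if np.linalg.det(v) < 0:
        v[:, 1] *= -1
    if (aligned[0] @ v)[0, 0] < 0:  # resolve the pi ambiguity
        v = -v
    aligned = aligned @ v
    consensus = consensus @ v
    return ProcrustesResult(aligned=aligned, centroid_sizes=csizes,
                            consensus=consensus, n_iter=it,
                            converged=converged, objective=obj)


def interlandmark_distance(result: ProcrustesResult, i: int,
                           j: int) -> np.ndarray:
    """Per-specimen Euclidean distance between landmarks i and j on the
    aligned (unit-size) coordinates."""
    if i == j:
        raise ValueError("landmark indices must differ")
    k = result.aligned.shape[1]
    if not (0 <= i < k and 0 <= j < k):
        raise ValueError("landmark index out of range")
    diff = result.aligned[:, i, :] - result.aligned[:, j, :]
    return np.sqrt(np.sum(diff ** 2, axis=1))


def _litter_dummies(litter: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(litter))
    cols = [(litter == lv).astype(float) for lv in levels[1:]]
    names = [f"litter[{lv}]" for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((litter.size, 0)),
            names)


def genotype_morph_test(widths: np.ndarray, dose: np.ndarray,
                        centroid_sizes: np.ndarray | None = None,
                        litter: np.ndarray | None = None,
                        min_group: int = 3
                        ) -> tuple[MeanTestRecord, VqtlRecord]:
    """Mean and variance tests of a width measure across allele doses.

    Mean test: OLS of width on additive dose + centroid size + litter
    indicators, Wald p for the dose coefficient.  Variance test: the
    median-based Levene test across dose groups of the width residuals
    after adjusting for centroid size and litter only (dose excluded so
    a genuine variance difference is preserved).
    """
    widths = np.asarray(widths, dtype=float)
    dose = np.asarray(dose, dtype=float)
    n = widths.size
    if np.unique(dose).size < 2:
        raise ValueError("need >= 2 dose groups")
    cols: list[np.ndarray] = []
    names: list[str] = []
    if centroid_sizes is not None:
        cols.append(np.asarray(centroid_sizes, dtype=float))
        names.append("centroid_size")
    if litter is not None:
        litter = np.asarray(litter)
        if len(set(litter.tolist())) < 2:
            warnings.warn("fewer than 2 litters: litter adjustment skipped")
            litter = None
        else:
            d, dn = _litter_dummies(litter)
            cols.append(d)
            names.extend(dn)
    Z = np.column_stack(cols) if cols else np.empty((n, 0))
    # mean test
    X = np.column_stack([np.ones(n), dose] + ([Z] if Z.size else []))
    p_params = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, widths, rcond=None)
    resid = widths - X @ beta
    rss = float(resid @ resid)
    df = n - p_params
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(rss / df * xtx_inv[1, 1]))
    t = float(beta[1] / se)
    mean_rec = MeanTestRecord(n=n, beta=float(beta[1]), se=se, stat=t,
                              df=df, p=float(2 * stats.t.sf(abs(t), df)),
                              covariates=names)
    # variance test on covariate-adjusted residuals (dose left out)
    Xv = np.column_stack([np.ones(n)] + ([Z] if Z.size else []))
    bv, *_ = np.linalg.lstsq(Xv, widths, rcond=None)
    resid_v = widths - Xv @ bv
    var_rec = levene_median_test(resid_v, dose, min_group=min_group)
    return mean_rec, var_rec
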