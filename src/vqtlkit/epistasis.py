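"""Anchored gene-by-gene interaction scanning with robust inference.

The interaction model is the classic product-term regression

    y = b0 + b1 gA + b2 gB + b3 gA*gB + e

fit by OLS, with the interaction coefficient b3 tested by a two-sided t
with N - 4 df.  Because anchoring the scan at a variance-heterogeneous
SNP violates homoscedasticity, the coefficient covariance can be the
heteroscedasticity-consistent sandwich (HC0-HC3; HC3 by default) instead
of the model-based sigma^2 (X'X)^-1 — the "auto" policy monitors the
genomic inflation factor of the model-based p-values and switches to the
sandwich when lambda exceeds a threshold (default 1.05).

The module also hosts the decomposition tools that discriminate an
interaction-induced variance signal from a direct one: stratified slopes,
stratified variance scans (with optional downsampling to equal strata),
gene-by-environment 1-df/2-df tests, co-localization tables and an
extreme-observation sensitivity re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GenotypeMatrix
from .preprocess import ld_r2
from .vqtl import (InsufficientGroupsError, ScanResult, VqtlRecord, _align,
                   genomic_lambda, levene_median_test, vqtl_scan,
                   GENOMEWIDE_P)

log = logging.getLogger(__name__)

__all__ = ["InteractionRecord", "StratumEffect", "interaction_test",
           "scan_partner", "stratified_effects", "stratified_vqtl",
           "gxe_tests", "colocalize_table", "sensitivity_drop_extreme"]

HC_TYPES = ("model", "HC0", "HC1", "HC2", "HC3")


@dataclass
class InteractionRecord:
    """Result of one product-term interaction fit."""

    id_a: str
    id_b: str
    n: int
    beta_a: float
    beta_b: float
    beta_ab: float
    se_ab: float
    cov_type: str
    stat: float
    df: int
    p: float
    degenerate: bool = False


@dataclass
class StratumEffect:
    """Slope of y on gB within one genotype stratum of gA."""

    stratum: int | str
    n: int
    beta_b: float
    se: float
    p: float


# ---------------------------------------------------------------------------
# core OLS + sandwich machinery
# ---------------------------------------------------------------------------

def _ols_core(X: np.ndarray, y: np.ndarray):
    """Return (beta, resid, XtX_inv, rss)."""
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (collinear columns)") from exc
    # guard against silently singular but numerically invertible designs
    if np.linalg.cond(xtx) > 1e12:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (collinear columns)")
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    return beta, resid, xtx_inv, float(resid @ resid)


def _cov_beta(X: np.ndarray, resid: np.ndarray, xtx_inv: np.ndarray,
              rss: float, cov_type: str) -> np.ndarray:
    """Model-based or HC0-HC3 sandwich covariance of the OLS coefficients.

    HC0 weights 1, HC1 n/(n-p), HC2 1/(1-h), HC3 1/(1-h)^2 where h is the
    leverage (hat-matrix diagonal).
    """
    n, p = X.shape
    if cov_type == "model":
        return rss / (n - p) * xtx_inv
    if cov_type not in HC_TYPES:
        raise ValueError(f"unknown cov_type {cov_type!r}")
    e2 = resid ** 2
    if cov_type == "HC0":
        w = e2
    elif cov_type == "HC1":
        w = e2 * (n / (n - p))
    else:
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        if cov_type == "HC2":
            w = e2 / (1.0 - h)
        else:  # HC3
            w = e2 / (1.0 - h) ** 2
    meat = (X * w[:, None]).T @ X
    return xtx_inv @ meat @ xtx_inv


def _complete(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    return tuple(a[mask] for a in arrays)


def interaction_test(y: np.ndarray, gA: np.ndarray, gB: np.ndarray,
                     cov_type: str = "HC3", id_a: str = "A",
                     id_b: str = "B", min_n: int = 30) -> InteractionRecord:
    """Product-term interaction test of two dosage vectors on y.

    Uses only complete (y, gA, gB) triples; raises on a rank-deficient
    design (e.g. gA and gB in perfect LD).  A zero-residual fit keeps the
    exact point estimates but is flagged degenerate with p = 0.
    """
    y, gA, gB = _complete(np.asarray(y, float), np.asarray(gA, float),
                          np.asarray(gB, float))
    n = y.size
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete triples, got {n}")
    X = np.column_stack([np.ones(n), gA, gB, gA * gB])
    beta, resid, xtx_inv, rss = _ols_core(X, y)
    df = n - 4
    if rss <= max(1e-12, 1e-12 * float(y @ y)):
        return InteractionRecord(id_a, id_b, n, beta[1], beta[2], beta[3],
                                 0.0, cov_type, float("inf"), df, 0.0,
                                 degenerate=True)
    cov = _cov_beta(X, resid, xtx_inv, rss, cov_type)
    se = float(np.sqrt(cov[3, 3]))
    t = beta[3] / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return InteractionRecord(id_a, id_b, n, float(beta[1]), float(beta[2]),
                             float(beta[3]), se, cov_type, float(t), df,
                             max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# anchored partner scan
# ---------------------------------------------------------------------------

def scan_partner(G: GenotypeMatrix, y, anchor_id: str,
                 robust_policy: str = "auto", cov_type: str = "HC3",
                 exclude_r2: float = 0.9, lambda_threshold: float = 1.05,
                 genomewide: float = GENOMEWIDE_P, min_n: int = 30
                 ) -> tuple[pd.DataFrame, dict]:
    """Test the anchor against every other variant in ``G``.

    Partners in near-perfect LD with the anchor (r^2 > ``exclude_r2``)
    and monomorphic partners are skipped (logged in diagnostics).  Both
    the model-based and the sandwich p-values are computed in one pass;
    the reported column follows ``robust_policy``:

    - ``never``: model-based covariance;
    - ``always``: the chosen HC sandwich;
    - ``auto``: model-based unless its genomic inflation factor exceeds
      ``lambda_threshold``, then the sandwich.
    """
    if robust_policy not in ("never", "always", "auto"):
        raise ValueError(f"unknown robust_policy {robust_policy!r}")
    yv = _align(G, y)
    ja = G.index_of(anchor_id)
    gA = G.dosage(ja)
    if np.nanstd(gA) == 0:
        raise ValueError(f"anchor {anchor_id!r} is monomorphic")
    rows, excluded = [], []
    for j in range(G.n_variants):
        if j == ja:
            continue
        vid = G.variants.at[j, "id"]
        gB = G.dosage(j)
        if np.nanstd(gB) == 0:
            excluded.append({"ID": vid, "REASON": "monomorphic"})
            continue
        r2 = ld_r2(G, ja, j)
        if np.isfinite(r2) and r2 > exclude_r2:
            excluded.append({"ID": vid, "REASON": f"r2={r2:.3f} to anchor"})
            continue
        yc, a, b = _complete(yv, gA, gB)
        n = yc.size
        if n < min_n:
            excluded.append({"ID": vid, "REASON": "too few complete triples"})
            continue
        X = np.column_stack([np.ones(n), a, b, a * b])
        try:
            beta, resid, xtx_inv, rss = _ols_core(X, yc)
        except np.linalg.LinAlgError:
            excluded.append({"ID": vid, "REASON": "collinear with anchor"})
            continue
        df = n - 4
        if rss <= 1e-12 * max(1.0, float(yc @ yc)):
            rows.append({"ID_A": anchor_id, "ID_B": vid, "N": n,
                         "BETA_A": beta[1], "BETA_B": beta[2],
                         "BETA_INT": beta[3], "SE_MODEL": 0.0,
                         "SE_ROBUST": 0.0, "P_MODEL": 0.0, "P_ROBUST": 0.0,
                         "DF": df, "DEGENERATE": True})
            continue
        se_m = float(np.sqrt(_cov_beta(X, resid, xtx_inv, rss,
                                       "model")[3, 3]))
        se_r = float(np.sqrt(_cov_beta(X, resid, xtx_inv, rss,
                                       cov_type)[3, 3]))
        p_m = float(2 * stats.t.sf(abs(beta[3] / se_m), df))
        p_r = float(2 * stats.t.sf(abs(beta[3] / se_r), df))
        rows.append({"ID_A": anchor_id, "ID_B": vid, "N": n,
                     "BETA_A": beta[1], "BETA_B": beta[2],
                     "BETA_INT": beta[3], "SE_MODEL": se_m,
                     "SE_ROBUST": se_r, "P_MODEL": p_m, "P_ROBUST": p_r,
                     "DF": df, "DEGENERATE": False})
    table = pd.DataFrame(rows)
    diagnostics: dict = {"anchor": anchor_id, "policy": robust_policy,
                         "hc_type": cov_type,
                         "excluded": pd.DataFrame(excluded)}
    if len(table) == 0:
        diagnostics.update(lambda_model=float("nan"),
                           lambda_robust=float("nan"), cov_type_used="none")
        return table, diagnostics
    ok = ~table["DEGENERATE"]
    lam_m = genomic_lambda(table.loc[ok, "P_MODEL"].to_numpy()) \
        if ok.sum() >= 100 else float("nan")
    lam_r = genomic_lambda(table.loc[ok, "P_ROBUST"].to_numpy()) \
        if ok.sum() >= 100 else float("nan")
    use_robust = robust_policy == "always" or (
        robust_policy == "auto" and np.isfinite(lam_m)
        and lam_m > lambda_threshold)
    chosen = "P_ROBUST" if use_robust else "P_MODEL"
    table["P"] = table[chosen]
    table["SE_INT"] = table["SE_ROBUST" if use_robust else "SE_MODEL"]
    with np.errstate(divide="ignore", invalid="ignore"):
        table["STAT"] = np.where(table["SE_INT"] > 0,
                                 table["BETA_INT"] / table["SE_INT"],
                                 np.inf)
    table["COV_TYPE"] = cov_type if use_robust else "model"
    table["SIGNIFICANT"] = table["P"] < genomewide
    diagnostics.update(lambda_model=lam_m, lambda_robust=lam_r,
                       cov_type_used=cov_type if use_robust else "model")
    return table, diagnostics


# ---------------------------------------------------------------------------
# decomposition of the variance signal
# ---------------------------------------------------------------------------

def _slope(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of y on (1, x): (beta, se, p)."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    beta, resid, xtx_inv, rss = _ols_core(X, y)
    se = float(np.sqrt(rss / (n - 2) * xtx_inv[1, 1]))
    t = beta[1] / se
    return float(beta[1]), se, float(2 * stats.t.sf(abs(t), n - 2))


def stratified_effects(y: np.ndarray, gA: np.ndarray, gB: np.ndarray,
                       min_n: int = 10) -> pd.DataFrame:
    """Per-stratum (of gA) slope of y on gB, plus the unstratified slope.

    Under the interaction model the stratum-a slope is beta_b +
    beta_ab * a, while the combined slope is beta_b + beta_ab * E[gA]
    — opposite stratum effects can cancel in the combined sample.
    """
    y, gA, gB = _complete(np.asarray(y, float), np.asarray(gA, float),
                          np.asarray(gB, float))
    rows = []
    for a in (0, 1, 2):
        mask = gA == a
        n = int(mask.sum())
        if n >= min_n and np.ptp(gB[mask]) > 0:
            b, se, p = _slope(y[mask], gB[mask])
        else:
            b = se = p = float("nan")
        rows.append({"STRATUM_GENO": a, "N": n, "BETA_B": b,
                     "SE": se, "P": p})
    b, se, p = _slope(y, gB)
    rows.append({"STRATUM_GENO": "all", "N": y.size, "BETA_B": b,
                 "SE": se, "P": p})
    return pd.DataFrame(rows)


def stratified_vqtl(G_locusA: GenotypeMatrix, y, gB: np.ndarray,
                    downsample: bool = False, seed: int | None = None,
                    min_group: int = 5) -> dict[int, ScanResult]:
    """Variance scan of the anchor-locus variants within each gB stratum.

    If the anchor's variance heterogeneity is induced by its interaction
    with gB, the within-stratum signal should be absent or much
    attenuated; a direct variance effect persists.  With ``downsample``
    the larger strata are randomly reduced (without replacement, seeded)
    to the smallest stratum size.
    """
    yv = _align(G_locusA, y)
    gB = np.asarray(gB, dtype=float)
    strata = {}
    sizes = {a: int(np.sum(gB == a)) for a in (0, 1, 2) if np.any(gB == a)}
    floor = 3 * min_group
    usable = {a: s for a, s in sizes.items() if s >= floor}
    target = min(usable.values()) if (downsample and usable) else None
    rng = np.random.default_rng(seed)
    for a, size in sizes.items():
        if size < floor:
            log.info("stratified_vqtl: stratum %d skipped (n=%d < %d)",
                     a, size, floor)
            continue
        idx = np.flatnonzero(gB == a)
        if target is not None and idx.size > target:
            idx = np.sort(rng.choice(idx, size=target, replace=False))
        strata[a] = vqtl_scan(G_locusA.take_samples(idx), yv[idx],
                              min_group=min_group)
    return strata


def gxe_tests(y: np.ndarray, g: np.ndarray, E: np.ndarray,
              cov_type: str = "HC3"
              ) -> tuple[InteractionRecord, dict]:
    """1-df and 2-df gene-by-environment tests for y = b0 + b1 g + b2 E
    + b3 gE.

    The 1-df record is the Wald test of the interaction coefficient b3
    alone; the 2-df record the joint Wald chi-square of (b1, b3) against
    chi-square with 2 df.
    """
    y, g, E = _complete(np.asarray(y, float), np.asarray(g, float),
                        np.asarray(E, float))
    n = y.size
    if np.ptp(E) == 0:
        raise np.linalg.LinAlgError("exposure E is constant (rank error)")
    X = np.column_stack([np.ones(n), g, E, g * E])
    beta, resid, xtx_inv, rss = _ols_core(X, y)
    cov = _cov_beta(X, resid, xtx_inv, rss, cov_type)
    df = n - 4
    se3 = float(np.sqrt(cov[3, 3]))
    t = beta[3] / se3
    rec1 = InteractionRecord("g", "E", n, float(beta[1]), float(beta[2]),
                             float(beta[3]), se3, cov_type, float(t), df,
                             float(2 * stats.t.sf(abs(t), df)))
    theta = beta[[1, 3]]
    V = cov[np.ix_([1, 3], [1, 3])]
    chi2 = float(theta @ np.linalg.solve(V, theta))
    rec2 = {"n": n, "chi2": chi2, "df": 2,
            "p": float(stats.chi2.sf(chi2, 2)), "cov_type": cov_type,
            "beta_main": float(beta[1]), "beta_int": float(beta[3])}
    return rec1, rec2


def colocalize_table(vqtl_records: pd.DataFrame,
                     interaction_records: pd.DataFrame, lead_id: str,
                     G: GenotypeMatrix, window_bp: int = 500_000
                     ) -> pd.DataFrame:
    """Joint -log10 p table of the variance and interaction signals.

    One row per variant shared by both record sets within the closed
    +-window around the lead, with its LD (r^2) to the lead — the input
    for a co-localization scatter plus two regional tracks.
    """
    try:
        jl = G.index_of(lead_id)
    except KeyError as exc:
        raise ValueError(f"lead variant {lead_id!r} absent from LD "
                         "source") from exc
    lead = G.variants.iloc[jl]
    idx = G.region_index(lead["chrom"], lead["pos"] - window_bp,
                         lead["pos"] + window_bp)
    window_ids = set(G.variants.iloc[idx]["id"])
    epi = interaction_records.copy()
    # map each pair to its varying member (the scan anchor is constant)
    if epi["ID_A"].nunique() == 1:
        epi["ID"] = epi["ID_B"]
    elif epi["ID_B"].nunique() == 1:
        epi["ID"] = epi["ID_A"]
    else:
        epi["ID"] = np.where(epi["ID_A"] == lead_id, epi["ID_B"],
                             epi["ID_A"])
    epi_p = epi.set_index("ID")["P"]
    v = vqtl_records.set_index("ID")
    shared = [i for i in v.index if i in epi_p.index and i in window_ids]
    rows = []
    for vid in shared:
        rows.append({
            "ID": vid,
            "CHR": v.at[vid, "CHR"], "POS": v.at[vid, "POS"],
            "NEGLOG10P_VQTL": -np.log10(v.at[vid, "P"]),
            "NEGLOG10P_INT": -np.log10(epi_p[vid]),
            "R2_LEAD": 1.0 if vid == lead_id
            else ld_r2(G, jl, G.index_of(vid)),
        })
    return pd.DataFrame(
        rows, columns=["ID", "CHR", "POS", "NEGLOG10P_VQTL",
                       "NEGLOG10P_INT", "R2_LEAD"])


def sensitivity_drop_extreme(y: np.ndarray,
                             tests: Mapping[str, Callable[[np.ndarray], float]]
                             ) -> pd.DataFrame:
    """Re-run a battery of tests after dropping the most extreme residual.

    Each callable maps an index array (rows to analyze) to a p-value.
    The single observation with the largest |y| (y being the residual
    trait) is removed and every test is run before and after.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 30:
        raise ValueError("need N >= 30")
    full = np.arange(y.size)
    drop = int(np.nanargmax(np.abs(y)))
    reduced = np.delete(full, drop)
    rows = []
    for name, fn in tests.items():
        rows.append({"TEST": name, "P_BEFORE": fn(full),
                     "P_AFTER": fn(reduced), "N_BEFORE": full.size,
                     "N_AFTER": reduced.size, "DROPPED_INDEX": drop})
    return pd.DataFrame(rows)
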