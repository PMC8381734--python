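"""Genome-wide variance-QTL scanning with the median-based Levene test.

The Brown-Forsythe form of Levene's test compares group means of the
absolute deviations z_ij = |y_ij - median_j| across genotype groups with
an F statistic

    W = ((N - K) / (K - 1)) * sum_g n_g (zbar_g - zbar)^2
        / sum_g sum_j (z_ij - zbar_g)^2

on (K - 1, N - K) degrees of freedom.  The median centre makes the test
robust to non-normal residuals and outliers, which is what justifies its
use as a genome-wide variance screen.

Sparse genotype groups (below ``min_group``) are excluded, not merged,
and K recomputed; a degenerate zero-within-deviation fit is reported with
a flag rather than dropped so that scan counts reconcile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GenotypeMatrix
from .preprocess import ResidualTrait

log = logging.getLogger(__name__)

__all__ = ["VqtlRecord", "ScanResult", "InsufficientGroupsError",
           "levene_median_test", "vqtl_scan", "genomic_lambda",
           "empirical_type1", "qq_manhattan_tables",
           "CHI2_1_MEDIAN"]

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

SUGGESTIVE_P: float = 5e-7
GENOMEWIDE_P: float = 5e-8


class InsufficientGroupsError(ValueError):
    """Fewer than two genotype groups meet the group-size minimum."""


@dataclass
class VqtlRecord:
    """One median-based Levene test result."""

    n: int
    k: int
    group_sizes: dict[int, int]
    group_medians: dict[int, float]
    w: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False
    variant_id: str | None = None
    chrom: str | None = None
    pos: int | None = None
    maf: float | None = None

    def size_of(self, dose: int) -> int:
        return self.group_sizes.get(dose, 0)


@dataclass
class ScanResult:
    """A scan table plus the per-variant skip log."""

    table: pd.DataFrame
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)


def levene_median_test(y: np.ndarray, g: np.ndarray,
                       min_group: int = 5) -> VqtlRecord:
    """Median-based Levene (Brown-Forsythe) test of y across dosage groups.

    Pairs with a missing value in either vector are dropped; groups with
    fewer than ``min_group`` members are excluded (K recomputed).  Raises
    :class:`InsufficientGroupsError` when fewer than two groups remain.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    values = np.unique(g)
    groups = [y[g == v] for v in values]
    keep = [i for i, arr in enumerate(groups) if arr.size >= min_group]
    if len(keep) < 2:
        raise InsufficientGroupsError(
            f"only {len(keep)} genotype group(s) with n >= {min_group}")
    groups = [groups[i] for i in keep]
    values = values[keep]
    n = sum(arr.size for arr in groups)
    k = len(groups)
    medians = [float(np.median(arr)) for arr in groups]
    z = [np.abs(arr - med) for arr, med in zip(groups, medians)]
    zbar_g = np.array([arr.mean() for arr in z])
    n_g = np.array([arr.size for arr in z], dtype=float)
    zbar = float(np.sum(n_g * zbar_g) / n)
    ss_between = float(np.sum(n_g * (zbar_g - zbar) ** 2))
    ss_within = float(sum(np.sum((arr - m) ** 2)
                          for arr, m in zip(z, zbar_g)))
    df1, df2 = k - 1, n - k
    degenerate = False
    if ss_within == 0.0:
        if ss_between == 0.0:
            w, p = 0.0, 1.0
        else:
            w, p, degenerate = float("inf"), 0.0, True
    else:
        w = (df2 / df1) * ss_between / ss_within
        p = float(stats.f.sf(w, df1, df2))
    return VqtlRecord(
        n=n, k=k,
        group_sizes={int(v): int(s) for v, s in zip(values, n_g)},
        group_medians={int(v): m for v, m in zip(values, medians)},
        w=w, df1=df1, df2=df2, p=p, degenerate=degenerate)


def _align(G: GenotypeMatrix, y: ResidualTrait | pd.Series | np.ndarray
           ) -> np.ndarray:
    """Trait vector aligned to G.samples (NaN for absent samples)."""
    if isinstance(y, ResidualTrait):
        y = y.series()
    if isinstance(y, pd.Series):
        aligned = y.reindex(G.samples)
        if aligned.notna().sum() == 0:
            raise ValueError("no overlapping samples between genotypes "
                             "and phenotype")
        return aligned.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size != G.n_samples:
        raise ValueError("phenotype length does not match sample count")
    return y


def vqtl_scan(G: GenotypeMatrix, y: ResidualTrait | pd.Series | np.ndarray,
              min_group: int = 5, suggestive: float = SUGGESTIVE_P,
              genomewide: float = GENOMEWIDE_P) -> ScanResult:
    """Median-based Levene test for every testable variant in ``G``.

    Returns one record per testable variant with suggestive/significant
    flags, plus a skip log with one reason per untestable variant.
    """
    yv = _align(G, y)
    maf = G.maf()
    rows, skipped = [], []
    for j in range(G.n_variants):
        var = G.variants.iloc[j]
        try:
            rec = levene_median_test(yv, G.dosage(j), min_group=min_group)
        except InsufficientGroupsError as exc:
            skipped.append({"ID": var["id"], "REASON": str(exc)})
            continue
        rows.append({
            "CHR": var["chrom"], "POS": var["pos"], "ID": var["id"],
            "REF": var["ref"], "ALT": var["alt"], "MAF": maf[j],
            "N": rec.n, "K": rec.k, "N0": rec.size_of(0),
            "N1": rec.size_of(1), "N2": rec.size_of(2), "W": rec.w,
            "DF1": rec.df1, "DF2": rec.df2, "P": rec.p,
            "DEGENERATE": rec.degenerate,
            "SUGGESTIVE": rec.p < suggestive,
            "SIGNIFICANT": rec.p < genomewide,
        })
    table = pd.DataFrame(rows)
    return ScanResult(table=table, skipped=pd.DataFrame(skipped))


def genomic_lambda(p_values: np.ndarray, min_count: int = 100) -> float:
    """Genomic inflation factor: the median association chi-square over
    the null chi-square median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < min_count:
        raise ValueError(f"need >= {min_count} p-values, got {p.size}")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def empirical_type1(G: GenotypeMatrix, y, threshold: float,
                    n_perm: int, seed: int,
                    min_group: int = 5) -> np.ndarray:
    """Counts of p < threshold per phenotype permutation (full rescans).

    The phenotype is shuffled without replacement per replicate, so any
    count in excess of the binomial expectation reflects miscalibration,
    not signal.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    yv = _align(G, y)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        perm = rng.permutation(yv)
        res = vqtl_scan(G, perm, min_group=min_group)
        counts[r] = int((res.table["P"] < threshold).sum()) \
            if len(res.table) else 0
    return counts


def qq_manhattan_tables(records: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready QQ and Manhattan tables from a scan table.

    QQ: expected -log10 quantiles (i - 0.5)/n against the observed
    -log10 p sorted descending.  Manhattan: cumulative genome coordinate
    per chromosome plus -log10 p.
    """
    n = len(records)
    obs = np.sort(-np.log10(records["P"].to_numpy(dtype=float)))[::-1]
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"EXPECTED": exp, "OBSERVED": obs})
    man = records[["CHR", "POS", "ID", "P"]].copy()
    offset, offsets = 0, {}
    for chrom, grp in man.groupby("CHR", sort=False):
        offsets[chrom] = offset
        offset += int(grp["POS"].max()) + 1
    man["GPOS"] = man.apply(lambda r: r["POS"] + offsets[r["CHR"]], axis=1)
    man["NEGLOG10P"] = -np.log10(man["P"].to_numpy(dtype=float))
    return qq, man
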