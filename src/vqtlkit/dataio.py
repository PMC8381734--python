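"""Reading and writing of the standard formats the pipeline touches.

All parsing lives here: VCF genotypes (via cyvcf2), phenotype/covariate
TSV tables, 2D landmark CSV files, and the fixed tab-separated result
schemas written by the scans.  Internally genotypes are hard-call dosage
matrices (samples x variants) with ``MISSING`` (-1) as the missing
sentinel; VCF positions are 1-based and region queries are closed
intervals in bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: missing-dosage sentinel in ``GenotypeMatrix.calls``
MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

#: fixed column orders for the tab-separated result files
RESULT_SCHEMAS: dict[str, list[str]] = {
    "vqtl": ["CHR", "POS", "ID", "REF", "ALT", "MAF", "N", "K",
             "N0", "N1", "N2", "W", "DF1", "DF2", "P"],
    "epi": ["ID_A", "ID_B", "N", "BETA_A", "BETA_B", "BETA_INT",
            "SE_INT", "COV_TYPE", "STAT", "DF", "P"],
    "strata": ["STRATUM_GENO", "N", "BETA_B", "SE", "P"],
}

_P_COLUMNS = {"P", "MAF", "W", "BETA_A", "BETA_B", "BETA_INT", "SE_INT",
              "STAT", "SE"}


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Hard-call dosage matrix with per-variant metadata.

    Attributes
    ----------
    samples:
        Ordered sample identifiers (length N).
    variants:
        DataFrame with columns ``chrom, pos, id, ref, alt`` (one row per
        variant, M rows); positions are 1-based and non-decreasing within
        a chromosome.
    calls:
        ``(N, M)`` integer array with entries in ``{0, 1, 2, MISSING}``.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        if self.calls.shape[0] != len(self.samples):
            raise ValueError(
                f"sample count {len(self.samples)} does not match matrix "
                f"row count {self.calls.shape[0]}")
        if self.calls.shape[1] != len(self.variants):
            raise ValueError("variant count does not match matrix columns")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or MISSING")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def index_of(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(idx[0])

    def dosage(self, variant: int | str) -> np.ndarray:
        """Dosage vector as float with NaN at missing calls."""
        j = variant if isinstance(variant, (int, np.integer)) \
            else self.index_of(variant)
        d = self.calls[:, j].astype(float)
        d[d == MISSING] = np.nan
        return d

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency from non-missing calls."""
        calls = self.calls
        ok = calls != MISSING
        n_ok = ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_ok > 0, alt / (2.0 * n_ok), np.nan)
        return np.minimum(p, 1.0 - p)

    # -- subsetting -----------------------------------------------------
    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(self.samples,
                              self.variants.iloc[idx].reset_index(drop=True),
                              self.calls[:, idx])

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix([self.samples[i] for i in idx],
                              self.variants.copy(), self.calls[idx, :])

    def region_index(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of variants in the closed interval [start, end] bp."""
        v = self.variants
        mask = (v["chrom"].astype(str) == str(chrom)) & \
            (v["pos"] >= start) & (v["pos"] <= end)
        return np.flatnonzero(mask.to_numpy())


@dataclass
class PhenotypeTable:
    """Trait and covariate columns, one row per sample.

    ``table`` is indexed by unique sample id.  ``complete`` marks rows
    with no missing value among trait + covariates.
    """

    table: pd.DataFrame
    trait: str | None = None
    covariates: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample id(s): {dups}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def complete(self) -> np.ndarray:
        cols = ([self.trait] if self.trait else []) + list(self.covariates)
        if not cols:
            return np.ones(len(self.table), dtype=bool)
        return self.table[cols].notna().all(axis=1).to_numpy()

    def trait_values(self) -> np.ndarray:
        return self.table[self.trait].to_numpy(dtype=float)


@dataclass
class LandmarkTable:
    """A collection of fixed-k 2D landmark configurations.

    coords has shape ``(n_specimens, k, 2)``; ``dose`` holds the genotype
    dose in {0,1,2}; ``litter`` the litter label per specimen.
    """

    specimens: list[str]
    litters: list[str]
    doses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.doses = np.asarray(self.doses, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n, k, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, min_maf: float = 0.0,
             region: str | None = None,
             ds_uncertainty: float = 0.1) -> GenotypeMatrix:
    """Read biallelic SNP hard calls from a VCF 4.x file.

    GT is used when present; otherwise DS dosages are hard-called by
    rounding to the nearest integer (ties round up).  Multiallelic or
    non-SNP records are skipped (with a logged count), and variants with
    MAF below ``min_maf`` (computed from non-missing calls) are dropped.

    ``region`` is an optional ``chrom:start-end`` closed interval.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom_q = start_q = end_q = None
    if region is not None:
        chrom_q, span = region.split(":")
        start_q, end_q = (int(x) for x in span.split("-"))

    rows, columns, uncertain = [], [], []
    n_skipped = 0
    for i, v in enumerate(vcf):
        try:
            alts = v.ALT
            if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            if chrom_q is not None and (
                    str(v.CHROM) != chrom_q or not start_q <= v.POS <= end_q):
                continue
            gts = v.gt_types  # gts012: 0,1,2 dosage; 3 = unknown
            if (gts == 3).all():
                try:
                    ds = v.format("DS")
                except KeyError:  # DS not declared in the header
                    ds = None
                if ds is None:
                    dose = np.full(len(samples), MISSING, dtype=np.int16)
                    uncertain.append(False)
                else:
                    ds = np.asarray(ds, dtype=float).reshape(-1)
                    dose = np.floor(ds + 0.5).astype(np.int16)  # ties up
                    dose = np.clip(dose, 0, 2)
                    dose[~np.isfinite(ds)] = MISSING
                    if np.nanmean(np.abs(ds - np.floor(ds + 0.5))) > ds_uncertainty:
                        uncertain.append(True)
                    else:
                        uncertain.append(False)
            else:
                dose = gts.astype(np.int16)
                dose[dose == 3] = MISSING
                uncertain.append(False)
            rows.append((str(v.CHROM), int(v.POS),
                         v.ID or f"{v.CHROM}:{v.POS}", v.REF, alts[0]))
            columns.append(dose)
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfParseError(f"malformed VCF record #{i + 1}: {exc}") from exc
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)

    if not rows:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
        calls = np.zeros((len(samples), 0), dtype=np.int16)
    else:
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        calls = np.column_stack(columns).astype(np.int16)
    variants["ds_uncertain"] = pd.Series(uncertain, dtype=bool) \
        if uncertain else False
    G = GenotypeMatrix(samples, variants, calls)
    if min_maf > 0 and G.n_variants:
        keep = np.flatnonzero(G.maf() >= min_maf)
        n_drop = G.n_variants - keep.size
        if n_drop:
            log.info("read_vcf: dropped %d variants with MAF < %g",
                     n_drop, min_maf)
        G = G.take_variants(keep)
    return G


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write hard calls as a minimal plain-text VCF 4.2 (GT only)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(G.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for j, var in G.variants.iterrows():
            gts = "\t".join(gt_map[int(c)] for c in G.calls[:, j])
            fh.write(f"{var['chrom']}\t{var['pos']}\t{var['id']}\t"
                     f"{var['ref']}\t{var['alt']}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path, trait: str | None = None,
                    covariates: Sequence[str] | None = None,
                    id_col: str | None = None) -> PhenotypeTable:
    """Read a phenotype/covariate TSV with a header and one id column.

    ``age2`` may be requested as a covariate even when only ``age`` is
    present; it is then derived as age squared.
    """
    df = pd.read_csv(path, sep="\t")
    if id_col is None:
        id_col = df.columns[0]
    if id_col not in df.columns:
        raise ValueError(f"id column {id_col!r} not in {list(df.columns)}")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    covariates = list(covariates or [])
    if "age2" in covariates and "age2" not in df.columns:
        if "age" not in df.columns:
            raise ValueError("cannot derive age2: no 'age' column")
        df["age2"] = df["age"] ** 2
    requested = ([trait] if trait else []) + covariates
    missing_cols = [c for c in requested if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"column(s) {missing_cols} not found; available: "
            f"{sorted(df.columns)}")
    return PhenotypeTable(df, trait=trait, covariates=covariates)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path,
                     id_col: str = "sample") -> None:
    pheno.table.rename_axis(id_col).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> LandmarkTable:
    """Read a landmark CSV: specimen,litter,genotype,lm1_x,lm1_y,..."""
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c.startswith("lm")]
    k = len(coord_cols) // 2
    coords = df[coord_cols].to_numpy(dtype=float).reshape(len(df), k, 2)
    return LandmarkTable(df["specimen"].astype(str).tolist(),
                         df["litter"].astype(str).tolist(),
                         df["genotype"].to_numpy(int), coords)


def write_landmarks(lm: LandmarkTable, path: str | Path) -> None:
    k = lm.k
    cols = {}
    for i in range(k):
        cols[f"lm{i + 1}_x"] = lm.coords[:, i, 0]
        cols[f"lm{i + 1}_y"] = lm.coords[:, i, 1]
    out = pd.DataFrame({"specimen": lm.specimens, "litter": lm.litters,
                        "genotype": lm.doses, **cols})
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(records: pd.DataFrame, path: str | Path,
                  schema: str) -> None:
    """Write a result table in one of the fixed tab-separated schemas.

    Floating-point statistic/p-value columns are written in scientific
    notation with 6 significant digits after the leading digit, so a
    re-read reproduces values to at least 6 significant figures.
    """
    if schema not in RESULT_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; "
                         f"one of {sorted(RESULT_SCHEMAS)}")
    cols = RESULT_SCHEMAS[schema]
    if len(records) == 0:
        out = pd.DataFrame(columns=cols)
    else:
        out = pd.DataFrame({c: records[c] if c in records.columns else np.nan
                            for c in cols})
    for c in cols:
        if c in _P_COLUMNS:
            out[c] = out[c].map(
                lambda x: "NA" if pd.isna(x) else f"{x:.6e}")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
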