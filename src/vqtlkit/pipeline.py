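"""Orchestration of the discovery -> decomposition -> replication-threshold
workflow as one reproducible run.

``run_discovery`` chains covariate residualization, MAF filtering, the
genome-wide variance scan, and — for each suggestive anchor — the
anchored interaction scan (with the robust-SE policy), stratified
effects, stratified variance scans with and without downsampling,
co-localization tables, the extreme-observation sensitivity re-run and
gene-by-environment tests, writing all result TSVs plus a JSON report.
``run_replication_thresholds`` computes eigenvalue-based effective-test
counts per region and the product-rule Bonferroni thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataio import (GenotypeMatrix, PhenotypeTable, read_phenotypes,
                     read_vcf, write_results)
from .epistasis import (colocalize_table, gxe_tests, scan_partner,
                        sensitivity_drop_extreme, stratified_effects,
                        stratified_vqtl)
from .multtest import MeffResult, bonferroni_threshold, meff_li_ji, \
    select_proxies
from .preprocess import maf_filter, residualize
from .simulate import SimConfig, simulate_genotypes, simulate_phenotype
from .vqtl import levene_median_test, vqtl_scan

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_replication_thresholds"]


@dataclass
class RunConfig:
    """One reproducible discovery run.

    Inputs are either file paths (``vcf``/``pheno``) or a ``sim``
    generative configuration for a self-generated cohort.
    """

    vcf: str | None = None
    pheno: str | None = None
    sim: SimConfig | None = None
    trait: str = "y"
    covariates: list[str] = field(default_factory=list)
    exposures: list[str] = field(default_factory=list)
    min_maf: float = 0.2
    suggestive: float = 5e-7
    genomewide: float = 5e-8
    min_group: int = 5
    robust_policy: str = "auto"
    cov_type: str = "HC3"
    lambda_threshold: float = 1.05
    window_kb: float = 500.0
    anchors: list[str] | None = None   # override automatic anchor selection
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.suggestive, self.genomewide):
            if not 0 < t < 1:
                raise ValueError("significance thresholds must be in (0,1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sim" in raw and raw["sim"] is not None:
            from .simulate import Block
            sim = dict(raw["sim"])
            sim["blocks"] = [Block(**b) for b in sim.get("blocks", [])]
            raw["sim"] = SimConfig(**sim)
        return cls(**raw)


def _load_inputs(config: RunConfig
                 ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    if config.sim is not None:
        G = simulate_genotypes(config.sim)
        pheno = simulate_phenotype(G, config.sim)
        return G, pheno
    if config.vcf is None or config.pheno is None:
        raise ValueError("either sim or both vcf and pheno must be given")
    G = read_vcf(config.vcf)
    pheno = read_phenotypes(config.pheno, trait=config.trait,
                            covariates=config.covariates)
    return G, pheno


def run_discovery(config: RunConfig, out_dir: str | Path | None = None
                  ) -> dict:
    """Execute the full discovery workflow; returns the JSON-able report."""
    G, pheno = _load_inputs(config)
    covs = config.covariates if config.sim is None else \
        (config.covariates or [])
    resid = residualize(pheno, trait=config.trait or pheno.trait,
                        covariates=covs)
    G = maf_filter(G, config.min_maf)
    scan = vqtl_scan(G, resid, min_group=config.min_group,
                     suggestive=config.suggestive,
                     genomewide=config.genomewide)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": G.n_samples,
        "n_variants": G.n_variants,
        "n_tested": int(len(scan.table)),
        "n_skipped": int(len(scan.skipped)),
        "n_suggestive": int(scan.table["SUGGESTIVE"].sum())
        if len(scan.table) else 0,
        "n_genomewide": int(scan.table["SIGNIFICANT"].sum())
        if len(scan.table) else 0,
        "anchors": {},
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_results(scan.table, out / "vqtl.tsv", "vqtl")
    if config.anchors is not None:
        anchor_ids = list(config.anchors)
    elif len(scan.table):
        anchor_ids = scan.table.loc[scan.table["SUGGESTIVE"], "ID"].tolist()
    else:
        anchor_ids = []
    if not anchor_ids:
        report["note"] = "no suggestive anchors; stopped after the scan"
        if out is not None:
            (out / "report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True))
        return report
    yv = resid.series().reindex(G.samples).to_numpy(dtype=float)
    window_bp = int(config.window_kb * 1000)
    for anchor_id in anchor_ids:
        ja = G.index_of(anchor_id)
        gA = G.dosage(ja)
        epi, diag = scan_partner(
            G, resid, anchor_id, robust_policy=config.robust_policy,
            cov_type=config.cov_type,
            lambda_threshold=config.lambda_threshold,
            genomewide=config.genomewide)
        top = epi.sort_values("P").iloc[0] if len(epi) else None
        entry: dict = {
            "lambda_model": diag["lambda_model"],
            "lambda_robust": diag["lambda_robust"],
            "cov_type_used": diag["cov_type_used"],
            "n_pairs": int(len(epi)),
            "top_pair": None,
        }
        if top is not None:
            gB = G.dosage(str(top["ID_B"]))
            entry["top_pair"] = {"id_b": str(top["ID_B"]),
                                 "beta_int": float(top["BETA_INT"]),
                                 "p": float(top["P"])}
            strata = stratified_effects(yv, gA, gB)
            sv = stratified_vqtl(G, resid, gB, downsample=False)
            sv_ds = stratified_vqtl(G, resid, gB, downsample=True,
                                    seed=config.seed)
            entry["stratified_vqtl_p"] = {
                str(a): (float(res.table.set_index("ID")["P"][anchor_id])
                         if anchor_id in set(res.table["ID"]) else None)
                for a, res in sv.items()}
            entry["stratified_vqtl_downsampled_p"] = {
                str(a): (float(res.table.set_index("ID")["P"][anchor_id])
                         if anchor_id in set(res.table["ID"]) else None)
                for a, res in sv_ds.items()}
            coloc = colocalize_table(scan.table, epi, anchor_id, G,
                                     window_bp=window_bp)
            sens = sensitivity_drop_extreme(yv, {
                "levene_anchor": lambda idx, _g=gA: levene_median_test(
                    yv[idx], _g[idx], min_group=config.min_group).p,
            })
            entry["sensitivity"] = sens.to_dict(orient="records")
            if out is not None:
                tag = anchor_id
                write_results(epi, out / f"epi_{tag}.tsv", "epi")
                write_results(strata, out / f"strata_{tag}.tsv", "strata")
                coloc.to_csv(out / f"coloc_{tag}.tsv", sep="\t",
                             index=False)
        entry["gxe"] = {}
        for expo in config.exposures:
            E = pheno.table[expo].reindex(G.samples).to_numpy(dtype=float)
            rec1, rec2 = gxe_tests(yv, gA, E, cov_type=config.cov_type)
            entry["gxe"][expo] = {"p_1df": rec1.p, "p_2df": rec2["p"]}
        report["anchors"][anchor_id] = entry
    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def run_replication_thresholds(alpha: float = 0.05,
                               ld_source: GenotypeMatrix | None = None,
                               regions: list[str] | None = None,
                               meff_values: list[int] | None = None,
                               proxy_targets: list[str] | None = None,
                               min_r2: float = 0.8) -> dict:
    """Effective-test counts per region and product-rule thresholds.

    ``meff_values`` may be supplied directly (e.g. previously published
    counts); otherwise each ``chrom:start-end`` region of ``ld_source``
    is decomposed.  The single-locus threshold divides alpha by the first
    region's Meff; the pair threshold by the product of all of them.
    """
    meffs: list[MeffResult | int] = []
    details = []
    if meff_values is not None:
        meffs = [int(v) for v in meff_values]
        details = [{"meff": int(v)} for v in meff_values]
    else:
        if ld_source is None or not regions:
            raise ValueError("need either meff_values or ld_source+regions")
        for region in regions:
            chrom, span = region.split(":")
            start, end = (int(x) for x in span.split("-"))
            idx = ld_source.region_index(chrom, start, end)
            if idx.size < 2:
                raise ValueError(f"region {region} has < 2 variants")
            res = meff_li_ji(ld_source.take_variants(idx))
            meffs.append(res)
            details.append({"region": region, "m": res.m,
                            "meff_real": res.meff, "meff": res.meff_int})
    report = {
        "alpha": alpha,
        "regions": details,
        "single_locus_threshold": bonferroni_threshold(alpha, meffs[:1]),
        "pair_threshold": bonferroni_threshold(alpha, meffs),
    }
    if proxy_targets and ld_source is not None:
        report["proxies"] = {
            t: select_proxies(ld_source, t, min_r2=min_r2)
            .to_dict(orient="records") for t in proxy_targets}
    return report
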