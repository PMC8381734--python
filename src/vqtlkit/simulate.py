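"""Synthetic genotypes, phenotypes and landmark data.

The generator emulates the statistical structure that the analysis
modules assume: unrelated individuals, common SNPs arranged in LD blocks
(latent-Gaussian threshold model with AR(1) within-block correlation), a
quantitative trait with covariates and a two-locus interaction able to
induce variance heterogeneity at the anchor locus, direct (multiplicative)
variance effects, a gene-by-environment effect, injected outliers, and
6-landmark 2D cranial configurations with a genotype-dose width effect and
litter structure.  Closed-form moment oracles for the interaction
architecture live here too.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GenotypeMatrix, LandmarkTable, PhenotypeTable, VARIANT_COLUMNS

__all__ = [
    "Block", "SimConfig", "simulate_genotypes", "simulate_covariates",
    "simulate_phenotype", "theoretical_moments", "inject_outliers",
    "simulate_landmarks", "landmark_template", "config_interaction",
    "config_pure_vqtl", "config_null",
]

#: spacing in bp between adjacent SNPs within a block, and between blocks
_SNP_SPACING = 5_000
_BLOCK_SPACING = 2_000_000


@dataclass
class Block:
    """An LD block: ``n_snps`` SNPs with AR(1) latent correlation ``rho``.

    ``maf`` is a single frequency for every SNP, a (low, high) range
    sampled uniformly per SNP, or an explicit per-SNP sequence.
    """

    n_snps: int
    maf: float | tuple[float, float] | Sequence[float] = 0.3
    rho: float = 0.0

    def resolve_mafs(self, rng: np.random.Generator) -> np.ndarray:
        """Per-SNP frequencies; a length-2 array that does not match
        ``n_snps`` is a (low, high) sampling range."""
        if np.isscalar(self.maf):
            mafs = np.full(self.n_snps, float(self.maf))
        else:
            arr = np.asarray(self.maf, dtype=float)
            if arr.shape == (self.n_snps,):
                mafs = arr
            elif arr.shape == (2,):
                mafs = rng.uniform(arr[0], arr[1], self.n_snps)
            else:
                raise ValueError("maf must be scalar, a (low, high) range "
                                 "or one value per SNP")
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")
        return mafs

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("block must contain at least one SNP")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("within-block correlation rho must be in [0, 1)")
        if np.isscalar(self.maf):
            if not 0.0 < float(self.maf) <= 0.5:
                raise ValueError("maf must lie in (0, 0.5]")


@dataclass
class SimConfig:
    """Generative configuration for one synthetic cohort.

    The trait model is::

        y_i = mu + sum_c gamma_c x_ic + beta_a g_iA + beta_b g_iB
              + beta_ab g_iA g_iB + beta_e g_iA E_i + eps_i,
        eps_i ~ Normal(0, (sigma0 * kappa**g_iA)^2)

    so ``kappa`` is a scale-free per-anchor-allele multiplier on the
    residual SD (kappa = 1 means homoscedastic residuals) and ``beta_ab``
    is the two-locus interaction that induces variance heterogeneity at
    the anchor when the partner is unobserved.
    """

    n_samples: int
    blocks: list[Block]
    anchor: int = 0
    partner: int = 1
    mu: float = 0.0
    beta_a: float = 0.0
    beta_b: float = 0.0
    beta_ab: float = 0.0
    beta_e: float = 0.0
    gamma: dict[str, float] = field(default_factory=dict)
    sigma0: float = 1.0
    kappa: float = 1.0
    n_outliers: int = 0
    outlier_mag: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.blocks:
            raise ValueError("at least one block is required")
        for b in self.blocks:
            b.validate()
        m = sum(b.n_snps for b in self.blocks)
        if not (0 <= self.anchor < m and 0 <= self.partner < m):
            raise ValueError("anchor/partner index out of range")
        if self.anchor == self.partner:
            raise ValueError("anchor and partner must differ")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.kappa < 1:
            raise ValueError("variance ratio kappa must be >= 1")

    def block_of(self, snp_index: int) -> int:
        off = 0
        for i, b in enumerate(self.blocks):
            if snp_index < off + b.n_snps:
                return i
            off += b.n_snps
        raise IndexError(snp_index)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per purpose, all derived from seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw hard-call genotypes under the latent-Gaussian threshold model.

    Per haplotype and block a latent vector with AR(1) covariance
    ``rho**|i-j|`` is drawn and allele = 1 iff latent < Phi^-1(maf); the
    genotype is the sum of two independent haplotypes.  Blocks are
    mutually independent.  Realized allelic correlation is attenuated
    relative to the latent rho, so LD is calibrated qualitatively
    (monotone decay), not numerically.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_samples
    cols, rows = [], []
    global_idx = 0
    for bi, block in enumerate(config.blocks):
        mafs = block.resolve_mafs(rng)
        L = block.n_snps
        thresholds = stats.norm.ppf(mafs)
        if block.rho > 0 and L > 1:
            lag = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
            chol = np.linalg.cholesky(block.rho ** lag)
        else:
            chol = None
        g = np.zeros((n, L), dtype=np.int16)
        for _hap in range(2):
            z = rng.standard_normal((n, L))
            if chol is not None:
                z = z @ chol.T
            g += (z < thresholds).astype(np.int16)
        cols.append(g)
        base = bi * _BLOCK_SPACING + 1
        for j in range(L):
            rows.append(("1", base + j * _SNP_SPACING,
                         f"snp{global_idx:05d}", "A", "G"))
            global_idx += 1
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(
        [f"id{i:06d}" for i in range(n)], variants, np.hstack(cols))


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort-style covariates: age U(3,49), sex Bernoulli(0.62),
    height/weight/size Gaussian, and a standard-normal exposure E."""
    age = rng.uniform(3.0, 49.0, n)
    return pd.DataFrame({
        "age": age,
        "age2": age ** 2,
        "sex": rng.binomial(1, 0.62, n).astype(float),
        "height": rng.normal(165.0, 10.0, n),
        "weight": rng.normal(65.0, 12.0, n),
        "size": rng.normal(0.0, 1.0, n),
        "E": rng.standard_normal(n),
    })


def simulate_phenotype(G: GenotypeMatrix, config: SimConfig,
                       covariate_spec: Sequence[str] | None = None
                       ) -> PhenotypeTable:
    """Simulate the quantitative trait ``y`` for the samples of ``G``.

    Covariate draws use an independent stream from the genotype draws, so
    the phenotype given G is reproducible from the config seed alone.
    """
    config.validate()
    rng = _rng(config, 1)
    n = G.n_samples
    cov = simulate_covariates(n, rng)
    gA = G.calls[:, config.anchor].astype(float)
    gB = G.calls[:, config.partner].astype(float)
    y = np.full(n, config.mu, dtype=float)
    for name, coef in config.gamma.items():
        y += coef * cov[name].to_numpy()
    y += config.beta_a * gA + config.beta_b * gB + config.beta_ab * gA * gB
    y += config.beta_e * gA * cov["E"].to_numpy()
    sd = config.sigma0 * config.kappa ** gA
    y += rng.standard_normal(n) * sd
    table = cov.copy()
    table.insert(0, "y", y)
    table.index = pd.Index(G.samples, name="sample")
    keep = ["y"] + list(covariate_spec if covariate_spec is not None
                        else cov.columns)
    return PhenotypeTable(table[keep], trait="y",
                          covariates=[c for c in keep if c != "y"],
                          provenance={"seed": config.seed})


def theoretical_moments(config: SimConfig, a: int) -> tuple[float, float]:
    """Closed-form E[y | g_A = a] and Var[y | g_A = a].

    Valid only for independent anchor/partner loci (different blocks),
    homoscedastic residuals (kappa = 1), no G x E effect and no covariate
    effects, where

        E[y|a]   = mu + beta_a a + (beta_b + beta_ab a) * 2 p_B
        Var[y|a] = (beta_b + beta_ab a)^2 * 2 p_B (1 - p_B) + sigma0^2
    """
    config.validate()
    if config.kappa != 1 or config.beta_e != 0:
        raise ValueError("theoretical_moments requires kappa = 1 and "
                         "beta_e = 0")
    if any(v != 0 for v in config.gamma.values()):
        raise ValueError("theoretical_moments requires zero covariate "
                         "coefficients")
    if config.block_of(config.anchor) == config.block_of(config.partner):
        raise ValueError("anchor and partner must be in independent blocks")
    bi = config.block_of(config.partner)
    block = config.blocks[bi]
    if np.isscalar(block.maf):
        p_b = float(block.maf)
    else:
        arr = np.asarray(block.maf, dtype=float)
        if arr.shape != (block.n_snps,):
            raise ValueError("partner block maf must be scalar or an "
                             "explicit per-SNP sequence")
        offset = sum(b.n_snps for b in config.blocks[:bi])
        p_b = float(arr[config.partner - offset])
    slope = config.beta_b + config.beta_ab * a
    mean = config.mu + config.beta_a * a + slope * 2.0 * p_b
    var = slope ** 2 * 2.0 * p_b * (1.0 - p_b) + config.sigma0 ** 2
    return mean, var


def inject_outliers(pheno: PhenotypeTable, k_out: int, m: float,
                    seed: int) -> PhenotypeTable:
    """Replace ``k_out`` random trait values by value + m * SD(trait).

    The perturbed row positions are recorded in the returned table's
    provenance metadata.
    """
    if k_out < 0 or k_out >= len(pheno.table):
        raise ValueError("k_out must satisfy 0 <= k_out < N")
    rng = np.random.default_rng(seed)
    table = pheno.table.copy()
    idx = np.sort(rng.choice(len(table), size=k_out, replace=False))
    if k_out:
        sd = float(np.nanstd(table[pheno.trait].to_numpy(dtype=float)))
        table.iloc[idx, table.columns.get_loc(pheno.trait)] += m * sd
    prov = dict(pheno.provenance)
    prov["outlier_rows"] = idx.tolist()
    prov["outlier_mag_sd"] = m
    return PhenotypeTable(table, trait=pheno.trait,
                          covariates=list(pheno.covariates), provenance=prov)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

#: 6-landmark cranial template: eyes, ears, anterior and posterior midline
TEMPLATE = np.array([
    [-0.30, 0.30], [0.30, 0.30],    # eyes (left, right)
    [-0.45, -0.20], [0.45, -0.20],  # ears
    [0.00, 0.55],                   # anterior midline
    [0.00, -0.55],                  # posterior midline
])
EYE_LANDMARKS = (0, 1)


def landmark_template(dose: int = 0, width_delta: float = 0.0) -> np.ndarray:
    """Template configuration with the eye separation widened by
    ``width_delta * dose`` (half on each side)."""
    shape = TEMPLATE.copy()
    shape[EYE_LANDMARKS[0], 0] -= width_delta * dose / 2.0
    shape[EYE_LANDMARKS[1], 0] += width_delta * dose / 2.0
    return shape


def simulate_landmarks(n_per_genotype: tuple[int, int, int] = (7, 10, 13),
                       width_delta: float = 0.0, noise_sd: float = 0.01,
                       litter_sd: float = 0.1, seed: int = 0,
                       n_litters: int = 6,
                       individual_scale_sd: float = 0.05) -> LandmarkTable:
    """Simulate 2D cranial configurations with a dose-dependent width.

    Each specimen is the dose-widened template put through a random
    similarity transform — rotation U(0, 2pi), log-normal scale with a
    litter-level size intercept (SD ``litter_sd`` on the log scale), and
    translation — followed by isotropic Gaussian landmark noise
    (``noise_sd``, post-transform units).  Specimens are assigned to
    litters round-robin after a seeded shuffle, so litters mix genotypes.
    """
    rng = np.random.default_rng(seed)
    doses = np.repeat([0, 1, 2], n_per_genotype)
    n = doses.size
    order = rng.permutation(n)
    litter_ids = np.empty(n, dtype=int)
    litter_ids[order] = np.arange(n) % n_litters
    litter_effect = rng.normal(0.0, litter_sd, n_litters)
    coords = np.empty((n, TEMPLATE.shape[0], 2))
    for i in range(n):
        shape = landmark_template(doses[i], width_delta)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        scale = np.exp(litter_effect[litter_ids[i]]
                       + rng.normal(0.0, individual_scale_sd))
        trans = rng.uniform(-1.0, 1.0, 2)
        x = shape @ rot.T * scale + trans
        coords[i] = x + rng.normal(0.0, noise_sd, shape.shape)
    return LandmarkTable([f"m{i:03d}" for i in range(n)],
                         [f"L{l}" for l in litter_ids], doses, coords)


# ---------------------------------------------------------------------------
# Canonical study scenarios
# ---------------------------------------------------------------------------

def _two_block_config(n_samples: int, m_partners: int, seed: int,
                      **effects) -> SimConfig:
    # anchor sits mid-block in a 10-SNP AR(0.8) block; the true partner is
    # the first SNP of an independent block of candidate partners
    anchor_block = Block(10, maf=0.25, rho=0.8)
    partner_mafs = np.full(m_partners, 0.5)
    if m_partners > 1:
        # spread the decoy partners over the common-variant range
        decoys = np.linspace(0.2, 0.5, m_partners - 1)
        partner_mafs[1:] = decoys
    partner_block = Block(m_partners, maf=tuple(partner_mafs), rho=0.0)
    return SimConfig(n_samples=n_samples, blocks=[anchor_block, partner_block],
                     anchor=4, partner=10, seed=seed, **effects)


def config_interaction(n_samples: int = 2447, m_partners: int = 2000,
                       beta_ab: float = 0.7, seed: int = 0) -> SimConfig:
    """Two-locus interaction scenario: the anchor has no direct variance
    effect; its variance heterogeneity is induced entirely by the
    interaction with the partner (p_B = 0.5)."""
    return _two_block_config(n_samples, m_partners, seed, beta_ab=beta_ab)


def config_pure_vqtl(n_samples: int = 2447, m_partners: int = 2000,
                     kappa: float = 1.3, seed: int = 0) -> SimConfig:
    """Direct variance effect at the anchor (residual SD multiplied by
    kappa per anchor allele) with no interaction anywhere."""
    return _two_block_config(n_samples, m_partners, seed, kappa=kappa)


def config_null(n_samples: int = 2447, m_snps: int = 2000,
                seed: int = 0) -> SimConfig:
    """No genetic effects at all: pure-noise trait."""
    return _two_block_config(n_samples, max(m_snps, 2), seed)
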