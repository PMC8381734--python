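# Methods

This note documents the statistical models vqtlkit implements, the
defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Variance scan (module `vqtl`)

Per SNP, samples are grouped by hard-call dosage {0, 1, 2} and the
median-based Levene (Brown–Forsythe) statistic is computed on the
covariate-adjusted residual trait:

    z_ij = |y_ij − median(group g)|,
    W = ((N − K)/(K − 1)) · Σ_g n_g (z̄_g − z̄)² / Σ_g Σ_j (z_ij − z̄_g)²,

referred to F(K − 1, N − K). The even-n group median is the mean of the
two middle order statistics. The median centre (rather than the mean)
buys robustness to skewness and outliers; the test's empirical size at
α = 0.05 stays within [0.045, 0.055] for Gaussian residuals and
[0.04, 0.065] for log-normal residuals at n = 500 (10,000 null
replicates; recomputed by `scripts/acceptance.py`).

Defaults and edge rules:

- `min_group = 5`: genotype groups smaller than this are *excluded*
  (never merged with another genotype class — a heterozygote group is
  biologically distinct from a homozygote group) and K is recomputed; a
  variant with fewer than two qualifying groups is skipped with a
  logged reason.
- A zero within-group deviation sum with non-zero between-group sum is
  reported as W = ∞, p = 0 with a `degenerate` flag instead of being
  dropped, so scan counts always reconcile.
- Flags: suggestive at p < 5×10⁻⁷ (the relaxed screen threshold
  appropriate when the common-variant search space is restricted to
  MAF ≥ 0.2), genome-wide at p < 5×10⁻⁸. Both configurable.
- The genomic inflation factor is λ = median(χ²₁(1 − p)) / 0.4549364.

## Anchored interaction scan (module `epistasis`)

For an anchor SNP A and each candidate partner B, OLS of

    y = b0 + b1 g_A + b2 g_B + b3 g_A g_B + e

with the two-sided t test of b3 on N − 4 df. Coefficient covariance is
either model-based σ̂²(XᵀX)⁻¹ or the heteroscedasticity-consistent
sandwich (XᵀX)⁻¹ Xᵀ diag(w_i e_i²) X (XᵀX)⁻¹ with HC0 w = 1,
HC1 w = N/(N−4), HC2 w = 1/(1−h_i), HC3 w = 1/(1−h_i)² (h_i the
leverage). HC3 is the default sandwich: it is the most conservative of
the standard weightings in finite samples. The t reference (rather than
a normal approximation) is kept for finite-sample honesty.

Why robust errors at all: anchoring at a variance-heterogeneous SNP
guarantees heteroscedastic residuals with respect to g_A, which
inflates the model-based interaction test across random partners. At
n = 2447 with a κ = 1.3 multiplicative variance effect and 2,000
independent partners the model-based λ is ≈ 1.3–1.4 while the HC3 λ
stays within [0.9, 1.1] (median over 20 seeds; recomputed by the
acceptance script). The `auto` policy computes both p-value sets in one
pass and reports the sandwich column when the model-based λ exceeds
1.05 — a deliberately tight trigger, since the cost of the sandwich
under homoscedasticity is small (HC3/model SE ratio within 3% at
n = 5,000).

Partners with r² > 0.9 to the anchor are excluded (near-collinear
product terms) and logged, as are monomorphic partners.

### Decomposition of a variance signal

An interaction-induced vQTL and a direct variance effect are separated
by conditioning on the putative partner:

- `stratified_effects`: the slope of y on g_B within each g_A stratum
  is β_B + β_AB·a under the model, so opposite stratum slopes with a
  near-zero combined slope (β_B + β_AB·E[g_A]) are the interaction
  signature.
- `stratified_vqtl`: the anchor's Levene scan within each partner
  stratum. Under a pure interaction the within-stratum signal collapses
  to null (median within-stratum p ≥ 0.1 across seeds at the study
  scale); under a direct variance effect it persists strongly (median
  within-stratum p < 10⁻³). Note the comparison must be on this
  absolute scale, not relative to the unstratified p-value: −log₁₀ p
  scales roughly linearly with n, so restricting to a third-sized
  stratum attenuates *any* true signal by many decades while leaving it
  overwhelming. Optional downsampling equalizes stratum sizes (seeded,
  without replacement) to make the three strata comparable in power.
- `sensitivity_drop_extreme`: re-runs a test battery after removing the
  single largest |residual|. A robust signal moves by a small fraction
  of its depth (roughly ≤ 15% of |log₁₀ p|); a signal produced by one
  outlier collapses.
- `gxe_tests`: the 1-df Wald test of the g×E coefficient and the 2-df
  joint Wald chi-square of the main and interaction coefficients, with
  the same covariance options, for exposures such as age or sex.
- `colocalize_table`: per-variant −log₁₀ p of the variance and
  interaction tests within ±500 kb of a lead, with r² to the lead —
  plot-ready evidence that the two signals track the same LD structure.

## Replication thresholds (module `multtest`)

The effective number of tests in a region is the eigenvalue-based count

    Meff = Σ_i f(|λ_i|),  f(x) = 1[x ≥ 1] + (x − ⌊x⌋),

over the eigenvalues of the variant correlation matrix
(pairwise-complete Pearson on dosages, symmetrized as (R + Rᵀ)/2, tiny
negative eigenvalues above −10⁻⁸ clipped to zero). Both the real-valued
sum and the round-half-up integer are reported; thresholds use the
integer. Replication significance is α/Meff for a single locus and
α/(Meff_A·Meff_B) for a locus pair (0.05/138 = 3.62×10⁻⁴ and
0.05/138/162 = 2.24×10⁻⁶ for the canonical counts). Proxy SNPs for an
unavailable target are ranked by descending r², ties broken by physical
distance.

## Morphometrics (module `morpho`)

Landmark configurations (k×2) are centered, scaled to unit centroid
size CS = √Σ‖x_i − centroid‖², and iteratively rotated to the evolving
consensus by the 2D orthogonal Procrustes solution with determinant
constrained to +1 — labelled biological landmarks must never be
mirrored. The consensus is the renormalized mean of the aligned
configurations; iteration stops when the summed squared Procrustes
distance changes by < 10⁻¹⁰ (or at 100 iterations; typical runs
converge in ≤ 5). The global rotational ambiguity is fixed by rotating
everything onto the first specimen's principal axes, with the residual
π ambiguity resolved by a sign convention on the first landmark.

The width measure is the inter-landmark distance between the bilateral
eye landmarks on the *aligned unit-size* coordinates; centroid size is
nevertheless retained as a covariate in the association models,
mirroring standard morphometric practice of adjusting for a global size
measure even after scaling (a flag allows raw-coordinate distances).
The mean test is OLS of width on additive dose + centroid size + litter
fixed-effect indicators (random-effect litter is out of scope), Wald p
for dose; with doses {0, 2} only and no covariates this reduces exactly
to the pooled two-sample t-test. The variance test is the median-based
Levene test across dose groups of the width residuals after adjusting
for centroid size and litter only (dose excluded from the adjustment so
that a genuine variance difference survives); `min_group = 3` here
because mouse group sizes are small.

## Synthetic data (module `simulate`)

Genotypes: per LD block, two independent haplotypes are drawn from a
latent Gaussian with AR(1) correlation ρ^|i−j| and thresholded at
Φ⁻¹(MAF); the genotype is their sum. This is simple, seedable, and
yields Hardy–Weinberg-consistent marginals, but the realized allelic
correlation is attenuated relative to the latent ρ, so LD targets are
asserted qualitatively (monotone decay with lag), never numerically.
Blocks are placed 2 Mb apart on one chromosome (5 kb between SNPs
within a block) so that ±500 kb windows isolate a block.

Trait: y = μ + Σ γ_c x_c + β_A g_A + β_B g_B + β_AB g_A g_B +
β_E g_A E + ε with ε ~ N(0, (σ₀ κ^{g_A})²). κ is a scale-free
per-anchor-allele multiplier on the residual SD (κ = 1 ⇒
homoscedastic); κ and β_AB are the two competing variance-heterogeneity
mechanisms. Covariates: age ~ U(3, 49) (the cohort age range), age²,
sex ~ Bernoulli(0.62) (the cohort female fraction), height/weight
Gaussian, an opaque "size" covariate N(0, 1) (the facial-size covariate
has no published operational definition, so it is treated as an opaque
column), and a standard-normal exposure E. `inject_outliers` replaces k
random trait values by value + m·SD with provenance recorded.

Canonical scenarios (the study conditions; not tuning knobs):
`config_interaction` (n = 2447, a 10-SNP ρ = 0.8 anchor block with
MAF 0.25 and the anchor mid-block, an independent partner block with
the true partner at MAF 0.5 and decoys spanning 0.2–0.5, β_AB = 0.7),
`config_pure_vqtl` (same geometry, κ = 1.3, no interaction), and
`config_null`. β_AB = 0.7 and κ = 1.3 sit near the detection boundary
at n = 2447 — strong enough for reliable recovery, weak enough that the
calibration questions are non-trivial.

Landmarks: a fixed 6-landmark cranial template (eyes ±(0.30, 0.30),
ears ±(0.45, −0.20), anterior (0, 0.55), posterior (0, −0.55)); the eye
separation grows by width_delta·dose, half per side. Each specimen gets
a random similarity transform — rotation U(0, 2π), log-normal scale
with a litter-level intercept (SD 0.1 on the log scale) plus individual
SD 0.05, translation U(−1, 1)² — then isotropic Gaussian landmark noise
(default SD 0.01; 0.005 in the small-sample power settings). Litters
(default 6) are assigned round-robin after a seeded shuffle, so they
mix genotypes; this reflects litters from heterozygote crosses, not a
confounded design.

What the generator does *not* emulate: relatedness and family
structure, imputation uncertainty beyond a simple DS-rounding flag,
X-chromosome inheritance, coalescent allele-frequency spectra, rare
variants, assortative mating, and any real LD map. Passing tests
therefore certify the statistical machinery under the stated generative
model, not performance on any particular human cohort.

## I/O conventions (module `dataio`)

VCF 4.x via cyvcf2 (plain or bgzipped); only biallelic SNPs are kept,
multiallelic/indel records are skipped with a logged count. GT is used
when present; otherwise DS dosages are hard-called by rounding with
x.5 rounding up, and a per-variant flag is set when mean |DS − round|
exceeds 0.1. Positions are 1-based; region queries are closed
intervals; internal indices 0-based. Missing calls use a −1 sentinel
and every test drops its own incomplete rows (pairwise-complete; no
imputation). Result tables are tab-separated with fixed column orders
and p-values in scientific notation with 6 significant digits after the
leading digit, so written files re-read to at least 6 significant
figures.

## Numerical choices

- Rank checks: the interaction design is rejected when the normal
  matrix has condition number > 10¹² (catches perfect-LD pairs that
  survive floating-point inversion).
- `ld_r2` is computed with commutative operations so it is exactly
  symmetric in its arguments; monomorphic-on-shared-samples pairs
  return NaN.
- LD pruning is sliding-window greedy (window 50 SNPs, step 5,
  r² > 0.2): within a window the offending pair with the largest r² is
  resolved first by dropping the lower-MAF member (ties drop the larger
  index); deterministic and idempotent.
- Ancestry PCA standardizes dosages as (g − 2p̂)/√(2p̂(1 − p̂)),
  mean-imputes missing calls after centering, and fixes each
  component's sign so its largest-|loading| variant loads positively.
- All randomness flows from `numpy.random.default_rng` seeded via
  `SeedSequence`; independent streams are used for genotypes,
  phenotypes and downsampling so that identical configurations
  reproduce bit-identical outputs.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the expensive properties
at the sizes stated above (n = 2447 cohorts, 2,000-partner scans over
20–50 seeds, 10,000 null replicates for calibration, n = 10⁶ for the
moment oracle, 200 seeds for the morphometric checks) and the routine
unit properties at smaller sizes chosen to keep the default run fast;
each test's docstring states its own scale.

## Known limitations

- The Levene scan tests hard-call groups only; dosage-aware
  (double-GLM or deviation-regression) variance estimators are not
  implemented.
- Fixed-effect litter adjustment can be anti-conservative with many
  tiny litters; a mixed model would be preferable at larger scale.
- The latent-Gaussian LD model cannot hit a target r² exactly, so
  proxy/pruning behaviour is validated by ordering properties rather
  than fixed LD values.
- `scan_partner` is single-anchor by design; exhaustive all-pairs
  epistasis is out of scope.
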