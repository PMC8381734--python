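# vqtlkit

Variance-QTL scanning and variance-prioritized gene-by-gene (G×G)
interaction analysis for quantitative traits, with the landmark
morphometrics needed to follow a statistical signal into a model
organism.

## The problem

Conventional GWAS compares genotype-group *means*. A variance QTL
(vQTL) is a variant whose genotype groups differ in phenotypic
*variance* instead — and unmodeled gene-by-gene interactions are one of
the processes that produce exactly that signature: if a trait follows

    y = μ + β_A g_A + β_B g_B + β_AB g_A g_B + ε,

then conditional on the anchor genotype `g_A = a` (with the partner
`g_B` unobserved),

    E[y | a]   = μ + β_A a + (β_B + β_AB a) · 2p_B
    Var[y | a] = (β_B + β_AB a)² · 2p_B(1 − p_B) + σ₀²,

so the interaction inflates the variance of some genotype groups.
Because an exhaustive genome-wide pairwise interaction search is
hopeless at cohort-scale sample sizes, *variance prioritization* scans
for vQTLs first and tests interactions only at those anchors. This
package implements that workflow end to end for geneticists and
biostatisticians:

- **Variance scan** — the median-based Levene (Brown–Forsythe) test
  per SNP: W = ((N−K)/(K−1)) · Σ n_g(z̄_g − z̄)² / ΣΣ(z_ij − z̄_g)² with
  z_ij = |y_ij − median_g|, referred to F(K−1, N−K). Robust to
  non-normal residuals and outliers.
- **Anchored interaction scan** — OLS with a product term, with
  heteroscedasticity-consistent sandwich covariance (HC0–HC3; HC3
  default) because anchoring at a variance-heterogeneous SNP violates
  the homoscedasticity the model-based standard errors assume. An
  `auto` policy monitors the genomic inflation factor λ of the
  model-based p-values and switches to the sandwich when λ > 1.05.
- **Decomposition** — stratified slopes, stratified variance scans
  (with downsampling to equal strata), co-localization tables, G×E 1-df
  and 2-df tests, and outlier sensitivity re-runs, to separate
  interaction-induced variance heterogeneity from direct variance
  effects and artifacts.
- **Replication thresholds** — the eigenvalue-based effective number of
  tests Meff = Σ f(|λ_i|), f(x) = 1[x ≥ 1] + (x − ⌊x⌋), over the
  regional SNP correlation matrix, with product-rule Bonferroni
  thresholds α / (Meff_A · Meff_B) and LD-proxy selection.
- **Morphometrics** — generalized Procrustes superimposition of 2D
  landmark configurations to unit centroid size, a bilateral width
  distance, and mean (dose regression) plus variance (Levene) tests
  adjusting for litter and centroid size.
- **Synthetic cohorts** — a seeded generator for LD-block genotypes
  (latent-Gaussian threshold model), traits with covariates and the
  architectures above, and 6-landmark cranial configurations with a
  dose-dependent width effect.

## Worked example

```python
import numpy as np
from vqtlkit import (config_interaction, simulate_genotypes,
                     simulate_phenotype, residualize, vqtl_scan,
                     scan_partner, stratified_vqtl)

cfg = config_interaction(n_samples=2447, m_partners=500,
                         beta_ab=0.7, seed=1)
G = simulate_genotypes(cfg)                    # 2447 x 510 hard calls
resid = residualize(simulate_phenotype(G, cfg))

scan = vqtl_scan(G, resid)                     # variance scan
best = scan.table.sort_values("P").iloc[0]
print(best["ID"], best["W"], best["P"])

epi, diag = scan_partner(G, resid, best["ID"])  # anchored G x G scan
top = epi.sort_values("P").iloc[0]
print(top["ID_B"], top["BETA_INT"], top["P"], diag["lambda_model"])

sv = stratified_vqtl(G.take_variants(np.arange(10)), resid,
                     G.dosage(top["ID_B"]))
print({a: float(r.table.set_index("ID")["P"][best["ID"]])
       for a, r in sv.items()})
```

Output (seed 1):

```
snp00004 23.858023224161684 5.4757222055157436e-11
snp00010 0.6935539311692974 1.730329989280748e-51 1.197694073639629
{0: 0.9674318736924477, 1: 0.717020551653022, 2: 0.782801544411121}
```

The vQTL scan flags the simulated anchor (`snp00004`, Levene
W = 23.9, p ≈ 5×10⁻¹¹); the anchored interaction scan ranks the true
partner (`snp00010`) first with β̂_AB ≈ 0.69 (truth 0.7) — note the
model-based λ of 1.20, which is why the sandwich p-value is reported —
and stratifying the anchor's variance scan on the partner genotype
wipes out the signal (within-stratum p = 0.97/0.72/0.78), the hallmark
that the variance heterogeneity was interaction-induced rather than a
direct variance effect.

The same workflow is scriptable from the shell: `vqtlkit simulate`,
`vqtlkit prep`, `vqtlkit vqtl`, `vqtlkit epi`, `vqtlkit meff`,
`vqtlkit gpa`, `vqtlkit pipeline` (see `vqtlkit --help`).

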