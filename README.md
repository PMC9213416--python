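# snpher

Liability-scale SNP heritability, genetic correlation and gene–environment
interaction analysis for **grouped case-control traits**, with a synthetic
cohort simulator for end-to-end validation.

## The problem

Diseases that share a mechanism — e.g. the hormone-responsive cancers of
the breast, prostate, uterus, ovary and thyroid — are usually studied one
site at a time, leaving their *shared* germline architecture unquantified.
Coding the related subtypes as a single grouped phenotype changes that: one
can ask how much variance in disease liability genome-wide SNPs explain for
the group, which loci drive the shared signal, how the grouped trait
correlates genetically with endocrine and anthropometric phenotypes, and
whether the genetic effects are modulated by environments such as adiposity.
`snpher` implements that complete workflow for anyone who wants to run or
study it: quantitative geneticists, genetic epidemiologists, and method
developers who need a self-contained, simulatable replica of the analysis.

## What is inside

For a binary trait with population prevalence *K*, case status is threshold
exceedance on a latent liability.  The package fits the linear mixed model

    y = Xb + a + e,   a ~ N(0, A σ²g),   e ~ N(0, I σ²e)

by AI-REML on the genomic relationship matrix
*A*ⱼₖ = (1/M) Σᵢ (xᵢⱼ−2pᵢ)(xᵢₖ−2pᵢ)/(2pᵢ(1−pᵢ)), and transforms the
observed-scale h² = σ²g/(σ²g+σ²e) to the liability scale,
h²ₗ = h²ₒ·K²(1−K)²/(P(1−P)z²).  Around that core:

- **`simulate`** — genotype panels with block-AR(1) copula LD and
  HapMap-like MAF spectrum; sex-restricted liability-threshold subtypes
  with a shared polygenic factor (controllable h² and pairwise r_g);
  correlated quantitative traits; binary and quantitative environments that
  modulate SNP effects.
- **`qc`** — the standard QC cascade (call rates, INFO, MAF, exact mid-p
  HWE, ambiguous/duplicate SNPs), relatedness pruning, PC-outlier removal,
  release-discordance filtering, GRM construction.
- **`greml`** — univariate and bivariate AI-REML (`GREML`,
  `BivariateGREML`, sklearn-style estimators), the liability
  transformation, stratified gene–environment interaction
  (r_g between environment strata, tested against 1), and split-sample
  meta-analysis (inverse-variance pooling + Fisher's method).
- **`gwas`** — per-SNP logistic or linear-probability scans, genomic
  inflation λ and λ₁₀₀₀, greedy LD clumping into independent loci,
  fixed-effect meta-analysis with allele harmonization.
- **`ldsc`** — LD scores (small-sample adjusted), LD-score regression for
  h² and cross-trait r_g (overlap-robust intercept, block jackknife), the
  per-SNP interaction scan, and GxEsum: regressing interaction χ² on LD
  scores to estimate the GxE variance σ²g₁ and scale variance σ²τ₁ from
  E[χ²ⱼ|ℓⱼ] = Nσ²g₁/M·ℓⱼ + 1 + 2(σ²g₁+σ²τ₁).
- **`endocrine`** — Pearson/Fisher-z phenotypic correlations, the
  calculated-free-oestradiol record, leave-one-out subtype groupings.
- **`pipeline` / `snpher` CLI** — the whole study replica with seeded,
  bit-stable, resumable runs and open-format outputs (PLINK, GCTA GRM,
  TSV).

## Worked example

```python
import numpy as np
from snpher import (SimulationConfig, simulate_panel, simulate_phenotypes,
                    compute_grm, GREML, observed_to_liability)

cfg = SimulationConfig(n_samples=2500, n_variants=2500, master_seed=11,
                       ld_block_length=1)
panel = simulate_panel(cfg)
pheno = simulate_phenotypes(panel, cfg)
grm = compute_grm(panel)

y = pheno.table["grouped_status"].to_numpy(float)
print(f"grouped case proportion: {y.mean():.4f}")
est = GREML().fit(y, grm=grm).estimate_
lia = observed_to_liability(est, K=float(y.mean()))
print(f"disease h2 observed:  {est.h2_observed:.4f} (SE {est.h2_se:.4f})")
print(f"disease h2 liability: {lia.h2_liability:.4f} (SE {lia.se:.4f})")

height = pheno.table["height_like"].to_numpy(float)
est_q = GREML().fit(height, grm=grm).estimate_
print(f"height-like h2:       {est_q.h2_observed:.4f} (SE {est_q.h2_se:.4f})")
```

prints

```
grouped case proportion: 0.0628
disease h2 observed:  0.0156 (SE 0.0291)
disease h2 liability: 0.0604 (SE 0.1122)
height-like h2:       0.4861 (SE 0.0280)
```

The grouped disease is simulated at ~6% prevalence with liability h² of
8–10% per subtype.  The observed-scale disease estimate is the liability
value shrunk by the threshold model, and the transformation maps it back
(0.06 ± 0.11 here — a binary trait at n = 2500 is individually very noisy,
which is why the validation suite averages replicates), while the
quantitative height-like trait (true h² 0.5) is recovered tightly
(0.486 ± 0.028).  Or run the pipeline from a shell:

```bash
snpher run-all --seed 1 --out runs/demo
snpher report --out runs/demo
```

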