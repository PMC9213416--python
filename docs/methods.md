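# Methods

`snpher` implements the quantitative-genetics workflow used to analyse a
*grouped* case-control phenotype — several related binary disease subtypes
(here hormone-responsive cancer-like subtypes) coded as a single disease —
together with a synthetic cohort generator that reproduces the statistical
structure such an analysis assumes.  This note records the models, the
defaults and their rationale, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Liability-threshold simulation

Each subtype *t* has a latent liability

    L_t = c_t sqrt(h2_t) G_shared + sqrt((1 - c_t^2) h2_t) G_t
          + covariate effects + e_t,

standardized to unit variance, where `G_shared` and `G_t` are standardized
polygenic scores (i.i.d. normal effects on frequency-standardized
genotypes, the GCTA working model — deliberately matched to the GREML
estimand, with no frequency-dependent architecture).  A sample is a case
iff its liability exceeds `Phi^-1(1 - K_t)` within the eligible sex; the
excluded sex is recorded missing, not control.  The grouped phenotype is
the union of subtype cases.  Two subtypes have genetic correlation
`c_s c_t`.

Polygenic scores are empirically standardized, so realized variance shares
match their targets almost exactly, and the realized prevalence of each
subtype is binomially distributed around `K_t` (verified over seeded
replicates).  Causal sets for different architectures are drawn
independently and may overlap; with i.i.d. effects, independent draws are
near-orthogonal, so genetic correlations remain controllable without
bookkeeping disjoint SNP pools.

**Default subtype composition.**  Female-only breast- (K = 5.0%),
uterine- (1.1%) and ovarian-like (0.8%) subtypes, a male-only
prostate-like subtype (4.55%) and a thyroid-like subtype in both sexes
(0.4%), with shared-factor loadings 0.7–0.8 and liability h2 8–10%.
These prevalences were chosen once so that the grouped sample proportion
averages ~6.06%, the reference value for the study design this package
replicates; per-subtype population prevalences are otherwise free
configuration.

**Genotypes and LD.**  Two haplotypes per individual; within an LD block
each haplotype carries a stationary AR(1) latent Gaussian (parameter
`ld_rho`) and the allele indicates the latent falling below the MAF
quantile.  This Gaussian-copula construction preserves Hardy–Weinberg
equilibrium exactly per SNP and gives closed-form control of LD decay.
The copula attenuates correlations relative to the latent scale (more so
for rare alleles), so dosage-scale r² is below `ld_rho²`; validation
scenarios that need a wide LD-score spread use `ld_rho = 0.9` with blocks
of 50 SNPs.  MAFs are uniform on a configurable range (default
0.05–0.5).  What this generator does *not* emulate: realistic human LD
maps and long-range LD, MAF–LD coupling, population structure and
admixture, genotyping batch artefacts, X-chromosome dosages, or
age-dependent onset.  Passing recovery tests on these cohorts therefore
demonstrates correctness of the estimators under their own model
assumptions, not robustness to the violations real data exhibit.

**Gene–environment structure.**  A binary environment splits the cohort in
two strata whose shared-factor SNP effects correlate `strata_rg` (1 = no
GxE).  A quantitative environment E modulates a separate trait:
`y = sqrt(s2_g0) G0 + E sqrt(s2_g1) G1 + sqrt(s2_tau1) E e0 + e`, the
generative counterpart of the summary-statistic interaction-variance model
below.  Incident/prevalent flags are assigned by Bernoulli thinning of
cases (fraction 0.5 by default): a calendar-time split has no synthetic
counterpart.

**Randomness.**  One master seed; every stage derives a named substream
(CRC-32 of the stage name spawning a `SeedSequence`), so stages can be
re-run independently and adding a stage never shifts existing streams.
Identical config + seed reproduces outputs bit for bit.

## QC and the GRM

The QC cascade applies, in a fixed logged order: sample call rate ≥ 0.95 →
SNP call rate ≥ 0.95 → INFO ≥ 0.6 → MAF ≥ 0.01 → Hardy–Weinberg exact
mid-p ≥ 1e-7 → removal of strand-ambiguous (A/T, C/G) and duplicated
(chromosome, position, allele-set) SNPs.  The order is a documented
choice; the thresholds are the conventional ones for biobank-scale
analyses.  The HWE test is the exact conditional enumeration with mid-p
tie handling (a chi-square approximation misbehaves for rare genotypes);
ties are resolved with a *relative* tolerance, since an absolute one would
absorb the far tail.

The GRM is the frequency-standardized estimator
`A_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))` with `p_i`
estimated from the panel (optionally supplied).  Missing dosages are
mean-imputed for the GRM and PCA only; association testing uses observed
genotypes, so per-SNP sample counts vary.  Relatedness pruning is greedy
over pairs in descending relatedness with a seeded random choice of which
member to drop, and is verified post hoc (no retained pair above the
cutoff).  In the pipeline the effective cutoff is
`max(0.05, mean + 6 SD of the off-diagonals)`: the conventional 0.05
threshold presumes a dense panel whose off-diagonal noise SD (~1/√M) is
far below it, and at desk-scale M the guard prevents sampling noise from
being read as relatedness.  PCs come from the GRM eigendecomposition
(eigenvectors scaled by √eigenvalue); samples beyond ±6 SD on PC1/PC2 are
dropped and the PCs are returned for use as covariates.

## GREML

Univariate model `y = Xb + a + e`, `a ~ N(0, A σ²_g)`, `e ~ N(0, I σ²_e)`;
binary traits are analysed as 0/1 under this linear mixed model (the
classical GREML route for disease traits; logistic mixed models are out of
scope).  The fit eigendecomposes the GRM once and rotates, making every
REML iteration O(n p²): two EM warm-up iterations, then average-information
(Newton) updates with step halving, convergence at |Δ logL| < 1e-6 (cap
100).  Variance components are floored at 1e-6 × Var(y) to keep V positive
definite; a boundary hit is flagged.  A (near-)identity GRM leaves the
two components identified only in sum; this is detected and flagged
(`non_identified`) with the total set to the REML residual variance.
Standard errors come from the inverse AI matrix; the h² SE by the delta
method; the h² p-value is a two-sided Wald test.

**Liability transformation.**  `h2_lia = h2_obs · K²(1−K)² / (P(1−P) z²)`
with `z` the normal density at the threshold; this reduces to
`h2_obs · K(1−K)/z²` when the population prevalence K equals the sample
proportion P — the convention used throughout (K = P), matching an
analysis that assumes the sample is population-representative.  The SE
scales by the same factor.

**Bivariate model.**  Two traits on either the identical sample set (with
a residual covariance) or disjoint strata (no residual covariance — the
stratified-GxE design).  The fit is dense AI-REML on the stacked system:
V is rebuilt per iterate, Cholesky-factorized, and the update is
Levenberg-damped (the ridge escalates until a positive-definite,
non-decreasing step is found; at high damping the step degenerates to a
scaled gradient).  This handles the singular geometry near |rg| = 1.
Exactly identical traits are detected and short-circuited to rg = 1 (the
optimum sits on the singular boundary).  rg is reported clamped to
[−1, 1] with the raw value retained; Wald tests against rg = 0 and rg = 1
use the raw value (clamping would degenerate the rg = 1 test), and a
likelihood-ratio test against σ_g12 = 0 (2 df when the residual covariance
is also freed) is optional.  If either genetic variance hits its floor,
rg is reported as undefined with the reason, mirroring how non-estimable
cells are handled downstream.

**Stratified GxE.**  The phenotype in two environment strata is treated as
two traits on disjoint samples; genetic correlation significantly below 1
indicates SNP effects differ between environments.  Binary phenotypes
report both observed- and liability-scale per-stratum h² (the appropriate
scale for a stratified disease phenotype is genuinely ambiguous, so both
are emitted).  The rg = 1 test is the Wald test on the raw estimate; its
type-I calibration is verified empirically in the acceptance suite.

**Split-sample meta-analysis.**  Large cohorts are split into seeded
near-equal parts (sizes differ by ≤ 1); per-split estimates are pooled by
inverse-variance weighting and p-values combined by Fisher's
`−2 Σ ln p ~ χ²_{2k}`.  Fisher's method cannot pool point estimates, so
the two roles are deliberately separated.

## GWAS

Per-SNP fits of `phenotype ~ intercept + covariates + dosage` in two
modes: logistic (per-SNP IRLS, 25-iteration cap, separation flagged and
reported as NA) and linear-probability on 0/1 (covariates residualized
once; this is also the scale on which published per-SNP betas of a ~6%
trait are printed).  P-values are two-sided normal tails of BETA/SE,
consistent to 1e-6 with the stored statistics by construction and checked
against printed worked examples.  Genomic inflation: λ = median χ² /
0.4549364, rescaled to a 1000-case/1000-control equivalent as
`λ1000 = 1 + (λ−1)(1/n_cases + 1/n_controls)/(2/1000)`; case and control
counts always come from the data.  Clumping is greedy by ascending P
(ties by chromosome, position, id) with defaults r² ≥ 0.1 within 1 Mb at
p < 5e-8 — the conventional parameters, config-exposed.  Meta-analysis is
fixed-effect inverse-variance with allele harmonization (sign flips for
swapped alleles, irreconcilable SNPs dropped with a log entry).

## LD-score regression

LD scores use the small-sample-adjusted estimator
`r~² = r² − (1 − r²)/(n − 2)` summed over a physical window (default
1 Mb), self term 1; scores are invariant to SNP order and strand
relabeling.  Univariate: weighted regression (weights 1/max(ℓ,1)) of χ²
on `N ℓ / M`, slope = h²; χ² > max(80, 0.001 N) dropped first; standard
errors by delete-one-block jackknife over 200 contiguous blocks (fewer,
automatically, below 2000 SNPs).  M — the number of SNPs the h² refers
to — is an explicit parameter everywhere, never inferred silently.
Cross-trait: `Z_A Z_B` on `sqrt(N_A N_B) ℓ / M` gives the genetic
covariance; the cross-trait intercept absorbs sample/control overlap and
is reported with a jackknife SE; rg = gcov/√(h²_A h²_B), with the whole
pipeline re-run per deleted block for the rg jackknife.  Non-positive h²
makes rg undefined, reported with the reason.  Heteroskedasticity-optimal
iterative weights are out of scope.

**Interaction scan and GxEsum.**  Per SNP,
`y ~ covariates + E + g + g×E` (E standardized, main effects always
included), vectorized via a closed-form partialled 2×2 solve; the
interaction χ² then follows
`E[χ²_j | ℓ_j] = N σ²_g1/M · ℓ_j + 1 + 2(σ²_g1 + σ²_τ1)`,
so a weighted regression of interaction χ² on ℓ inverts to the GxE
variance `σ²_g1 = b1 M/N` and the residual-heterogeneity (scale) variance
`σ²_τ1 = (b0 − 1)/2 − σ²_g1`.  An intercept below 1 makes σ²_τ1 negative
and is flagged as a boundary case.  Single-replicate σ²_g1 estimates are
noisy at desk scale; recovery is therefore validated on the mean over
seeded replicates against its empirical SE.

## Phenotypic correlations and free oestradiol

Pearson correlations on complete pairs, with the two-tailed Fisher-z
normal test (`p = 2Φ(−|atanh r|·√(n−3))`); binary traits use the same
machinery (point-biserial).  SEs are reported on both the r scale,
`(1−r²)/√(n−3)`, and the z scale, `1/√(n−3)`.

Calculated free oestradiol is evaluated literally as published:
`cFO = (E2 − N_TOTAL)/(N_SHBG − (E2 + N_E2))` with
`N_E2 = 0.64e9·albumin + 1`, `N_SHBG = 5.55e4·SHBG`,
`N_TOTAL = N_SHBG + N_E2`, all intermediates retained, units passed
through unconverted, and a zero denominator raised as an error.  This
printed form is dimensionally inconsistent with the mass-action
free-hormone literature (the likely original is a quadratic in the free
concentration); because no worked value or units accompany it, literal
evaluation is the only faithful choice.  A clearly named standard
mass-action quadratic (`free_estradiol_mass_action`) is provided for
comparison and is used nowhere by default.

**Leave-one-out grouping.**  One fold per subtype: the grouped phenotype
excluding it; the rg grid between each subtype and each grouped-minus-one
phenotype is assembled with whichever rg backend is supplied (cross-trait
LDSC by default in the pipeline), and non-estimable cells carry the
failure reason rather than a number.

## Pipeline

Stages run in dependency order (simulate → QC → GRM → GREML → GWAS → LDSC
→ correlations → LOO → GxE), writing only documented open formats (TSV,
PLINK BED/BIM/FAM, GCTA binary GRM, `.l2.ldscore`, `(SNP, A1, A2, N, Z)`
sumstats).  Every defaulted value is echoed to the log and frozen into
`config.frozen.yaml`; the report carries a config hash and the seed, and a
completed run with a matching hash is reloaded rather than recomputed.
The config hash covers exactly the analysis-relevant fields (not paths or
log level).

## Validation problem sizes

The test suite exercises every estimator against generative truth at desk
scale, chosen so the full suite runs in minutes on one CPU while each
check retains statistical resolution:

- GREML quantitative recovery: n = 1500, m = 2500 unlinked SNPs, true
  h² = 0.3, 20 replicates; the mean must land within 0.03 of truth
  (SE of the mean ≈ 0.011).
- Case-control liability recovery: n = 2000, K = P = 0.06, true liability
  h² = 0.10, 10 replicates, 2-SE coverage in ≥ 9/10.
- LDSC recovery and GREML concordance: one block-LD cohort, n = 3000,
  m = 16,000, AR(1) ρ = 0.9.
- Bivariate rg recovery: n = 1000, 10 replicates, nominal rg = 0.5,
  assessed against the *realized* genetic correlation of each replicate's
  simulated architecture — with 500 causal SNPs the realized rg differs
  from nominal by O(1/√n_causal), which is simulation noise, not
  estimator error.
- Stratified-GxE calibration: 40 null replicates at 800 samples/stratum
  (chosen as large as is consistent with a minutes-scale suite, since the
  normal approximation of the Wald statistic improves with stratum size);
  power at between-strata rg = 0.15 over 8 replicates.  With only 40 binary outcomes the rejection count is
  highly discrete; the calibration band is 5% ± 3%.
- GxEsum recovery: mean over 8 block-LD cohorts (n = 2500, m = 8000)
  against the empirical SE of the mean.
- Null calibration: λ on an m = 20,000 null scan; interaction-χ² mean over
  20,000 null tests within 1 ± 0.05.

`scripts/acceptance.py` re-runs the same designs from scratch under a
user-supplied seed and writes the headline numbers as JSON.

## Known limitations

- Binary traits use the linear-mixed-model-plus-transformation route;
  severe case-control ascertainment (K far from P) is handled by the
  general transformation but not by ascertainment-corrected REML.
- The bivariate fitter supports identical or disjoint sample sets, not
  partial overlap.
- Single genetic component only: no partitioned GREML or
  annotation-stratified LDSC.
- The synthetic LD model cannot reproduce reference-panel LD scores for
  real summary statistics; the LDSC module is validated within the
  package's own generative world.
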