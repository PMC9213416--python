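"""Synthetic cohort generator.

Emulates the statistical structure a grouped case-control quantitative-genetics
analysis assumes: a panel of biallelic SNPs with a HapMap-like allele-frequency
spectrum and block LD, several (possibly sex-restricted) binary disease
subtypes generated from a liability-threshold model with a shared polygenic
factor, correlated quantitative traits, and environments that modulate SNP
effects (for gene-environment interaction).

The LD model is a Gaussian-copula AR(1) over haplotypes: within an LD block
each haplotype carries a stationary AR(1) latent Gaussian and the allele is
the indicator of that latent falling below the allele-frequency quantile.
Hardy-Weinberg equilibrium therefore holds exactly per SNP, and the LD decay
rate is controlled in closed form by the AR(1) parameter.

Effect sizes are i.i.d. normal on standardized genotypes (the GCTA working
model), with no frequency dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

__all__ = [
    "SubtypeSpec",
    "TraitSpec",
    "GxESpec",
    "CovariateSpec",
    "SimulationConfig",
    "GenotypePanel",
    "CohortPhenotypes",
    "simulate_panel",
    "simulate_phenotypes",
]

MISSING = -1  # dosage code for a missing genotype

#: subtype composition mirroring a grouped hormone-sensitive cancer phenotype:
#: breast/uterine/ovarian-like female-only, prostate-like male-only,
#: thyroid-like in both sexes.  Prevalences are within the eligible sex and
#: chosen so the grouped sample proportion lands near 6.06%.
DEFAULT_SUBTYPES = (
    ("breast_like", "female", 0.050, 0.10, 0.80, 400, 100),
    ("prostate_like", "male", 0.0455, 0.10, 0.80, 400, 100),
    ("uterine_like", "female", 0.011, 0.08, 0.70, 400, 60),
    ("ovarian_like", "female", 0.008, 0.08, 0.70, 400, 60),
    ("thyroid_like", "both", 0.004, 0.08, 0.70, 400, 60),
)


@dataclass(frozen=True)
class SubtypeSpec:
    """One binary disease subtype on the liability scale.

    ``prevalence`` is the lifetime risk K within the eligible sex,
    ``liability_h2`` the liability-scale SNP heritability, and
    ``shared_loading`` c the loading of the subtype's genetic factor on the
    shared polygenic factor, so two subtypes have genetic correlation
    c_s * c_t (plus 0 from their specific parts).
    """

    name: str
    sex_restriction: str = "both"  # female | male | both
    prevalence: float = 0.06
    liability_h2: float = 0.10
    shared_loading: float = 0.8
    n_causal_shared: int = 400
    n_causal_specific: int = 100

    def __post_init__(self):
        if self.sex_restriction not in ("female", "male", "both"):
            raise ValueError(f"bad sex_restriction {self.sex_restriction!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.liability_h2 <= 1.0:
            raise ValueError("liability_h2 must be in [0, 1]")
        if abs(self.shared_loading) > 1.0:
            raise ValueError("shared_loading must be in [-1, 1]")
        # c^2 * shared variance cannot exceed the total genetic variance
        if self.shared_loading**2 * self.liability_h2 > self.liability_h2 + 1e-12:
            raise ValueError("shared variance exceeds liability_h2")


@dataclass(frozen=True)
class TraitSpec:
    """A quantitative trait with target h2 and genetic correlation ``rg``
    with the grouped disease's shared polygenic factor."""

    name: str
    h2: float = 0.3
    rg_with_grouped_liability: float = 0.0
    n_causal: int = 400

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if abs(self.rg_with_grouped_liability) > 1.0:
            raise ValueError("rg must be in [-1, 1]")


@dataclass(frozen=True)
class GxESpec:
    """Gene-environment structure.

    A quantitative environment E modulates SNP effects additively on a
    quantitative GxE trait::

        y = sqrt(s2_g0) G0 + E sqrt(s2_g1) G1 + sqrt(s2_tau1) E e0 + e

    with variance fractions ``sigma2_g0`` (main genetic), ``sigma2_g1``
    (GxE) and ``sigma2_tau1`` (residual-by-environment scale effect).

    A binary environment splits the cohort into two strata; the shared
    polygenic factor of the disease uses stratum-specific SNP effects with
    correlation ``strata_rg`` (1 means no GxE on the disease).
    """

    sigma2_g0: float = 0.3
    sigma2_g1: float = 0.0
    sigma2_tau1: float = 0.0
    environment_type: str = "quantitative"  # quantitative | binary
    strata_rg: float = 1.0
    n_causal: int = 400

    def __post_init__(self):
        for v in (self.sigma2_g0, self.sigma2_g1, self.sigma2_tau1):
            if not 0.0 <= v <= 1.0:
                raise ValueError("variance fractions must be in [0, 1]")
        if self.sigma2_g0 + self.sigma2_g1 + self.sigma2_tau1 > 1.0:
            raise ValueError("variance fractions sum to more than 1")
        if self.environment_type not in ("quantitative", "binary"):
            raise ValueError(f"bad environment_type {self.environment_type!r}")
        if abs(self.strata_rg) > 1.0:
            raise ValueError("strata_rg must be in [-1, 1]")


@dataclass(frozen=True)
class CovariateSpec:
    """Liability-scale effects (per-SD, i.e. sqrt of variance fractions) of
    the simulated covariates."""

    age_beta: float = 0.0
    sex_beta: float = 0.0
    centre_beta: float = 0.0
    batch_beta: float = 0.0

    def variance(self) -> float:
        return (
            self.age_beta**2
            + self.sex_beta**2
            + self.centre_beta**2
            + self.batch_beta**2
        )


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 4000
    n_variants: int = 8000
    master_seed: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_length: int = 50
    ld_rho: float = 0.0
    bp_spacing: int = 5000
    missing_rate: float = 0.0
    subtype_specs: tuple[SubtypeSpec, ...] = tuple(
        SubtypeSpec(*s) for s in DEFAULT_SUBTYPES
    )
    trait_specs: tuple[TraitSpec, ...] = (
        TraitSpec("igf1_like", 0.25, 0.30),
        TraitSpec("oestradiol_like", 0.15, -0.25),
        TraitSpec("shbg_like", 0.25, -0.10),
        TraitSpec("albumin_like", 0.20, 0.0),
        TraitSpec("height_like", 0.50, 0.15),
    )
    gxe_spec: GxESpec = field(default_factory=GxESpec)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    incident_fraction: float = 0.5

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("n_samples and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_length <= 0:
            raise ValueError("ld_block_length must be positive")
        for s in self.subtype_specs:
            for nc in (s.n_causal_shared, s.n_causal_specific):
                if nc > self.n_variants:
                    raise ValueError("n_causal exceeds n_variants")
        if self.covariate_spec.variance() >= 1.0:
            raise ValueError("covariate variance must be < 1")


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypePanel:
    """Samples x variants allele-count matrix plus variant metadata.

    ``dosages`` holds counts of ``allele1`` (the effect allele) in
    {0, 1, 2} with -1 for missing, stored as int8.  ``variants`` is a
    DataFrame with columns (chrom, pos, snp, a1, a2, maf, info).
    """

    sample_ids: np.ndarray
    sex: np.ndarray  # "female" / "male"
    variants: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if len(np.unique(self.sample_ids)) != self.n_samples:
            raise ValueError("sample ids not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages outside {0,1,2,missing}")

    def allele_frequencies(self) -> np.ndarray:
        """Empirical frequency of allele1 per variant (missing excluded)."""
        d = self.dosages
        obs = d != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(0) / (2.0 * obs.sum(0))

    def standardized(self, dtype=np.float64) -> np.ndarray:
        """Mean-imputed, frequency-standardized genotype matrix
        (x - 2p) / sqrt(2p(1-p)) with p estimated from the panel."""
        p = self.allele_frequencies()
        denom = np.sqrt(2.0 * p * (1.0 - p))
        if np.any(denom == 0) or np.any(~np.isfinite(denom)):
            bad = self.variants["snp"].values[(denom == 0) | ~np.isfinite(denom)]
            raise ValueError(f"zero-variance SNP(s): {bad[:5].tolist()}")
        x = self.dosages.astype(dtype)
        x[self.dosages == MISSING] = np.nan
        mu = 2.0 * p
        x = np.where(np.isnan(x), mu, x)
        return (x - mu) / denom

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypePanel":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypePanel(
            sample_ids=self.sample_ids[si],
            sex=self.sex[si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosages=self.dosages[np.ix_(si, vi)],
        )


@dataclass
class CohortPhenotypes:
    """Per-sample phenotypes, covariates, environments and (for testing)
    the true latent liabilities and generative parameters."""

    table: pd.DataFrame  # indexed by sample id
    subtype_names: list[str]
    truth: dict

    @property
    def grouped_status(self) -> np.ndarray:
        return self.table["grouped_status"].to_numpy()

    def validate(self) -> None:
        sub = self.table[self.subtype_names]
        grouped = (sub == 1).any(axis=1).astype(int).to_numpy()
        if not np.array_equal(grouped, self.grouped_status):
            raise ValueError("grouped_status is not the union of subtypes")


# ---------------------------------------------------------------------------
# panel simulation


def _block_layout(m: int, block_len: int, bp_spacing: int) -> pd.DataFrame:
    """Assign whole LD blocks to chromosomes 1..22, contiguous positions."""
    n_blocks = int(np.ceil(m / block_len))
    per_chrom = int(np.ceil(n_blocks / 22))
    chrom = np.repeat(np.arange(n_blocks) // per_chrom + 1, block_len)[:m]
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        k = int((chrom == c).sum())
        pos[chrom == c] = 1 + bp_spacing * np.arange(k)
    block = np.repeat(np.arange(n_blocks), block_len)[:m]
    return pd.DataFrame({"chrom": chrom.astype(np.int64), "pos": pos, "block": block})


def simulate_panel(config: SimulationConfig) -> GenotypePanel:
    """Simulate an n x m genotype panel with block-AR(1) copula LD.

    Two haplotypes per individual; within a block each haplotype's latent
    Gaussian is a stationary AR(1) with parameter ``ld_rho`` and the allele
    is 1 when the latent falls below the MAF quantile, so HWE holds per SNP.
    Deterministic given ``config.master_seed``.
    """
    n, m = config.n_samples, config.n_variants
    rng = substream(config.master_seed, "panel")

    layout = _block_layout(m, config.ld_block_length, config.bp_spacing)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresh = stats.norm.ppf(maf)

    dos = np.empty((n, m), dtype=np.int8)
    rho = config.ld_rho
    sq = np.sqrt(1.0 - rho * rho)
    if rho == 0.0:
        # unlinked fast path: one latent draw, no recursion
        z = rng.standard_normal((2 * n, m))
        alle = (z < thresh).astype(np.int8)
        dos = alle[0::2] + alle[1::2]
    else:
        for b in np.unique(layout["block"].values):
            cols = np.where(layout["block"].values == b)[0]
            L = len(cols)
            e = rng.standard_normal((2 * n, L))
            z = np.empty_like(e)
            z[:, 0] = e[:, 0]
            for j in range(1, L):
                z[:, j] = rho * z[:, j - 1] + sq * e[:, j]
            alle = (z < thresh[cols]).astype(np.int8)
            dos[:, cols] = alle[0::2] + alle[1::2]

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dos[mask] = MISSING

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    sample_ids = np.array([f"S{i:06d}" for i in range(1, n + 1)])

    # alternating allele pairs avoid strand-ambiguous (A/T, C/G) SNPs
    pairs = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    pick = pairs[np.arange(m) % 4]
    variants = pd.DataFrame(
        {
            "chrom": layout["chrom"],
            "pos": layout["pos"],
            "snp": [f"rs{i:07d}" for i in range(1, m + 1)],
            "a1": pick[:, 0],
            "a2": pick[:, 1],
            "maf": maf,
            "info": rng.uniform(0.85, 1.0, size=m),
        }
    )
    return GenotypePanel(sample_ids=sample_ids, sex=sex, variants=variants, dosages=dos)


# ---------------------------------------------------------------------------
# phenotype simulation


def _pgs(xs: np.ndarray, causal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standardized polygenic score over ``causal`` columns of the
    standardized genotype matrix ``xs`` (i.i.d. normal effects)."""
    beta = rng.standard_normal(len(causal))
    g = xs[:, causal] @ beta
    sd = g.std()
    if sd == 0:
        return np.zeros(len(g))
    return (g - g.mean()) / sd


def _stratified_pgs(
    xs: np.ndarray,
    causal: np.ndarray,
    strata: np.ndarray,
    rg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared factor with stratum-specific SNP effects of correlation rg."""
    b0 = rng.standard_normal(len(causal))
    b1 = rg * b0 + np.sqrt(max(0.0, 1.0 - rg * rg)) * rng.standard_normal(len(causal))
    g0 = xs[:, causal] @ b0
    g1 = xs[:, causal] @ b1
    g0 = (g0 - g0.mean()) / g0.std()
    g1 = (g1 - g1.mean()) / g1.std()
    return np.where(strata == 0, g0, g1)


def simulate_phenotypes(
    panel: GenotypePanel, config: SimulationConfig
) -> CohortPhenotypes:
    """Generate subtype indicators, grouped status, quantitative traits,
    covariates and environment variables for ``panel``.

    Each subtype's liability is c_t * sqrt(h2_t) * G_shared +
    sqrt((1-c_t^2) h2_t) * G_specific_t + covariate effects + Gaussian
    residual, standardized to unit variance; case iff liability exceeds the
    (1 - K_t) normal quantile within the eligible sex.
    """
    if panel.n_samples != config.n_samples or panel.n_variants != config.n_variants:
        raise ValueError("panel and config dimensions disagree")
    n, m = panel.n_samples, panel.n_variants
    xs = panel.standardized()

    rng_arch = substream(config.master_seed, "architecture")
    rng_env = substream(config.master_seed, "environment")
    rng_res = substream(config.master_seed, "residuals")

    # covariates
    female = (panel.sex == "female").astype(float)
    if config.subtype_specs and not len(panel.sex):
        raise ValueError("sex restriction requested but panel lacks sex")
    age = rng_env.normal(57.0, 8.0, size=n)
    centre = rng_env.integers(1, 6, size=n)
    batch = rng_env.integers(1, 11, size=n)
    cov = config.covariate_spec
    zage = (age - age.mean()) / age.std()
    zsex = (female - female.mean()) / max(female.std(), 1e-12)
    zcentre = (centre - centre.mean()) / centre.std()
    zbatch = (batch - batch.mean()) / batch.std()
    cov_part = (
        cov.age_beta * zage
        + cov.sex_beta * zsex
        + cov.centre_beta * zcentre
        + cov.batch_beta * zbatch
    )
    var_cov = cov.variance()

    # environment
    gxe = config.gxe_spec
    env_binary = (rng_env.random(n) < 0.5).astype(int)
    env_quant = rng_env.standard_normal(n)

    # shared polygenic factor over a common causal set; each subtype-specific
    # and trait architecture draws its own random causal subset with
    # independent effects (independent draws are near-orthogonal, so rg
    # control does not require disjoint sets)
    n_shared = max((s.n_causal_shared for s in config.subtype_specs), default=400)
    n_shared = min(n_shared, m)
    shared_causal = np.sort(rng_arch.choice(m, n_shared, replace=False))
    if gxe.environment_type == "binary" and gxe.strata_rg < 1.0:
        g_shared = _stratified_pgs(
            xs, shared_causal, env_binary, gxe.strata_rg, rng_arch
        )
        g_shared = (g_shared - g_shared.mean()) / g_shared.std()
    else:
        g_shared = _pgs(xs, shared_causal, rng_arch)

    table = pd.DataFrame(index=pd.Index(panel.sample_ids, name="sample_id"))
    table["sex"] = panel.sex
    table["age"] = age
    table["centre"] = centre
    table["batch"] = batch
    table["env_binary"] = env_binary
    table["env_quant"] = env_quant

    truth: dict = {
        "shared_causal": shared_causal,
        "g_shared": g_shared,
        "liabilities": {},
        "config": config,
    }

    # subtypes
    subtype_names = []
    for spec in config.subtype_specs:
        ns = min(spec.n_causal_specific, m)
        spec_causal = np.sort(rng_arch.choice(m, ns, replace=False)) if ns else np.array([], int)
        c, h2 = spec.shared_loading, spec.liability_h2
        g_spec = _pgs(xs, spec_causal, rng_arch) if ns > 0 else np.zeros(n)
        g_part = np.sqrt(h2) * (c * g_shared + np.sqrt(max(0.0, 1 - c * c)) * g_spec)
        resid_var = max(0.0, (1.0 - var_cov) * (1.0 - h2))
        # genetic part scaled to variance h2*(1-var_cov); residual fills to 1
        liab = cov_part + np.sqrt(1.0 - var_cov) * g_part + rng_res.normal(
            0.0, np.sqrt(resid_var), size=n
        )
        liab = (liab - liab.mean()) / liab.std()
        thr = stats.norm.isf(spec.prevalence)
        status = (liab > thr).astype(float)
        if spec.sex_restriction == "female":
            status[panel.sex != "female"] = np.nan
        elif spec.sex_restriction == "male":
            status[panel.sex != "male"] = np.nan
        table[spec.name] = status
        truth["liabilities"][spec.name] = liab
        subtype_names.append(spec.name)

    sub = table[subtype_names]
    grouped = ((sub == 1).any(axis=1)).astype(int).to_numpy()
    table["grouped_status"] = grouped
    incident = np.zeros(n, dtype=int)
    cases = np.where(grouped == 1)[0]
    incident[cases] = (
        substream(config.master_seed, "incident").random(len(cases))
        < config.incident_fraction
    ).astype(int)
    table["incident_flag"] = incident

    # quantitative traits correlated with the shared factor
    for tspec in config.trait_specs:
        nt = min(tspec.n_causal, m)
        own_causal = np.sort(rng_arch.choice(m, nt, replace=False)) if nt else np.array([], int)
        g_own = _pgs(xs, own_causal, rng_arch) if nt > 0 else np.zeros(n)
        r = tspec.rg_with_grouped_liability
        g_trait = r * g_shared + np.sqrt(max(0.0, 1 - r * r)) * g_own
        sd = g_trait.std()
        if sd > 0:
            g_trait = (g_trait - g_trait.mean()) / sd
        y = np.sqrt(tspec.h2) * g_trait + rng_res.normal(
            0.0, np.sqrt(1.0 - tspec.h2), size=n
        )
        table[tspec.name] = y

    # quantitative GxE trait: y = G0 + E*G1 + tau*E*e0 + e
    ng = min(gxe.n_causal, m)
    gxe_causal = np.sort(rng_arch.permutation(m)[:ng])
    g0 = _pgs(xs, gxe_causal, rng_arch)
    g1 = _pgs(xs, gxe_causal, rng_arch)
    E = env_quant if gxe.environment_type == "quantitative" else (
        (env_binary - env_binary.mean()) / max(env_binary.std(), 1e-12)
    )
    e0 = rng_res.standard_normal(n)
    resid = np.sqrt(max(0.0, 1.0 - gxe.sigma2_g0 - gxe.sigma2_g1 - gxe.sigma2_tau1))
    y_gxe = (
        np.sqrt(gxe.sigma2_g0) * g0
        + E * np.sqrt(gxe.sigma2_g1) * g1
        + np.sqrt(gxe.sigma2_tau1) * E * e0
        + resid * rng_res.standard_normal(n)
    )
    table["gxe_trait"] = y_gxe
    truth["gxe_causal"] = gxe_causal
    truth["g0"] = g0
    truth["g1"] = g1

    pheno = CohortPhenotypes(table=table, subtype_names=subtype_names, truth=truth)
    pheno.validate()
    return pheno
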