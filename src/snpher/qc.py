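"""Genotype/sample QC cascade and genomic relationship matrix.

The filter order is fixed and logged: sample call rate -> SNP call rate ->
INFO -> MAF -> HWE (exact mid-p) -> strand-ambiguous/duplicate removal.
The GRM is the frequency-standardized estimator
A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._rng import substream
from .simulate import MISSING, GenotypePanel

__all__ = [
    "QcThresholds",
    "QcReport",
    "Grm",
    "hwe_exact_midp",
    "apply_qc",
    "compute_grm",
    "prune_related",
    "pc_outlier_filter",
    "discordance_filter",
]

logger = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class QcThresholds:
    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1.0e-7
    info_min: float = 0.6
    relatedness_max: float = 0.05
    pc_sd_limit: float = 6.0
    discordance_max: float = 0.05


@dataclass
class QcReport:
    """Removal counts per rule, in the order the rules were applied."""

    samples_call_rate: int = 0
    snps_call_rate: int = 0
    snps_info: int = 0
    snps_maf: int = 0
    snps_hwe: int = 0
    snps_ambiguous: int = 0
    snps_duplicate: int = 0
    log: list = field(default_factory=list)

    def total_snps_removed(self) -> int:
        return (
            self.snps_call_rate
            + self.snps_info
            + self.snps_maf
            + self.snps_hwe
            + self.snps_ambiguous
            + self.snps_duplicate
        )


@dataclass
class Grm:
    """Symmetric genomic relationship matrix over samples."""

    sample_ids: np.ndarray
    values: np.ndarray
    n_snps: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise ValueError("GRM not symmetric")

    def subset(self, idx) -> "Grm":
        idx = np.asarray(idx)
        return Grm(self.sample_ids[idx], self.values[np.ix_(idx, idx)], self.n_snps)


def hwe_exact_midp(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Mid-p exact Hardy-Weinberg test (Wigginton-style enumeration).

    Enumerates the conditional null distribution of the heterozygote count
    given the allele counts; returns the mid-p two-sided value (half the
    probability of the observed count plus the probability of all counts
    less likely than it).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # log P(het = h | allele counts) up to a constant, h with parity of n_rare
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    n_homr = (n_rare - hs) // 2
    n_homc = n - hs - n_homr
    valid = n_homc >= 0
    hs, n_homr, n_homc = hs[valid], n_homr[valid], n_homc[valid]
    logp = (
        hs * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hs + 1)
        - gammaln(n_homr + 1)
        - gammaln(n_homc + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hs == n_het][0]
    # relative tie tolerance: an absolute one would lump all tiny tail
    # probabilities in with the observed class
    tie = np.abs(p - obs) <= 1e-12 * obs
    return float(p[(p < obs) & ~tie].sum() + 0.5 * p[tie].sum())


def _genotype_counts(dosages: np.ndarray):
    obs = dosages != MISSING
    n2 = (dosages == 2).sum(0)
    n1 = (dosages == 1).sum(0)
    n0 = (dosages == 0).sum(0)
    return n0, n1, n2, obs


def apply_qc(
    panel: GenotypePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypePanel, QcReport]:
    """Apply the QC cascade; raises if everything is removed."""
    if panel.n_samples == 0 or panel.n_variants == 0:
        raise ValueError("empty panel")
    report = QcReport()
    d = panel.dosages

    # 1. sample call rate
    rate = (d != MISSING).mean(1)
    keep_s = rate >= thresholds.sample_call_rate_min
    report.samples_call_rate = int((~keep_s).sum())
    report.log.append(f"sample call rate: removed {report.samples_call_rate}")
    panel = panel.subset(sample_idx=np.where(keep_s)[0])
    if panel.n_samples == 0:
        raise ValueError("empty panel: all samples removed by call-rate filter")

    keep = np.ones(panel.n_variants, dtype=bool)
    d = panel.dosages

    # 2. SNP call rate
    crate = (d != MISSING).mean(0)
    drop = keep & (crate < thresholds.snp_call_rate_min)
    report.snps_call_rate = int(drop.sum())
    keep &= ~drop

    # 3. INFO score
    drop = keep & (panel.variants["info"].to_numpy() < thresholds.info_min)
    report.snps_info = int(drop.sum())
    keep &= ~drop

    # 4. MAF
    freq = panel.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    drop = keep & ~(maf >= thresholds.maf_min)
    report.snps_maf = int(drop.sum())
    keep &= ~drop

    # 5. HWE exact mid-p
    n0, n1, n2, _ = _genotype_counts(d)
    hwe_drop = np.zeros(panel.n_variants, dtype=bool)
    for j in np.where(keep)[0]:
        if hwe_exact_midp(int(n1[j]), int(n2[j]), int(n0[j])) < thresholds.hwe_p_min:
            hwe_drop[j] = True
    report.snps_hwe = int(hwe_drop.sum())
    keep &= ~hwe_drop

    # 6. strand-ambiguous and duplicate (chrom, pos, allele-set) SNPs
    v = panel.variants
    amb = np.array(
        [(a1, a2) in _AMBIGUOUS for a1, a2 in zip(v["a1"], v["a2"])], dtype=bool
    )
    drop = keep & amb
    report.snps_ambiguous = int(drop.sum())
    keep &= ~drop
    key = pd.Series(
        list(
            zip(
                v["chrom"],
                v["pos"],
                [frozenset((a, b)) for a, b in zip(v["a1"], v["a2"])],
            )
        )
    )
    dup = key.duplicated(keep="first").to_numpy()
    drop = keep & dup
    report.snps_duplicate = int(drop.sum())
    keep &= ~drop

    for name in (
        "snps_call_rate",
        "snps_info",
        "snps_maf",
        "snps_hwe",
        "snps_ambiguous",
        "snps_duplicate",
    ):
        report.log.append(f"{name}: removed {getattr(report, name)}")
        logger.info(report.log[-1])

    if not keep.any():
        raise ValueError("empty panel: all variants removed by QC")
    return panel.subset(variant_idx=np.where(keep)[0]), report


def compute_grm(panel: GenotypePanel, freqs=None) -> Grm:
    """Frequency-standardized GRM; missing dosages are mean-imputed first.

    ``freqs`` optionally fixes the allele-1 frequencies p_i (e.g. reference
    frequencies); by default they are estimated from the panel.
    """
    n_missing = int((panel.dosages == MISSING).sum())
    if n_missing:
        logger.info("compute_grm: mean-imputing %d missing dosages", n_missing)
    if freqs is None:
        x = panel.standardized()
    else:
        p = np.asarray(freqs, float)
        denom = np.sqrt(2.0 * p * (1.0 - p))
        if np.any(denom == 0):
            bad = panel.variants["snp"].values[denom == 0]
            raise ValueError(f"zero-variance SNP(s): {bad[:5].tolist()}")
        d = panel.dosages.astype(float)
        d[panel.dosages == MISSING] = np.nan
        d = np.where(np.isnan(d), 2.0 * p, d)
        x = (d - 2.0 * p) / denom
    a = (x @ x.T) / panel.n_variants
    a = (a + a.T) / 2.0
    return Grm(sample_ids=panel.sample_ids.copy(), values=a, n_snps=panel.n_variants)


def prune_related(grm: Grm, cutoff: float = 0.05, seed: int = 0) -> np.ndarray:
    """Greedily remove one member of each pair with relatedness > cutoff.

    Pairs are processed in descending relatedness; the removed member of a
    pair is a seeded random choice.  Returns the kept sample ids.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    grm.validate()
    rng = substream(seed, "prune_related")
    a = grm.values
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    over = a[iu] > cutoff
    order = np.argsort(-a[iu][over], kind="stable")
    pairs = np.column_stack([iu[0][over][order], iu[1][over][order]])
    removed = np.zeros(n, dtype=bool)
    for i, j in pairs:
        if removed[i] or removed[j]:
            continue
        removed[i if rng.random() < 0.5 else j] = True
    return grm.sample_ids[~removed]


def pc_outlier_filter(
    grm: Grm, n_pcs: int = 10, sd_limit: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Remove samples outside ``sd_limit`` SDs on PC1 or PC2.

    PCs are the leading eigenvectors of the GRM scaled by sqrt(eigenvalue);
    returns (kept sample ids, PC coordinates for all input samples).
    """
    n = grm.n_samples
    if n_pcs > n:
        raise ValueError("n_pcs exceeds GRM rank")
    w, v = np.linalg.eigh(grm.values)
    order = np.argsort(w)[::-1][:n_pcs]
    w, v = w[order], v[:, order]
    if w[0] < -1e-6 * abs(w).max():
        raise ValueError("GRM is not positive semi-definite")
    pcs = v * np.sqrt(np.maximum(w, 0.0))
    keep = np.ones(n, dtype=bool)
    for k in range(min(2, n_pcs)):
        z = (pcs[:, k] - pcs[:, k].mean()) / pcs[:, k].std()
        keep &= np.abs(z) <= sd_limit
    return grm.sample_ids[keep], pcs


def discordance_filter(
    panel_a: GenotypePanel, panel_b: GenotypePanel, max_rate: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Drop samples/variants whose genotype mismatch fraction between two
    releases exceeds ``max_rate`` (over jointly non-missing entries)."""
    sids = np.intersect1d(panel_a.sample_ids, panel_b.sample_ids)
    vids = np.intersect1d(panel_a.variants["snp"], panel_b.variants["snp"])
    if len(sids) == 0 or len(vids) == 0:
        raise ValueError("no overlap between panels")
    ia = pd.Index(panel_a.sample_ids).get_indexer(sids)
    ib = pd.Index(panel_b.sample_ids).get_indexer(sids)
    ja = pd.Index(panel_a.variants["snp"]).get_indexer(vids)
    jb = pd.Index(panel_b.variants["snp"]).get_indexer(vids)
    da = panel_a.dosages[np.ix_(ia, ja)]
    db = panel_b.dosages[np.ix_(ib, jb)]
    both = (da != MISSING) & (db != MISSING)
    mism = both & (da != db)
    with np.errstate(invalid="ignore"):
        sample_rate = np.where(both.sum(1) > 0, mism.sum(1) / both.sum(1), 0.0)
        variant_rate = np.where(both.sum(0) > 0, mism.sum(0) / both.sum(0), 0.0)
    return sids[sample_rate <= max_rate], vids[variant_rate <= max_rate]
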