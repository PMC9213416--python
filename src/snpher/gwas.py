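"""Per-SNP association scans, genomic-inflation diagnostics, LD clumping and
fixed-effect meta-analysis.

The scan supports logistic regression on a binary phenotype and a
linear-probability model on 0/1 (whose betas are the linear-scale magnitudes
association tables usually print); covariates are residualized once for the
linear mode.  P-values are two-sided normal tails of BETA/SE.

The genomic inflation factor lambda is the median association chi-square
divided by 0.4549364 (the median of a 1-df chi-square); lambda_1000 rescales
it to an equivalent study of 1000 cases and 1000 controls:

    lambda_1000 = 1 + (lambda - 1) * (1/n_cases + 1/n_controls)
                                     / (1/1000 + 1/1000)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MISSING, GenotypePanel

__all__ = [
    "CHI2_MEDIAN_1DF",
    "AssociationTable",
    "InflationSummary",
    "LocusTable",
    "association_scan",
    "genomic_inflation",
    "lambda_1000",
    "clump_loci",
    "meta_analyse_gwas",
    "to_sumstats",
]

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with one degree of freedom
CHI2_MEDIAN_1DF = 0.4549364

GENOME_WIDE_P = 5e-8


@dataclass
class AssociationTable:
    """Per-SNP association results with the standard column set
    (CHR BP SNP A1 P BETA STAT NMISS) plus SE."""

    table: pd.DataFrame
    model: str
    n_cases: int | None
    n_controls: int | None
    covariates: list[str] = field(default_factory=list)

    def validate(self) -> None:
        t = self.table.dropna(subset=["BETA", "SE"])
        ratio = t["BETA"] / t["SE"]
        if not np.allclose(ratio, t["STAT"], rtol=1e-6):
            raise ValueError("STAT != BETA/SE")
        p = 2.0 * stats.norm.sf(np.abs(t["STAT"]))
        ok = np.isclose(p, t["P"], rtol=1e-6) | (p < 1e-300)
        if not ok.all():
            raise ValueError("P inconsistent with STAT")

    def write(self, path) -> None:
        cols = ["CHR", "BP", "SNP", "A1", "P", "BETA", "STAT", "NMISS", "SE"]
        self.table[cols].to_csv(path, sep="\t", index=False)


@dataclass
class InflationSummary:
    lambda_observed: float
    lambda_1000: float
    n_cases: int
    n_controls: int
    median_chi2: float
    qq: pd.DataFrame  # expected / observed -log10 p


@dataclass
class LocusTable:
    """Lead SNPs of independent loci with their member SNPs."""

    table: pd.DataFrame  # one row per locus
    members: dict  # lead SNP id -> list of member SNP ids


def _logistic_fit(y, Xfull, max_iter=25, tol=1e-8):
    """IRLS logistic fit; returns (beta, se, separated_flag) for the last
    column of ``Xfull``."""
    n, p = Xfull.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9))
    for _ in range(max_iter):
        eta = Xfull @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if w.max() < 1e-12:
            return np.nan, np.nan, True
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        WX = Xfull * w[:, None]
        H = Xfull.T @ WX
        try:
            new = np.linalg.solve(H, WX.T @ z)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, True
        if np.abs(new - beta).max() < tol:
            beta = new
            break
        beta = new
    if np.abs(beta).max() > 30:
        return np.nan, np.nan, True
    eta = Xfull @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    H = Xfull.T @ (Xfull * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, True
    return beta[-1], np.sqrt(cov[-1, -1]), False


def association_scan(
    panel: GenotypePanel,
    phenotype,
    covariates=None,
    model: str = "linear",
    chunk: int = 2048,
) -> AssociationTable:
    """Scan phenotype ~ intercept + covariates + dosage(A1) per SNP.

    ``model`` is "linear" (linear-probability on 0/1 or a quantitative
    trait; covariates residualized once) or "logistic" (per-SNP IRLS).
    NMISS counts samples with an observed genotype; missing genotypes are
    dropped per SNP, not imputed.
    """
    y = np.asarray(phenotype, float).ravel()
    n = len(y)
    if covariates is None:
        C = np.ones((n, 1))
        cov_names: list[str] = []
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        C = np.column_stack([np.ones(n), cov])
        cov_names = [f"cov{i}" for i in range(cov.shape[1])]
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariates are rank-deficient")
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if model == "logistic" and not binary:
        raise ValueError("logistic model requires a binary phenotype")

    m = panel.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    nmiss = np.zeros(m, dtype=int)
    flags = np.zeros(m, dtype=bool)

    if model == "linear":
        Q, _ = np.linalg.qr(C)
        yr = y - Q @ (Q.T @ y)
        yss = yr @ yr
        dof = n - C.shape[1] - 1
        for start in range(0, m, chunk):
            cols = slice(start, min(start + chunk, m))
            d = panel.dosages[:, cols].astype(float)
            miss = d == MISSING
            has_missing = miss.any(0)
            nmiss[cols] = n - miss.sum(0)
            d[miss] = np.nan
            # fast path: complete SNPs, vectorized partialled regression
            dc = np.where(miss, 0.0, d)
            gr = dc - Q @ (Q.T @ dc)
            gss = np.einsum("ij,ij->j", gr, gr)
            gy = gr.T @ yr
            ok = (~has_missing) & (gss > 1e-12)
            b = np.where(gss > 0, gy / np.where(gss > 0, gss, 1.0), np.nan)
            rss = yss - b**2 * gss
            s2 = rss / dof
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.sqrt(s2 / gss)
            idx = np.where(ok)[0] + start
            beta[idx] = b[ok]
            se[idx] = s[ok]
            # slow path: per-SNP complete-case OLS
            for j in np.where(has_missing)[0]:
                col = start + j
                obs = ~miss[:, j]
                gj = d[obs, j]
                if gj.std() < 1e-9 or obs.sum() <= C.shape[1] + 1:
                    continue
                Xj = np.column_stack([C[obs], gj])
                XtX = Xj.T @ Xj
                coef = np.linalg.solve(XtX, Xj.T @ y[obs])
                resid = y[obs] - Xj @ coef
                s2j = resid @ resid / (obs.sum() - Xj.shape[1])
                covb = s2j * np.linalg.inv(XtX)
                beta[col] = coef[-1]
                se[col] = np.sqrt(covb[-1, -1])
            zero_var = (~has_missing) & (gss <= 1e-12)
            for j in np.where(zero_var)[0]:
                logger.info("zero-variance SNP skipped: %s",
                            panel.variants["snp"].iloc[start + j])
    elif model == "logistic":
        for col in range(m):
            d = panel.dosages[:, col].astype(float)
            obs = d != MISSING
            nmiss[col] = int(obs.sum())
            gj = d[obs]
            if gj.std() < 1e-9:
                logger.info("zero-variance SNP skipped: %s",
                            panel.variants["snp"].iloc[col])
                continue
            Xj = np.column_stack([C[obs], gj])
            b, s, sep = _logistic_fit(y[obs], Xj)
            if sep:
                flags[col] = True
            beta[col], se[col] = b, s
    else:
        raise ValueError(f"unknown model {model!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        stat = beta / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    v = panel.variants
    table = pd.DataFrame(
        {
            "CHR": v["chrom"].to_numpy(),
            "BP": v["pos"].to_numpy(),
            "SNP": v["snp"].to_numpy(),
            "A1": v["a1"].to_numpy(),
            "A2": v["a2"].to_numpy(),
            "P": p,
            "BETA": beta,
            "SE": se,
            "STAT": stat,
            "NMISS": nmiss,
            "FLAG_SEPARATION": flags,
        }
    )
    n_cases = int(y.sum()) if binary else None
    n_controls = int((y == 0).sum()) if binary else None
    return AssociationTable(
        table=table, model=model, n_cases=n_cases, n_controls=n_controls,
        covariates=cov_names,
    )


def lambda_1000(lam: float, n_cases: int, n_controls: int) -> float:
    """Rescale lambda to a 1000-case/1000-control equivalent study."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("need positive case and control counts")
    return 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)


def genomic_inflation(
    assoc: AssociationTable, n_cases: int, n_controls: int
) -> InflationSummary:
    """lambda from the median association chi-square, plus QQ data."""
    t = assoc.table.dropna(subset=["STAT"])
    if len(t) < 100:
        raise ValueError("need at least 100 SNPs for inflation diagnostics")
    chi2 = t["STAT"].to_numpy() ** 2
    med = float(np.median(chi2))
    lam = med / CHI2_MEDIAN_1DF
    p_sorted = np.sort(t["P"].to_numpy())
    k = len(p_sorted)
    expected = -np.log10((np.arange(1, k + 1) - 0.5) / k)
    observed = -np.log10(np.maximum(p_sorted, 1e-300))
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    return InflationSummary(
        lambda_observed=lam,
        lambda_1000=lambda_1000(lam, n_cases, n_controls),
        n_cases=n_cases,
        n_controls=n_controls,
        median_chi2=med,
        qq=qq,
    )


def _r2(panel: GenotypePanel, j: int, k: int) -> float:
    d = panel.dosages
    obs = (d[:, j] != MISSING) & (d[:, k] != MISSING)
    a, b = d[obs, j].astype(float), d[obs, k].astype(float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def clump_loci(
    assoc: AssociationTable,
    panel: GenotypePanel,
    p_threshold: float = GENOME_WIDE_P,
    clump_r2: float = 0.1,
    window_bp: int = 1_000_000,
) -> LocusTable:
    """Greedy LD clumping of significant SNPs into independent loci.

    Significant SNPs are sorted by ascending P (ties by CHR, BP, id); the top
    SNP leads a locus and absorbs all significant SNPs within ``window_bp``
    whose r-squared with it is at least ``clump_r2``.
    """
    t = assoc.table.dropna(subset=["P"])
    sig = t[t["P"] < p_threshold].copy()
    if sig.empty:
        return LocusTable(table=sig.assign(LOCUS=[]), members={})
    sig = sig.sort_values(["P", "CHR", "BP", "SNP"], kind="stable")
    snp_pos = pd.Index(panel.variants["snp"])
    col_of = {s: snp_pos.get_loc(s) for s in sig["SNP"]}
    unassigned = dict(zip(sig["SNP"], sig.index))
    leads = []
    members: dict[str, list[str]] = {}
    for snp in sig["SNP"]:
        if snp not in unassigned:
            continue
        row = sig.loc[unassigned.pop(snp)]
        leads.append(row)
        mem = []
        for other, oidx in list(unassigned.items()):
            orow = sig.loc[oidx]
            if orow["CHR"] != row["CHR"] or abs(orow["BP"] - row["BP"]) > window_bp:
                continue
            if _r2(panel, col_of[snp], col_of[other]) >= clump_r2:
                mem.append(other)
                del unassigned[other]
        members[snp] = mem
    out = pd.DataFrame(leads).reset_index(drop=True)
    out.insert(0, "LOCUS", np.arange(1, len(out) + 1))
    out["N_MEMBERS"] = [len(members[s]) + 1 for s in out["SNP"]]
    return LocusTable(table=out, members=members)


def meta_analyse_gwas(tables: list[AssociationTable]) -> AssociationTable:
    """Fixed-effect inverse-variance meta-analysis across scans.

    Alleles are harmonized to the first table's A1/A2 (betas sign-flipped at
    swapped-allele SNPs; irreconcilable SNPs dropped with a log entry).
    """
    if len(tables) == 1:
        return tables[0]
    ref = tables[0].table.set_index("SNP")
    num = pd.Series(0.0, index=ref.index)
    den = pd.Series(0.0, index=ref.index)
    nmiss = pd.Series(0, index=ref.index)
    dropped: set[str] = set()
    for at in tables:
        t = at.table.set_index("SNP")
        common = ref.index.intersection(t.index)
        t = t.loc[common]
        r = ref.loc[common]
        same = (t["A1"] == r["A1"]) & (t["A2"] == r["A2"])
        flipped = (t["A1"] == r["A2"]) & (t["A2"] == r["A1"])
        bad = ~(same | flipped)
        for s in common[bad]:
            dropped.add(s)
            logger.info("meta: irreconcilable alleles at %s; dropped", s)
        sign = np.where(flipped, -1.0, 1.0)
        w = 1.0 / t["SE"] ** 2
        ok = (~bad) & np.isfinite(w)
        num.loc[common[ok]] += (sign * w * t["BETA"])[ok]
        den.loc[common[ok]] += w[ok]
        nmiss.loc[common[ok]] += t["NMISS"][ok]
    keep = (den > 0) & ~ref.index.isin(dropped)
    beta = num[keep] / den[keep]
    se = 1.0 / np.sqrt(den[keep])
    stat = beta / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    out = ref.loc[keep, ["CHR", "BP", "A1", "A2"]].copy()
    out["P"], out["BETA"], out["SE"], out["STAT"] = p, beta, se, stat
    out["NMISS"] = nmiss[keep]
    out = out.reset_index()
    return AssociationTable(
        table=out, model="meta", n_cases=None, n_controls=None,
        covariates=[],
    )


def to_sumstats(assoc: AssociationTable, n: int | None = None) -> pd.DataFrame:
    """(SNP, A1, A2, N, Z) layout consumable by the LD-score module."""
    t = assoc.table
    N = n if n is not None else t["NMISS"]
    return pd.DataFrame(
        {"SNP": t["SNP"], "A1": t["A1"], "A2": t["A2"], "N": N, "Z": t["STAT"]}
    )
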