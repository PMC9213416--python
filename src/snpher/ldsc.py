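"""LD-score computation and summary-statistics regression.

LD score of SNP j: l_j = sum over SNPs k in a physical window of the
small-sample-adjusted squared correlation r~2 = r2 - (1 - r2)/(n - 2),
with the self term included as 1.

Univariate regression: E[chi2_j] = N h2 / M * l_j + intercept; h2_observed =
slope * M / mean(N).  Cross-trait: E[Z_A Z_B] = sqrt(N_A N_B) gcov / M * l_j
+ intercept, where the intercept absorbs sample overlap; rg =
gcov / sqrt(h2_A h2_B).  Standard errors come from a delete-one block
jackknife over contiguous SNP blocks.

GxEsum: the chi-square of a per-SNP interaction term follows
E[chi2_j | l_j] = N sigma2_g1 / M * l_j + 1 + 2 (sigma2_g1 + sigma2_tau1),
so regressing interaction chi-squares on LD scores yields the GxE variance
sigma2_g1 = slope * M / N and the residual-heterogeneity (scale) variance
sigma2_tau1 = (intercept - 1)/2 - sigma2_g1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .greml import GeneticCorrelationEstimate, HeritabilityEstimate, observed_to_liability
from .simulate import GenotypePanel

__all__ = [
    "LdScoreTable",
    "LdscFit",
    "GxEsumFit",
    "compute_ld_scores",
    "LdscRegression",
    "ldsc_h2",
    "ldsc_rg",
    "interaction_scan",
    "GxEsumRegression",
    "gxesum_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class LdScoreTable:
    table: pd.DataFrame  # snp, chrom, pos, l2

    def validate(self, n: int, window_size: int) -> None:
        floor = 1.0 - window_size / max(n - 2, 1)
        if (self.table["l2"] < floor - 1e-9).any():
            raise ValueError("LD score below the adjusted-estimator floor")


@dataclass
class LdscFit:
    slope: float
    intercept: float
    intercept_se: float
    h2_observed: float
    h2_se: float
    M: int
    mean_chi2: float
    n_blocks: int
    n_snps: int
    mean_N: float
    h2_liability: float | None = None
    h2_liability_se: float | None = None


@dataclass
class GxEsumFit:
    sigma2_g1: float
    sigma2_g1_se: float
    sigma2_tau1: float
    sigma2_tau1_se: float
    slope: float
    intercept: float
    N: float
    M: int
    n_blocks: int
    p_value: float
    boundary: bool = False


def compute_ld_scores(
    panel: GenotypePanel, window_bp: int = 1_000_000, chunk: int = 512
) -> LdScoreTable:
    """Adjusted LD scores over a physical window, per chromosome."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n = panel.n_samples
    xs = panel.standardized()
    xs = (xs - xs.mean(0)) / np.maximum(xs.std(0), 1e-12)
    v = panel.variants
    l2 = np.zeros(panel.n_variants)
    for chrom in v["chrom"].unique():
        idx = np.where(v["chrom"].to_numpy() == chrom)[0]
        # input row order is arbitrary: work in position order
        idx = idx[np.argsort(v["pos"].to_numpy()[idx], kind="stable")]
        pos = v["pos"].to_numpy()[idx]
        Xc = xs[:, idx]
        mc = len(idx)
        for s in range(0, mc, chunk):
            e = min(s + chunk, mc)
            lo = np.searchsorted(pos, pos[s] - window_bp)
            hi = np.searchsorted(pos, pos[e - 1] + window_bp, side="right")
            R = (Xc[:, s:e].T @ Xc[:, lo:hi]) / n
            r2 = R**2
            adj = r2 - (1.0 - r2) / (n - 2)
            # zero out pairs outside each SNP's own window
            pj = pos[s:e][:, None]
            pk = pos[lo:hi][None, :]
            adj[np.abs(pj - pk) > window_bp] = 0.0
            # replace self term (r2 = 1 exactly)
            own = np.arange(s, e) - lo
            adj[np.arange(e - s), own] = 1.0
            l2[idx[s:e]] = adj.sum(1)
    out = pd.DataFrame(
        {"snp": v["snp"], "chrom": v["chrom"], "pos": v["pos"], "l2": l2}
    )
    return LdScoreTable(table=out)


# ---------------------------------------------------------------------------
# jackknife helpers


def _block_bounds(m: int, n_blocks: int) -> list[slice]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _jackknife_wls(x, y, w, n_blocks):
    """Weighted regression of y on [1, x] with delete-one-block jackknife.

    Returns (coef (intercept, slope), per-block leave-one-out coefs)."""
    X = np.column_stack([np.ones(len(x)), x])
    XtX = X.T @ (X * w[:, None])
    Xty = X.T @ (w * y)
    coef = np.linalg.solve(XtX, Xty)
    blocks = _block_bounds(len(x), n_blocks)
    loo = np.empty((len(blocks), 2))
    for i, sl in enumerate(blocks):
        Xb = X[sl]
        XtXb = Xb.T @ (Xb * w[sl, None])
        Xtyb = Xb.T @ (w[sl] * y[sl])
        loo[i] = np.linalg.solve(XtX - XtXb, Xty - Xtyb)
    return coef, loo


def _jackknife_se(loo: np.ndarray) -> np.ndarray:
    k = loo.shape[0]
    return np.sqrt((k - 1) / k * ((loo - loo.mean(0)) ** 2).sum(0))


def _n_blocks_for(m: int, requested: int) -> int:
    if m < 2000:
        return max(2, min(requested, m // 10))
    return requested


# ---------------------------------------------------------------------------
# univariate h2


class LdscRegression(BaseEstimator):
    """LD-score regression estimator for SNP heritability.

    Parameters: ``n_blocks`` jackknife blocks (reduced automatically below
    2000 SNPs), ``chi2_max`` outlier cutoff (None disables; default
    max(80, 0.001 N)), ``constrain_intercept`` pins the intercept at 1.

    After ``fit(sumstats, ldscores, M)``: ``h2_``, ``h2_se_``,
    ``intercept_``, ``fit_`` (:class:`LdscFit`).
    """

    def __init__(self, n_blocks=200, chi2_max="auto", constrain_intercept=False):
        self.n_blocks = n_blocks
        self.chi2_max = chi2_max
        self.constrain_intercept = constrain_intercept

    def fit(self, sumstats: pd.DataFrame, ldscores: LdScoreTable, M: int | None = None):
        merged = sumstats.merge(
            ldscores.table[["snp", "l2"]], left_on="SNP", right_on="snp"
        )
        if merged.empty:
            raise ValueError("no SNPs shared between sumstats and LD scores")
        if len(merged) < 200:
            raise ValueError("need at least 200 SNPs for LDSC")
        merged = merged.dropna(subset=["Z"])
        chi2 = merged["Z"].to_numpy() ** 2
        N = merged["N"].to_numpy().astype(float)
        if self.chi2_max == "auto":
            cut = max(80.0, 0.001 * N.mean())
        else:
            cut = self.chi2_max
        if cut is not None:
            keep = chi2 <= cut
            merged, chi2, N = merged[keep], chi2[keep], N[keep]
        ell = merged["l2"].to_numpy()
        M = int(M if M is not None else len(merged))
        w = 1.0 / np.maximum(ell, 1.0)
        nb = _n_blocks_for(len(merged), self.n_blocks)
        x = N * ell / M
        if self.constrain_intercept:
            yy = chi2 - 1.0
            num = np.sum(w * x * yy)
            den = np.sum(w * x * x)
            slope = num / den
            blocks = _block_bounds(len(x), nb)
            loo_slope = np.array(
                [
                    (num - np.sum(w[s] * x[s] * yy[s]))
                    / (den - np.sum(w[s] * x[s] * x[s]))
                    for s in blocks
                ]
            )
            loo = np.column_stack([np.ones(len(blocks)), loo_slope])
            coef = np.array([1.0, slope])
        else:
            coef, loo = _jackknife_wls(x, chi2, w, nb)
        ses = _jackknife_se(loo)
        # slope of chi2 on N*l/M is h2 directly
        h2 = float(coef[1])
        self.h2_ = h2
        self.h2_se_ = float(ses[1])
        self.intercept_ = float(coef[0])
        self.fit_ = LdscFit(
            slope=float(coef[1] * N.mean() / M),
            intercept=float(coef[0]),
            intercept_se=float(ses[0]),
            h2_observed=h2,
            h2_se=float(ses[1]),
            M=M,
            mean_chi2=float(chi2.mean()),
            n_blocks=len(loo),
            n_snps=len(merged),
            mean_N=float(N.mean()),
        )
        self._loo_h2 = loo[:, 1]
        return self


def ldsc_h2(
    sumstats: pd.DataFrame,
    ldscores: LdScoreTable,
    M: int | None = None,
    K: float | None = None,
    P: float | None = None,
    **opts,
) -> LdscFit:
    """Functional wrapper; optional liability-scale conversion via (K, P)."""
    reg = LdscRegression(**opts).fit(sumstats, ldscores, M)
    fit = reg.fit_
    if K is not None:
        est = HeritabilityEstimate(
            sigma_g=np.nan, sigma_g_se=np.nan, sigma_e=np.nan, sigma_e_se=np.nan,
            h2_observed=fit.h2_observed, h2_se=fit.h2_se, loglik=np.nan,
            n_iter=0, converged=True, n=int(fit.mean_N), p_value=np.nan,
        )
        lia = observed_to_liability(est, K, P)
        fit.h2_liability = lia.h2_liability
        fit.h2_liability_se = lia.se
    return fit


# ---------------------------------------------------------------------------
# cross-trait rg


def _harmonize(sa: pd.DataFrame, sb: pd.DataFrame) -> pd.DataFrame:
    m = sa.merge(sb, on="SNP", suffixes=("_a", "_b"))
    same = (m["A1_a"] == m["A1_b"]) & (m["A2_a"] == m["A2_b"])
    flip = (m["A1_a"] == m["A2_b"]) & (m["A2_a"] == m["A1_b"])
    m = m[same | flip].copy()
    m.loc[flip[same | flip], "Z_b"] *= -1.0
    return m


def ldsc_rg(
    sumstats_a: pd.DataFrame,
    sumstats_b: pd.DataFrame,
    ldscores: LdScoreTable,
    M: int | None = None,
    n_blocks: int = 200,
) -> GeneticCorrelationEstimate:
    """Cross-trait LD-score regression genetic correlation.

    The cross-trait intercept absorbs shared-sample/shared-control
    covariance, so overlapping designs are unbiased.  rg is undefined (with
    a reason) when either trait's h2 estimate is non-positive.
    """
    m = _harmonize(sumstats_a, sumstats_b)
    merged = m.merge(ldscores.table[["snp", "l2"]], left_on="SNP", right_on="snp")
    merged = merged.dropna(subset=["Z_a", "Z_b"])
    if len(merged) < 200:
        raise ValueError("need at least 200 shared SNPs for cross-trait LDSC")
    ell = merged["l2"].to_numpy()
    za, zb = merged["Z_a"].to_numpy(), merged["Z_b"].to_numpy()
    Na, Nb = merged["N_a"].to_numpy().astype(float), merged["N_b"].to_numpy().astype(float)
    M = int(M if M is not None else len(merged))
    w = 1.0 / np.maximum(ell, 1.0)
    nb = _n_blocks_for(len(merged), n_blocks)
    blocks = _block_bounds(len(merged), nb)

    def moments(x, y):
        X = np.column_stack([np.ones(len(x)), x])
        XtX = X.T @ (X * w[:, None])
        Xty = X.T @ (w * y)
        per_XtX = np.stack([X[s].T @ (X[s] * w[s, None]) for s in blocks])
        per_Xty = np.stack([X[s].T @ (w[s] * y[s]) for s in blocks])
        return XtX, Xty, per_XtX, per_Xty

    xa = Na * ell / M
    xb = Nb * ell / M
    xab = np.sqrt(Na * Nb) * ell / M
    ma = moments(xa, za**2)
    mb = moments(xb, zb**2)
    mab = moments(xab, za * zb)

    def solve_all(mm, drop=None):
        XtX, Xty, pX, py = mm
        if drop is None:
            return np.linalg.solve(XtX, Xty)
        return np.linalg.solve(XtX - pX[drop], Xty - py[drop])

    def rg_of(drop=None):
        ca = solve_all(ma, drop)
        cb = solve_all(mb, drop)
        cab = solve_all(mab, drop)
        h2a, h2b, gcov = ca[1], cb[1], cab[1]
        if h2a <= 0 or h2b <= 0:
            return None, (h2a, h2b, gcov, cab[0])
        return gcov / np.sqrt(h2a * h2b), (h2a, h2b, gcov, cab[0])

    rg_full, (h2a, h2b, gcov, xint) = rg_of()
    if rg_full is None:
        return GeneticCorrelationEstimate(
            rg=None, rg_raw=None, se=None, sigma_g12=float(gcov),
            h2_1=None, h2_2=None, p_zero=None, p_one=None, test="jackknife",
            reason="non-positive h2 estimate; rg not estimable",
        )
    loo, loo_int = [], []
    for i in range(len(blocks)):
        r, (_, _, _, xi) = rg_of(i)
        loo.append(r if r is not None else rg_full)
        loo_int.append(xi)
    loo, loo_int = np.array(loo), np.array(loo_int)
    k = len(loo)
    se = float(np.sqrt((k - 1) / k * ((loo - loo.mean()) ** 2).sum()))
    xint_se = float(np.sqrt((k - 1) / k * ((loo_int - loo_int.mean()) ** 2).sum()))
    clamped = abs(rg_full) > 1
    p0 = float(2 * stats.norm.sf(abs(rg_full / se))) if se > 0 else None
    p1 = float(2 * stats.norm.sf(abs((rg_full - 1) / se))) if se > 0 else None

    def h2_est(h2, who):
        return HeritabilityEstimate(
            sigma_g=np.nan, sigma_g_se=np.nan, sigma_e=np.nan, sigma_e_se=np.nan,
            h2_observed=float(h2), h2_se=np.nan, loglik=np.nan, n_iter=0,
            converged=True, n=int(who.mean()), p_value=np.nan,
        )

    return GeneticCorrelationEstimate(
        rg=float(np.clip(rg_full, -1, 1)), rg_raw=float(rg_full), se=se,
        sigma_g12=float(gcov), h2_1=h2_est(h2a, Na), h2_2=h2_est(h2b, Nb),
        p_zero=p0, p_one=p1, test="jackknife", clamped=clamped,
        cross_intercept=float(xint), cross_intercept_se=xint_se,
    )


# ---------------------------------------------------------------------------
# interaction scan and GxEsum


def interaction_scan(
    panel: GenotypePanel,
    phenotype,
    environment,
    covariates=None,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Per-SNP model y ~ covariates + E + g + g*E; returns (SNP, A1, A2, N,
    Z) for the interaction coefficient.

    E is standardized internally; the SNP and environment main effects are
    always included.
    """
    y = np.asarray(phenotype, float).ravel()
    E = np.asarray(environment, float).ravel()
    if E.std() == 0:
        raise ValueError("environment is constant")
    E = (E - E.mean()) / E.std()
    n = len(y)
    base = [np.ones(n), E]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        base.append(cov)
    C = np.column_stack(base)
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    m = panel.n_variants
    z = np.full(m, np.nan)
    dof = n - C.shape[1] - 2
    xs = panel.standardized()
    for s in range(0, m, chunk):
        e = min(s + chunk, m)
        G = xs[:, s:e]
        GE = G * E[:, None]
        Gr = G - Q @ (Q.T @ G)
        Qr = GE - Q @ (Q.T @ GE)
        a = np.einsum("ij,ij->j", Gr, Gr)
        b = np.einsum("ij,ij->j", Gr, Qr)
        c = np.einsum("ij,ij->j", Qr, Qr)
        d1 = Gr.T @ yr
        d2 = Qr.T @ yr
        det = a * c - b * b
        ok = det > 1e-10
        beta_g = np.where(ok, (c * d1 - b * d2) / np.where(ok, det, 1), np.nan)
        beta_i = np.where(ok, (a * d2 - b * d1) / np.where(ok, det, 1), np.nan)
        rss = (
            np.einsum("i,i->", yr, yr)
            - beta_g * d1
            - beta_i * d2
        )
        s2 = rss / dof
        var_i = s2 * a / np.where(ok, det, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z[s:e] = beta_i / np.sqrt(var_i)
    v = panel.variants
    return pd.DataFrame(
        {"SNP": v["snp"], "A1": v["a1"], "A2": v["a2"], "N": n, "Z": z}
    )


class GxEsumRegression(BaseEstimator):
    """GxE variance from interaction-term summary statistics.

    Fits chi2_j = b0 + b1 l_j by weighted least squares and inverts the
    GxEsum expectation: sigma2_g1 = b1 M / N, sigma2_tau1 = (b0 - 1)/2 -
    sigma2_g1.  Jackknife SEs; Wald p for sigma2_g1 = 0.
    """

    def __init__(self, n_blocks=200, chi2_max="auto"):
        self.n_blocks = n_blocks
        self.chi2_max = chi2_max

    def fit(
        self,
        sumstats: pd.DataFrame,
        ldscores: LdScoreTable,
        N: float | None = None,
        M: int | None = None,
    ):
        merged = sumstats.merge(
            ldscores.table[["snp", "l2"]], left_on="SNP", right_on="snp"
        ).dropna(subset=["Z"])
        if len(merged) < 200:
            raise ValueError("need at least 200 SNPs for GxEsum")
        chi2 = merged["Z"].to_numpy() ** 2
        Nv = float(N if N is not None else merged["N"].mean())
        if self.chi2_max == "auto":
            cut = max(80.0, 0.001 * Nv)
        else:
            cut = self.chi2_max
        if cut is not None:
            keep = chi2 <= cut
            merged, chi2 = merged[keep], chi2[keep]
        ell = merged["l2"].to_numpy()
        M = int(M if M is not None else len(merged))
        w = 1.0 / np.maximum(ell, 1.0)
        nb = _n_blocks_for(len(merged), self.n_blocks)
        coef, loo = _jackknife_wls(ell, chi2, w, nb)
        b0, b1 = coef

        def invert(c):
            s_g1 = c[1] * M / Nv
            s_t1 = (c[0] - 1.0) / 2.0 - s_g1
            return np.array([s_g1, s_t1])

        est = invert(coef)
        loo_inv = np.apply_along_axis(invert, 1, loo)
        ses = _jackknife_se(loo_inv)
        boundary = b0 < 1.0
        if boundary:
            logger.info("GxEsum intercept < 1: sigma2_tau1 negative (boundary)")
        zstat = est[0] / ses[0] if ses[0] > 0 else np.nan
        self.fit_ = GxEsumFit(
            sigma2_g1=float(est[0]),
            sigma2_g1_se=float(ses[0]),
            sigma2_tau1=float(est[1]),
            sigma2_tau1_se=float(ses[1]),
            slope=float(b1),
            intercept=float(b0),
            N=Nv,
            M=M,
            n_blocks=loo.shape[0],
            p_value=float(2 * stats.norm.sf(abs(zstat))) if np.isfinite(zstat) else np.nan,
            boundary=boundary,
        )
        self.sigma2_g1_ = self.fit_.sigma2_g1
        self.sigma2_tau1_ = self.fit_.sigma2_tau1
        return self


def gxesum_fit(
    sumstats: pd.DataFrame,
    ldscores: LdScoreTable,
    N: float | None = None,
    M: int | None = None,
    **opts,
) -> GxEsumFit:
    """Functional wrapper over :class:`GxEsumRegression`."""
    return GxEsumRegression(**opts).fit(sumstats, ldscores, N, M).fit_
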