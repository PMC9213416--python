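"""Variance-component estimation by AI-REML on a genomic relationship matrix.

Univariate model: y = Xb + a + e with a ~ N(0, A sigma2_g), e ~ N(0, I
sigma2_e); the SNP heritability on the observed scale is
sigma2_g / (sigma2_g + sigma2_e).  Binary disease traits are analysed as 0/1
responses under this linear mixed model and the estimate transformed to the
liability scale afterwards.

The bivariate model adds a second trait measured on the same samples (with a
residual covariance) or on disjoint strata (no residual covariance; this is
the stratified gene-environment interaction design), and reports the genetic
correlation rg = sigma_g12 / sqrt(sigma2_g1 sigma2_g2) with Wald tests
against rg = 0 and rg = 1 and an optional likelihood-ratio test.

Maximization runs EM warm-up iterations followed by average-information (AI)
updates with step halving; standard errors come from the inverse AI matrix
and the delta method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .qc import Grm

__all__ = [
    "RemlModel",
    "HeritabilityEstimate",
    "LiabilityEstimate",
    "GeneticCorrelationEstimate",
    "MetaEstimate",
    "GREML",
    "BivariateGREML",
    "reml_fit",
    "bivariate_reml",
    "observed_to_liability",
    "liability_multiplier",
    "gxe_stratified",
    "split_meta",
]

logger = logging.getLogger(__name__)


@dataclass
class RemlModel:
    """Response, fixed-effects design and GRM for one trait."""

    y: np.ndarray
    X: np.ndarray | None
    grm: Grm

    def design(self) -> np.ndarray:
        X = self.X
        n = len(self.y)
        if X is None:
            return np.ones((n, 1))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        if not np.any(np.all(X == X[0], axis=0)):
            X = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effects design X is singular")
        return X


@dataclass
class HeritabilityEstimate:
    sigma_g: float
    sigma_g_se: float
    sigma_e: float
    sigma_e_se: float
    h2_observed: float
    h2_se: float
    loglik: float
    n_iter: int
    converged: bool
    n: int
    p_value: float
    non_identified: bool = False
    scale: str = "observed"


@dataclass
class LiabilityEstimate:
    h2_liability: float
    se: float
    K: float
    P: float
    z: float
    threshold: float
    p_value: float
    scale: str = "liability"


@dataclass
class GeneticCorrelationEstimate:
    rg: float | None
    rg_raw: float | None
    se: float | None
    sigma_g12: float
    h2_1: HeritabilityEstimate | None
    h2_2: HeritabilityEstimate | None
    p_zero: float | None
    p_one: float | None
    test: str
    clamped: bool = False
    reason: str | None = None
    lrt_stat: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None
    # cross-trait LDSC only: intercept absorbing sample/control overlap
    cross_intercept: float | None = None
    cross_intercept_se: float | None = None


@dataclass
class MetaEstimate:
    estimate: float
    se: float
    p_value: float
    fisher_stat: float
    k: int


# ---------------------------------------------------------------------------
# univariate GREML (eigen-rotation path)


class GREML(BaseEstimator):
    """Univariate GREML estimator.

    Parameters
    ----------
    max_iter : maximum REML iterations.
    tol : convergence tolerance on the change in restricted log-likelihood.
    n_em : EM warm-up iterations before switching to AI updates.
    var_floor_frac : variance-component floor as a fraction of Var(y).

    Attributes (after ``fit``)
    --------------------------
    sigma_g_, sigma_e_ : variance components.
    h2_, h2_se_ : observed-scale heritability and its delta-method SE.
    loglik_, n_iter_, converged_ : optimizer state.
    estimate_ : the full :class:`HeritabilityEstimate`.
    """

    def __init__(self, max_iter=100, tol=1e-6, n_em=2, var_floor_frac=1e-6):
        self.max_iter = max_iter
        self.tol = tol
        self.n_em = n_em
        self.var_floor_frac = var_floor_frac

    def fit(self, y, X=None, *, grm: Grm):
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if n < 50:
            raise ValueError("GREML requires n >= 50")
        if grm.values.shape[0] != n:
            raise ValueError("GRM and response are not aligned")
        Xd = RemlModel(y, X, grm).design()
        p = Xd.shape[1]

        w, U = np.linalg.eigh(grm.values)
        yt = U.T @ y
        Xt = U.T @ Xd

        # OLS residual variance for initialization and the floor
        beta0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        vp = np.var(y - Xd @ beta0) * n / max(n - p, 1)
        floor = self.var_floor_frac * vp

        non_identified = w.max() - w.min() < 1e-8
        if non_identified:
            warnings.warn("GRM is (near) identity: non-identified split")
            est = HeritabilityEstimate(
                sigma_g=vp / 2, sigma_g_se=np.nan, sigma_e=vp / 2,
                sigma_e_se=np.nan, h2_observed=np.nan, h2_se=np.nan,
                loglik=np.nan, n_iter=0, converged=True, n=n,
                p_value=np.nan, non_identified=True,
            )
            self._finalize(est)
            return self

        theta = np.array([vp / 2, vp / 2])

        def reml_parts(th):
            v = th[0] * w + th[1]
            if np.any(v <= 0):
                return None
            D = 1.0 / v
            XtD = Xt * D[:, None]
            C = Xt.T @ XtD
            cf = linalg.cho_factor(C)
            alpha = linalg.cho_solve(cf, XtD.T @ yt)
            Py = D * yt - XtD @ alpha
            yPy = yt @ Py
            logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
            ll = -0.5 * (np.sum(np.log(v)) + logdetC + yPy)
            return {"D": D, "XtD": XtD, "C": C, "cf": cf, "Py": Py, "ll": ll}

        def traces(parts):
            D, XtD, cf = parts["D"], parts["XtD"], parts["cf"]
            # tr(P M) for M = diag(w) and M = I
            Tg = XtD.T @ (XtD * w[:, None])
            Te = XtD.T @ XtD
            tr_g = np.sum(w * D) - np.trace(linalg.cho_solve(cf, Tg))
            tr_e = np.sum(D) - np.trace(linalg.cho_solve(cf, Te))
            return tr_g, tr_e

        def apply_P(parts, u):
            D, XtD, cf = parts["D"], parts["XtD"], parts["cf"]
            return D * u - XtD @ linalg.cho_solve(cf, XtD.T @ u)

        parts = reml_parts(theta)
        ll_old = parts["ll"]
        converged = False
        it = 0
        AI = np.eye(2)
        for it in range(1, self.max_iter + 1):
            Py = parts["Py"]
            tr_g, tr_e = traces(parts)
            quad_g = Py @ (w * Py)
            quad_e = Py @ Py
            score = -0.5 * np.array([tr_g - quad_g, tr_e - quad_e])
            if it <= self.n_em:
                delta = (theta**2) * np.array(
                    [quad_g - tr_g, quad_e - tr_e]
                ) / n
            else:
                u_g, u_e = w * Py, Py
                Pu_g, Pu_e = apply_P(parts, u_g), apply_P(parts, u_e)
                AI = 0.5 * np.array(
                    [[u_g @ Pu_g, u_g @ Pu_e], [u_e @ Pu_g, u_e @ Pu_e]]
                )
                try:
                    delta = np.linalg.solve(AI, score)
                except np.linalg.LinAlgError:
                    delta = score / max(np.trace(AI) / 2, 1.0)
            # step halving
            for _ in range(30):
                prop = np.maximum(theta + delta, floor)
                new_parts = reml_parts(prop)
                if new_parts is not None and (
                    it <= self.n_em or new_parts["ll"] >= ll_old - 1e-9
                ):
                    break
                delta = delta / 2.0
            theta, parts = prop, new_parts
            ll_new = parts["ll"]
            if abs(ll_new - ll_old) < self.tol:
                converged = True
                ll_old = ll_new
                break
            ll_old = ll_new

        if not converged:
            warnings.warn("GREML did not converge; returning last iterate")

        # final AI for SEs
        Py = parts["Py"]
        u_g, u_e = w * Py, Py
        Pu_g, Pu_e = apply_P(parts, u_g), apply_P(parts, u_e)
        AI = 0.5 * np.array([[u_g @ Pu_g, u_g @ Pu_e], [u_e @ Pu_g, u_e @ Pu_e]])
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        sg, se_ = theta
        tot = sg + se_
        h2 = sg / tot
        grad = np.array([se_, -sg]) / tot**2
        h2_var = grad @ cov @ grad
        h2_se = float(np.sqrt(h2_var)) if h2_var > 0 else np.nan
        z = h2 / h2_se if h2_se and np.isfinite(h2_se) and h2_se > 0 else np.nan
        est = HeritabilityEstimate(
            sigma_g=float(sg),
            sigma_g_se=float(np.sqrt(max(cov[0, 0], 0.0))),
            sigma_e=float(se_),
            sigma_e_se=float(np.sqrt(max(cov[1, 1], 0.0))),
            h2_observed=float(np.clip(h2, 0.0, 1.0)),
            h2_se=h2_se,
            loglik=float(ll_old),
            n_iter=it,
            converged=converged,
            n=n,
            p_value=float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        )
        self._finalize(est)
        return self

    def _finalize(self, est: HeritabilityEstimate):
        self.estimate_ = est
        self.sigma_g_ = est.sigma_g
        self.sigma_e_ = est.sigma_e
        self.h2_ = est.h2_observed
        self.h2_se_ = est.h2_se
        self.loglik_ = est.loglik
        self.n_iter_ = est.n_iter
        self.converged_ = est.converged


def reml_fit(model: RemlModel, **opts) -> HeritabilityEstimate:
    """Functional wrapper over :class:`GREML`."""
    return GREML(**opts).fit(model.y, model.X, grm=model.grm).estimate_


# ---------------------------------------------------------------------------
# liability transformation


def liability_multiplier(K: float, P: float) -> float:
    """Observed -> liability scale factor K^2 (1-K)^2 / (P (1-P) z^2),
    which reduces to K (1-K) / z^2 when K = P."""
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ValueError("K and P must be in (0, 1)")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    return K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2)


def observed_to_liability(
    est: HeritabilityEstimate, K: float, P: float | None = None
) -> LiabilityEstimate:
    """Transform an observed-scale estimate to the liability scale.

    ``K`` is the population lifetime prevalence; ``P`` the sample case
    proportion (defaults to K, the same-prevalence convention)."""
    if P is None:
        P = K
    mult = liability_multiplier(K, P)
    t = stats.norm.isf(K)
    h2_l = est.h2_observed * mult
    se_l = est.h2_se * mult
    z = h2_l / se_l if se_l and np.isfinite(se_l) and se_l > 0 else np.nan
    return LiabilityEstimate(
        h2_liability=h2_l,
        se=se_l,
        K=K,
        P=P,
        z=float(stats.norm.pdf(t)),
        threshold=float(t),
        p_value=float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
    )


# ---------------------------------------------------------------------------
# bivariate GREML (dense AI-REML; overlapping samples or disjoint strata)


class BivariateGREML(BaseEstimator):
    """Bivariate AI-REML for two traits sharing a GRM.

    The traits may be measured on the identical sample set (a residual
    covariance is then estimated) or on disjoint strata (the stratified GxE
    design; no residual covariance).  ``fit`` takes per-trait responses,
    designs and integer indices into the GRM.

    Attributes after ``fit``: ``params_`` (sigma_g1, sigma_g12, sigma_g2,
    sigma_e1[, sigma_e12], sigma_e2), ``param_cov_``, ``rg_``,
    ``estimate_`` (:class:`GeneticCorrelationEstimate`), ``loglik_``.
    """

    def __init__(self, max_iter=100, tol=1e-6, var_floor_frac=1e-6, n_damped=2):
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor_frac = var_floor_frac
        self.n_damped = n_damped

    # -- internal dense REML machinery ------------------------------------
    def _reml(self, y, X, A11, A12, A22, overlap, theta0, floors, fixed=None):
        n1, n2 = A11.shape[0], A22.shape[0]
        ntot = n1 + n2
        s1, s2 = slice(0, n1), slice(n1, ntot)
        names = (
            ["g1", "g12", "g2", "e1", "e12", "e2"]
            if overlap
            else ["g1", "g12", "g2", "e1", "e2"]
        )
        fixed = fixed or {}
        free = [i for i, nm in enumerate(names) if nm not in fixed]

        def build_V(th):
            V = np.zeros((ntot, ntot))
            V[s1, s1] = th[0] * A11
            V[s2, s2] = th[2] * A22
            V[s1, s2] = th[1] * A12
            V[s2, s1] = th[1] * A12.T
            V[np.arange(n1), np.arange(n1)] += th[names.index("e1")]
            V[np.arange(n1, ntot), np.arange(n1, ntot)] += th[names.index("e2")]
            if overlap:
                ie = th[names.index("e12")]
                V[np.arange(n1), np.arange(n1, ntot)] += ie
                V[np.arange(n1, ntot), np.arange(n1)] += ie
            return V

        def parts_of(th):
            V = build_V(th)
            try:
                cf = linalg.cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                return None
            Vi = linalg.cho_solve(cf, np.eye(ntot))
            ViX = Vi @ X
            C = X.T @ ViX
            try:
                Ccf = linalg.cho_factor(C)
            except np.linalg.LinAlgError:
                return None
            P = Vi - ViX @ linalg.cho_solve(Ccf, ViX.T)
            Py = P @ y
            logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
            logdetC = 2.0 * np.sum(np.log(np.diag(Ccf[0])))
            ll = -0.5 * (logdetV + logdetC + y @ Py)
            return {"P": P, "Py": Py, "ll": ll}

        def tr_and_u(parts, k):
            P, Py = parts["P"], parts["Py"]
            nm = names[k]
            u = np.zeros(ntot)
            if nm == "g1":
                tr = np.sum(P[s1, s1] * A11)
                u[s1] = A11 @ Py[s1]
            elif nm == "g2":
                tr = np.sum(P[s2, s2] * A22)
                u[s2] = A22 @ Py[s2]
            elif nm == "g12":
                tr = 2.0 * np.sum(P[s1, s2] * A12)
                u[s1] = A12 @ Py[s2]
                u[s2] = A12.T @ Py[s1]
            elif nm == "e1":
                tr = np.trace(P[s1, s1])
                u[s1] = Py[s1]
            elif nm == "e2":
                tr = np.trace(P[s2, s2])
                u[s2] = Py[s2]
            else:  # e12
                tr = 2.0 * np.trace(P[s1, s2])
                u[s1] = Py[s2]
                u[s2] = Py[s1]
            return tr, u

        theta = theta0.copy()
        for nm, val in fixed.items():
            theta[names.index(nm)] = val
        parts = parts_of(theta)
        if parts is None:
            raise RuntimeError("initial V not positive definite")
        ll_old = parts["ll"]
        converged = False
        it = 0
        AI_free = np.eye(len(free))
        for it in range(1, self.max_iter + 1):
            trs, us = zip(*(tr_and_u(parts, k) for k in free))
            Py = parts["Py"]
            quads = [Py @ u for u in us]
            score = -0.5 * (np.array(trs) - np.array(quads))
            Pu = [parts["P"] @ u for u in us]
            AI_free = 0.5 * np.array(
                [[us[i] @ Pu[j] for j in range(len(free))] for i in range(len(free))]
            )
            # Levenberg-damped AI step: escalate the ridge until an
            # accepted (PD, non-decreasing) step is found; at high damping
            # the step degenerates to a scaled gradient.
            diag = np.diag(AI_free).copy()
            diag[diag <= 0] = 1.0
            accepted = False
            for lam in (0.0, 1e-6, 1e-3, 1e-1, 1.0, 1e2, 1e4):
                try:
                    delta = np.linalg.solve(
                        AI_free + lam * np.diag(diag), score
                    )
                except np.linalg.LinAlgError:
                    continue
                if not np.all(np.isfinite(delta)):
                    continue
                if it <= self.n_damped:
                    delta = 0.5 * delta
                for _ in range(20):
                    prop = theta.copy()
                    prop[free] += delta
                    for nm in ("g1", "g2", "e1", "e2"):
                        k = names.index(nm)
                        if nm not in fixed:
                            prop[k] = max(prop[k], floors[nm])
                    new_parts = parts_of(prop)
                    if new_parts is not None and new_parts["ll"] >= ll_old - 1e-9:
                        accepted = True
                        break
                    delta = delta / 2.0
                if accepted:
                    break
            if not accepted:
                new_parts = parts
                prop = theta
            theta, parts = prop, new_parts
            ll_new = parts["ll"]
            if abs(ll_new - ll_old) < self.tol:
                converged = True
                ll_old = ll_new
                break
            ll_old = ll_new

        cov_free = np.full((len(free), len(free)), np.nan)
        try:
            cov_free = np.linalg.inv(AI_free)
        except np.linalg.LinAlgError:
            pass
        cov = np.zeros((len(names), len(names)))
        for a, i in enumerate(free):
            for b, j in enumerate(free):
                cov[i, j] = cov_free[a, b]
        return {
            "names": names,
            "theta": theta,
            "cov": cov,
            "loglik": ll_old,
            "converged": converged,
            "n_iter": it,
        }

    # ----------------------------------------------------------------------
    def fit(self, y1, y2, X1=None, X2=None, *, grm: Grm, idx1=None, idx2=None,
            lrt=False):
        y1 = np.asarray(y1, float).ravel()
        y2 = np.asarray(y2, float).ravel()
        n1, n2 = len(y1), len(y2)
        idx1 = np.arange(n1) if idx1 is None else np.asarray(idx1)
        idx2 = np.arange(n2) if idx2 is None else np.asarray(idx2)
        overlap_ids = np.intersect1d(idx1, idx2)
        if len(overlap_ids) == len(idx1) == len(idx2) and np.array_equal(idx1, idx2):
            overlap = True
        elif len(overlap_ids) == 0:
            overlap = False
        else:
            raise ValueError(
                "traits must be on identical samples or disjoint strata"
            )
        if overlap and np.array_equal(y1, y2):
            # degenerate: identical traits put the optimum on the singular
            # boundary (residuals perfectly correlated); report rg = 1
            uni = GREML().fit(y1, X1, grm=grm.subset(idx1)).estimate_
            self.rg_ = 1.0
            self.params_ = {
                "g1": uni.sigma_g, "g12": uni.sigma_g, "g2": uni.sigma_g,
                "e1": uni.sigma_e, "e12": uni.sigma_e, "e2": uni.sigma_e,
            }
            self.loglik_ = uni.loglik
            self.converged_ = True
            self.n_iter_ = 0
            self.estimate_ = GeneticCorrelationEstimate(
                rg=1.0, rg_raw=1.0, se=0.0, sigma_g12=uni.sigma_g,
                h2_1=uni, h2_2=uni, p_zero=0.0, p_one=1.0, test="degenerate",
                reason="traits identical: boundary optimum, rg = 1 exactly",
            )
            return self
        A = grm.values
        A11 = A[np.ix_(idx1, idx1)]
        A12 = A[np.ix_(idx1, idx2)]
        A22 = A[np.ix_(idx2, idx2)]

        X1d = RemlModel(y1, X1, grm).design()
        X2d = RemlModel(y2, X2, grm).design()
        X = linalg.block_diag(X1d, X2d)
        y = np.concatenate([y1, y2])

        vp1 = float(np.var(y1 - X1d @ np.linalg.lstsq(X1d, y1, rcond=None)[0]))
        vp2 = float(np.var(y2 - X2d @ np.linalg.lstsq(X2d, y2, rcond=None)[0]))
        floors = {
            "g1": self.var_floor_frac * vp1,
            "g2": self.var_floor_frac * vp2,
            "e1": self.var_floor_frac * vp1,
            "e2": self.var_floor_frac * vp2,
        }
        nn = 6 if overlap else 5
        theta0 = np.zeros(nn)
        names = ["g1", "g12", "g2", "e1", "e12", "e2"] if overlap else [
            "g1", "g12", "g2", "e1", "e2"
        ]
        theta0[names.index("g1")] = vp1 / 2
        theta0[names.index("g2")] = vp2 / 2
        theta0[names.index("e1")] = vp1 / 2
        theta0[names.index("e2")] = vp2 / 2

        res = self._reml(y, X, A11, A12, A22, overlap, theta0, floors)
        self._assemble(res, n1, n2, floors)
        if lrt:
            fixed = {"g12": 0.0, "e12": 0.0} if overlap else {"g12": 0.0}
            res0 = self._reml(
                y, X, A11, A12, A22, overlap, theta0, floors, fixed=fixed
            )
            stat = max(0.0, 2.0 * (res["loglik"] - res0["loglik"]))
            df = len(fixed)
            self.estimate_.lrt_stat = stat
            self.estimate_.lrt_df = df
            self.estimate_.lrt_p = float(stats.chi2.sf(stat, df))
        return self

    def _assemble(self, res, n1, n2, floors):
        names, th, cov = res["names"], res["theta"], res["cov"]
        ig1, ig12, ig2 = names.index("g1"), names.index("g12"), names.index("g2")
        ie1, ie2 = names.index("e1"), names.index("e2")
        self.params_ = dict(zip(names, th))
        self.param_cov_ = cov
        self.loglik_ = res["loglik"]
        self.converged_ = res["converged"]
        self.n_iter_ = res["n_iter"]

        def h2_of(ig, ie, n):
            g, e = th[ig], th[ie]
            tot = g + e
            h2 = g / tot
            grad = np.zeros(len(names))
            grad[ig] = e / tot**2
            grad[ie] = -g / tot**2
            var = grad @ cov @ grad
            se = float(np.sqrt(var)) if var > 0 else np.nan
            z = h2 / se if se and np.isfinite(se) and se > 0 else np.nan
            return HeritabilityEstimate(
                sigma_g=float(g), sigma_g_se=float(np.sqrt(max(cov[ig, ig], 0))),
                sigma_e=float(e), sigma_e_se=float(np.sqrt(max(cov[ie, ie], 0))),
                h2_observed=float(np.clip(h2, 0, 1)), h2_se=se,
                loglik=res["loglik"], n_iter=res["n_iter"],
                converged=res["converged"], n=n,
                p_value=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            )

        h2a = h2_of(ig1, ie1, n1)
        h2b = h2_of(ig2, ie2, n2)
        g1, g12, g2 = th[ig1], th[ig12], th[ig2]
        at_floor = g1 <= floors["g1"] * 1.01 or g2 <= floors["g2"] * 1.01
        if at_floor:
            self.rg_ = None
            self.estimate_ = GeneticCorrelationEstimate(
                rg=None, rg_raw=None, se=None, sigma_g12=float(g12),
                h2_1=h2a, h2_2=h2b, p_zero=None, p_one=None, test="wald",
                reason="a genetic variance hit the floor; rg undefined",
            )
            return
        rg_raw = g12 / np.sqrt(g1 * g2)
        grad = np.zeros(len(names))
        grad[ig1] = -0.5 * rg_raw / g1
        grad[ig12] = 1.0 / np.sqrt(g1 * g2)
        grad[ig2] = -0.5 * rg_raw / g2
        var = grad @ cov @ grad
        se = float(np.sqrt(var)) if var > 0 else np.nan
        clamped = abs(rg_raw) > 1
        rg = float(np.clip(rg_raw, -1, 1))
        if clamped:
            logger.info("rg clamped from %.4f to %.4f", rg_raw, rg)
        p0 = float(2 * stats.norm.sf(abs(rg_raw / se))) if se > 0 else None
        p1 = float(2 * stats.norm.sf(abs((rg_raw - 1) / se))) if se > 0 else None
        self.rg_ = rg
        self.estimate_ = GeneticCorrelationEstimate(
            rg=rg, rg_raw=float(rg_raw), se=se, sigma_g12=float(g12),
            h2_1=h2a, h2_2=h2b, p_zero=p0, p_one=p1, test="wald",
            clamped=clamped,
        )


def bivariate_reml(
    model_a: RemlModel, model_b: RemlModel, idx1=None, idx2=None, lrt=False, **opts
) -> GeneticCorrelationEstimate:
    """Functional wrapper over :class:`BivariateGREML` (shared GRM in
    ``model_a.grm``)."""
    est = BivariateGREML(**opts).fit(
        model_a.y, model_b.y, model_a.X, model_b.X,
        grm=model_a.grm, idx1=idx1, idx2=idx2, lrt=lrt,
    )
    return est.estimate_


# ---------------------------------------------------------------------------
# stratified GxE


def gxe_stratified(
    phenotype,
    environment,
    grm: Grm,
    covariates=None,
    prevalence: float | None = None,
    min_cases: int = 50,
    lrt=False,
    **opts,
):
    """Stratified-GREML gene-environment interaction test.

    Treats the phenotype in the two environment strata as two traits on
    disjoint samples and fits the bivariate model; a genetic correlation
    significantly below 1 indicates that SNP effects differ between
    environments (GxE).  Returns a dict with per-stratum observed-scale (and,
    for binary phenotypes, liability-scale) heritability estimates, the rg
    estimate and the Wald p-value against rg = 1.
    """
    y = np.asarray(phenotype, float).ravel()
    env = np.asarray(environment)
    levels = np.unique(env)
    if len(levels) < 2:
        raise ValueError("environment label is constant: need two strata")
    if len(levels) > 2:
        raise ValueError("gxe_stratified requires exactly two strata")
    idx1 = np.where(env == levels[0])[0]
    idx2 = np.where(env == levels[1])[0]
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        for idx in (idx1, idx2):
            if y[idx].sum() < min_cases:
                raise ValueError(f"a stratum has fewer than {min_cases} cases")
    cov = None if covariates is None else np.asarray(covariates, float)
    X1 = cov[idx1] if cov is not None else None
    X2 = cov[idx2] if cov is not None else None
    fitter = BivariateGREML(**opts).fit(
        y[idx1], y[idx2], X1, X2, grm=grm, idx1=idx1, idx2=idx2, lrt=lrt
    )
    est = fitter.estimate_
    out = {
        "strata": (levels[0], levels[1]),
        "h2_observed": (est.h2_1, est.h2_2),
        "rg": est,
        "p_rg_one": est.p_one,
    }
    if binary:
        out["h2_liability"] = tuple(
            observed_to_liability(h, prevalence or float(y[idx].mean()))
            for h, idx in zip((est.h2_1, est.h2_2), (idx1, idx2))
        )
    return out


# ---------------------------------------------------------------------------
# split-sample meta-analysis


def split_meta(estimates) -> MetaEstimate:
    """Pool (value, SE, p) triples from independent sub-samples.

    Point estimates are pooled by inverse-variance weighting; p-values are
    combined with Fisher's statistic -2 sum(ln p) ~ chi2 with 2k df (the two
    cannot be collapsed: Fisher's method does not pool estimates).
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("need at least two estimates to meta-analyse")
    vals = np.array([e[0] for e in estimates], float)
    ses = np.array([e[1] for e in estimates], float)
    ps = np.array([e[2] for e in estimates], float)
    if not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("all standard errors must be finite and positive")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * vals) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    if np.any(ps == 0):
        warnings.warn("a component p-value is exactly 0; combined p reported as 0")
        return MetaEstimate(pooled, pooled_se, 0.0, np.inf, len(estimates))
    fisher = float(-2.0 * np.sum(np.log(ps)))
    p_comb = float(stats.chi2.sf(fisher, 2 * len(estimates)))
    return MetaEstimate(pooled, pooled_se, p_comb, fisher, len(estimates))
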