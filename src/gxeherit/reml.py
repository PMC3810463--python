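"""Variance-component estimation by restricted maximum likelihood (GREML).

The model is  y = X beta + sum_c u_c + eps  with cov(u_c) = sigma2_c K_c and
iid residuals, so V = sum_c sigma2_c K_c + sigma2_e I.  The restricted
log-likelihood (constants dropped) is

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Estimation uses average-information (AI) REML: the score for component c is
-1/2 [tr(P K_c) - y' P K_c P y], the AI matrix entry for (c, d) is
1/2 y' P K_c P K_d P y, and the first iterations are EM steps for stability.
Components are floored at a small fraction of the phenotypic variance
(constrained REML), so heritability ratios stay in [0, 1].  Standard errors
come from the inverse AI matrix at convergence; heritability SEs use the
delta method on the component covariance.

A single-kernel model (GRM + residual) is fitted through an exact
eigendecomposition rotation: after rotating by the GRM's eigenvectors the
covariance is diagonal in the variance ratio, and the restricted likelihood
is profiled to a one-dimensional maximization.  Both paths compute the same
likelihood value, so fits from either path are directly comparable in
likelihood-ratio tests.

The GxE variance test at the boundary uses the 50:50 chi2_0 / chi2_1 mixture
null by default (a pure chi2_1 option is provided); a Wald test on the GxE
component is also reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg as sla
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix
from .grm import build_gxe_grm, subset_grm
from .prep import EnvFactor

__all__ = [
    "VCFit",
    "GREML",
    "BootstrapNull",
    "reml_fit",
    "gxe_lrt",
    "fit_gxe_model",
    "heritability_report",
    "total_heritability",
    "bootstrap_null",
    "nearest_rank_percentile",
]

logger = logging.getLogger(__name__)


def _kernel_values(k) -> np.ndarray:
    return k.values if hasattr(k, "values") else np.asarray(k, dtype=float)


@dataclass
class VCFit:
    """Result of one REML fit.

    Component order is the kernel order with the residual last; named
    accessors assume the GREML convention [genetic, (gxe, ...), residual].
    Heritabilities are fractions of the total (sum of all components).
    """

    component_names: list[str]
    vc: np.ndarray
    se_vc: np.ndarray
    cov_vc: np.ndarray = field(repr=False)
    logL: float = np.nan
    converged: bool = False
    n_iter: int = 0
    n: int = 0
    beta: Optional[np.ndarray] = None
    logL_reduced: Optional[float] = None
    lrt_p: Optional[float] = None
    p_wald_gxe: Optional[float] = None

    def _get(self, name: str) -> int:
        return self.component_names.index(name)

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.vc))

    @property
    def Vg(self) -> float:
        return float(self.vc[self._get("Vg")])

    @property
    def Vgxe(self) -> float:
        i = [j for j, c in enumerate(self.component_names) if c.startswith("Vgxe")]
        return float(np.sum(self.vc[i])) if i else 0.0

    @property
    def Ve(self) -> float:
        return float(self.vc[-1])

    def h2(self, name: str) -> float:
        return float(self.vc[self._get(name)] / self.total_variance)

    def se_h2(self, name: str) -> float:
        """Delta-method SE of component/total from the component covariance."""
        c = self._get(name)
        s = self.total_variance
        grad = -self.vc / s**2
        grad[c] += 1.0 / s
        return float(np.sqrt(grad @ self.cov_vc @ grad))

    @property
    def h2_g(self) -> float:
        return self.h2("Vg")

    @property
    def h2_gxe(self) -> float:
        return self.Vgxe / self.total_variance

    @property
    def h2_total(self) -> float:
        return self.h2_g + self.h2_gxe

    @property
    def logL_full(self) -> float:
        return self.logL


def _prepare_X(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if not np.any(np.ptp(X, axis=0) == 0):
        X = np.column_stack([np.ones(n), X])
    # drop collinear columns for a stable projection
    q, r, piv = sla.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])))
    keep = np.sort(piv[:rank])
    return X[:, keep]


class GREML(BaseEstimator):
    """Multi-kernel REML variance-component estimator.

    Parameters
    ----------
    max_iter : int
        Iteration cap per start (default 100).
    tol_logl : float
        Convergence tolerance on the restricted log-likelihood change.
    tol_vc : float
        Convergence tolerance on component changes relative to the
        phenotypic variance.
    n_em : int
        Number of initial EM iterations before switching to AI updates.
    var_floor_frac : float
        Component floor as a fraction of phenotypic variance.
    n_restarts : int
        Perturbed restarts attempted on non-convergence.

    Attributes (after fit)
    ----------------------
    vc_, se_vc_, cov_vc_ : component estimates, SEs, covariance
    h2_ : components as fractions of total variance
    logL_, converged_, n_iter_, beta_ : fit diagnostics and GLS fixed effects
    fit_ : the :class:`VCFit` record
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol_logl: float = 1e-8,
        tol_vc: float = 1e-6,
        n_em: int = 2,
        var_floor_frac: float = 1e-6,
        n_restarts: int = 3,
    ):
        self.max_iter = max_iter
        self.tol_logl = tol_logl
        self.tol_vc = tol_vc
        self.n_em = n_em
        self.var_floor_frac = var_floor_frac
        self.n_restarts = n_restarts

    # ---------------- general multi-kernel AI-REML ----------------

    def _loglik(self, vc, Ks, X, y):
        n = len(y)
        V = np.zeros((n, n))
        for s2, K in zip(vc[:-1], Ks):
            V += s2 * K
        V[np.diag_indices(n)] += vc[-1]
        try:
            cf = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi = sla.cho_solve(cf, np.eye(n), check_finite=False)
        B = Vi @ X
        XtViX = X.T @ B
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        C = np.linalg.inv(XtViX)
        Py = Vi @ y - B @ (C @ (B.T @ y))
        logL = -0.5 * (logdetV + logdetX + float(y @ Py))
        return logL, Vi, B, C, Py

    def _fit_general(self, Ks, X, y, vc0, floor):
        n, p = X.shape
        vc = vc0.copy()
        nk = len(Ks)
        state = self._loglik(vc, Ks, X, y)
        if state is None:
            return None
        logL = state[0]
        cov = np.full((nk + 1, nk + 1), np.nan)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            _, Vi, B, C, Py = state
            # traces of P K_c and quadratic forms
            tr_pk = np.empty(nk + 1)
            t = np.empty((nk + 1, n))
            for c in range(nk):
                KB = Ks[c] @ B
                tr_pk[c] = float(np.sum(Vi * Ks[c])) - float(np.sum(C * (B.T @ KB)))
                t[c] = Ks[c] @ Py
            tr_pk[nk] = float(np.trace(Vi)) - float(np.sum(C * (B.T @ B)))
            t[nk] = Py
            yPKPy = t @ Py
            score = -0.5 * (tr_pk - yPKPy)

            Pt = (Vi @ t.T - B @ (C @ (B.T @ t.T))).T
            AI = 0.5 * (t @ Pt.T)

            if it <= self.n_em:
                new_vc = vc + vc**2 * (yPKPy - tr_pk) / n
                new_vc = np.maximum(new_vc, floor)
                new_state = self._loglik(new_vc, Ks, X, y)
                if new_state is None:
                    return None
            else:
                # active-set Newton: components pinned at the floor whose
                # score pushes them further down are frozen this iteration
                active = (vc > floor * (1 + 1e-12)) | (score > 0)
                delta = np.zeros(nk + 1)
                if active.any():
                    AI_a = AI[np.ix_(active, active)]
                    try:
                        delta[active] = np.linalg.solve(AI_a, score[active])
                    except np.linalg.LinAlgError:
                        delta[active] = score[active] / np.maximum(
                            np.diag(AI_a), 1e-12
                        )
                step = 1.0
                new_state, new_vc = None, None
                for _ in range(8):
                    cand = np.maximum(vc + step * delta, floor)
                    cand_state = self._loglik(cand, Ks, X, y)
                    if cand_state is not None and cand_state[0] >= logL - 1e-10:
                        new_state, new_vc = cand_state, cand
                        break
                    step *= 0.5
                if new_state is None:  # AI step failed entirely -> EM fallback
                    cand = np.maximum(vc + vc**2 * (yPKPy - tr_pk) / n, floor)
                    cand_state = self._loglik(cand, Ks, X, y)
                    if cand_state is None:
                        return None
                    new_state, new_vc = cand_state, cand

            d_logl = new_state[0] - logL
            d_vc = np.max(np.abs(new_vc - vc)) / max(np.sum(vc), 1e-300)
            vc, state, logL = new_vc, new_state, new_state[0]
            if it > self.n_em and abs(d_logl) < self.tol_logl and d_vc < self.tol_vc:
                converged = True
                break

        # AI and fixed effects at the solution
        _, Vi, B, C, Py = state
        t = np.empty((nk + 1, n))
        for c in range(nk):
            t[c] = Ks[c] @ Py
        t[nk] = Py
        Pt = (Vi @ t.T - B @ (C @ (B.T @ t.T))).T
        AI = 0.5 * (t @ Pt.T)
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.full((nk + 1, nk + 1), np.nan)
        beta = C @ (B.T @ y)
        return vc, cov, logL, converged, it, beta

    # ---------------- single-kernel eigendecomposition path ----------------

    @staticmethod
    def eigen_kernel(K) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of a kernel, reusable across fits on the same K.

        Eigenvalues are kept as-is (GRMs with the finite-sample diagonal can
        be slightly indefinite); the variance-ratio search is bounded so the
        total covariance stays positive definite.
        """
        d, U = np.linalg.eigh(_kernel_values(K))
        return d, U

    def _fit_eigen(self, eig, X, y, floor):
        d, U = eig
        n, p = X.shape
        yt, Xt = U.T @ y, U.T @ X
        d_min = float(d.min())

        def profile(log_gamma):
            g = math.exp(log_gamma)
            v = g * d + 1.0
            if v.min() <= 0:
                return np.inf, None
            w = 1.0 / v
            XtW = Xt * w[:, None]
            XtWX = Xt.T @ XtW
            try:
                beta = np.linalg.solve(XtWX, XtW.T @ yt)
            except np.linalg.LinAlgError:
                return np.inf, None
            r = yt - Xt @ beta
            ypy = float(r @ (w * r))
            s2e = ypy / (n - p)
            sign, logdetX = np.linalg.slogdet(XtWX)
            # same likelihood as the general path at (s2g, s2e) = (g*s2e, s2e)
            logL = -0.5 * (
                float(np.sum(np.log(v))) + n * math.log(s2e)
                + logdetX - p * math.log(s2e) + (n - p)
            )
            return -logL, (s2e, beta)

        hi_t = 12.0 if d_min >= 0 else min(12.0, math.log(0.95 / -d_min))
        grid = np.linspace(-12.0, hi_t, 49)
        vals = np.array([profile(t)[0] for t in grid])
        j = int(np.argmin(vals))
        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(lambda t: profile(t)[0], bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        neg, aux = profile(res.x)
        s2e, beta = aux
        gamma = math.exp(res.x)
        vc = np.array([max(gamma * s2e, floor), max(s2e, floor)])
        logL = -neg

        # AI matrix at the optimum (rotated space; everything diagonal + p x p)
        v = vc[0] * d + vc[1]
        w = 1.0 / v
        XtW = Xt * w[:, None]
        C = np.linalg.inv(Xt.T @ XtW)
        By = XtW.T @ yt
        Py = w * yt - XtW @ (C @ By)

        def P_apply(z):
            return w * z - XtW @ (C @ (XtW.T @ z))

        t_g, t_e = d * Py, Py
        AI = 0.5 * np.array(
            [[t_g @ P_apply(t_g), t_g @ P_apply(t_e)],
             [t_e @ P_apply(t_g), t_e @ P_apply(t_e)]]
        )
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        return vc, cov, logL, True, int(res.nfev) + len(grid), C @ By

    # ---------------- public API ----------------

    def fit(self, kernels, y, X=None, kernel_names: Optional[Sequence[str]] = None,
            eig=None, vc_start=None):
        """Fit the variance-component model.

        Parameters
        ----------
        kernels : list of (n, n) arrays or GRM/GxEGRM objects
            Covariance kernels; the residual identity is appended internally.
        y : (n,) phenotype
        X : covariate design (intercept added if absent)
        kernel_names : names per kernel, default ["Vg", "Vgxe", ...]
        eig : optional precomputed ``eigen_kernel`` output, used by the
            single-kernel fast path when fitting many phenotypes on one GRM.
        """
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        Ks = [_kernel_values(k) for k in kernels]
        if not Ks:
            raise ValueError("need at least one kernel")
        for K in Ks:
            if K.shape != (n, n):
                raise ValueError("kernel not conformable with phenotype")
        if np.isnan(y).any():
            raise ValueError("phenotype contains missing values; complete cases only")
        X = _prepare_X(X, n)

        ols_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        vp = float(ols_resid @ ols_resid) / max(n - X.shape[1], 1)
        floor = self.var_floor_frac * vp
        nk = len(Ks)

        if nk == 1:
            out = self._fit_eigen(eig if eig is not None else self.eigen_kernel(Ks[0]),
                                  X, y, floor)
        else:
            out = None
            starts = [np.full(nk + 1, vp / (nk + 1))]
            if vc_start is not None:
                starts.insert(0, np.maximum(np.asarray(vc_start, dtype=float), floor))
            rng = np.random.default_rng(12345)
            for _ in range(self.n_restarts):
                frac = rng.dirichlet(np.ones(nk + 1))
                starts.append(np.maximum(vp * frac, 10 * floor))
            best = None
            for s in starts:
                res = self._fit_general(Ks, X, y, s, floor)
                if res is None:
                    continue
                if res[3]:  # converged
                    best = res
                    break
                if best is None or res[2] > best[2]:
                    best = res
            out = best
        if out is None:
            raise RuntimeError("REML failed: covariance matrix not invertible from any start")

        vc, cov, logL, converged, n_iter, beta = out
        if not converged:
            logger.warning("REML did not converge in %d iterations (logL=%.6f)",
                           self.max_iter, logL)
        names = list(kernel_names) if kernel_names else (
            ["Vg"] + [f"Vgxe{i if i > 1 else ''}" for i in range(1, nk)]
        )
        names = names + ["Ve"]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.vc_ = vc
        self.se_vc_ = se
        self.cov_vc_ = cov
        self.h2_ = vc / vc.sum()
        self.logL_ = logL
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.beta_ = beta
        self.fit_ = VCFit(
            component_names=names, vc=vc, se_vc=se, cov_vc=cov, logL=logL,
            converged=converged, n_iter=n_iter, n=n, beta=beta,
        )
        return self


def reml_fit(y, X, kernels, kernel_names=None, eig=None, vc_start=None, **opts) -> VCFit:
    """Functional wrapper over :class:`GREML`; returns the :class:`VCFit`."""
    return GREML(**opts).fit(kernels, y, X=X, kernel_names=kernel_names, eig=eig,
                             vc_start=vc_start).fit_


def gxe_lrt(fit_full: VCFit, fit_reduced: VCFit, boundary_mixture: bool = True,
            tol: float = 1e-2) -> float:
    """Likelihood-ratio p-value for the GxE variance component.

    The statistic 2(logL_full - logL_reduced) is clipped at zero; under the
    boundary null it is a 50:50 mixture of a point mass at 0 and chi2_1, so
    p = 1/2 P(chi2_1 >= LRT) (and p = 1/2 at LRT = 0).  Set
    ``boundary_mixture=False`` for the pure chi2_1 convention.
    """
    if fit_full.n != fit_reduced.n:
        raise ValueError("full and reduced fits use different sample sizes")
    stat = 2.0 * (fit_full.logL - fit_reduced.logL)
    if stat < -tol:
        raise ValueError(
            f"reduced logL exceeds full logL by {-stat / 2:.4g}; refit with more starts"
        )
    stat = max(stat, 0.0)
    tail = float(stats.chi2.sf(stat, df=1))
    p = 0.5 * tail if boundary_mixture else tail
    if boundary_mixture and stat == 0.0:
        p = 0.5
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    fit_full.logL_reduced = fit_reduced.logL
    fit_full.lrt_p = p
    return p


def fit_gxe_model(y, X, grm, gxe_kernels: dict, boundary_mixture: bool = True,
                  grm_eig=None, **opts) -> VCFit:
    """Fit Vg + one-or-more GxE components + Ve, with the GxE test.

    ``gxe_kernels`` maps exposure names to GxE kernels.  The reported LRT
    compares the full model against the model with all GxE kernels dropped
    (a single-kernel fit, solved exactly through the eigen path); a Wald
    p-value on the first GxE component is attached as well.
    """
    names = ["Vg"] + [f"Vgxe_{k}" for k in gxe_kernels]
    kernels = [grm] + list(gxe_kernels.values())
    reduced = reml_fit(y, X, [grm], kernel_names=["Vg"], eig=grm_eig, **opts)
    # warm-start the full fit at the reduced solution with a small GxE seed;
    # monotone AI updates then keep logL_full >= logL_reduced (nesting)
    vp = reduced.total_variance
    start = np.concatenate([[reduced.vc[0]], np.full(len(gxe_kernels), 0.02 * vp),
                            [reduced.vc[-1]]])
    full = reml_fit(y, X, kernels, kernel_names=names, vc_start=start, **opts)
    if full.logL < reduced.logL - 1e-6:
        retry = reml_fit(y, X, kernels, kernel_names=names, **opts)
        if retry.logL > full.logL:
            full = retry
    gxe_lrt(full, reduced, boundary_mixture=boundary_mixture)
    v, se = full.vc[1], full.se_vc[1]
    if se > 0:
        full.p_wald_gxe = float(stats.norm.sf(v / se))  # one-sided: variance >= 0
    return full


def total_heritability(h2_g_pct: float, h2_gxe_pct: float) -> float:
    """Total heritability (percent) as the plain sum of the component
    heritabilities, e.g. 13.6 + 25.1 -> 38.7."""
    return h2_g_pct + h2_gxe_pct


def heritability_report(fits: dict[str, VCFit] | VCFit) -> "pd.DataFrame":
    """Tabulate heritabilities (percent) with delta-method SEs.

    ``h2_total`` is exactly ``h2_g + h2_gxe`` in every row.
    """
    import pandas as pd

    if isinstance(fits, VCFit):
        fits = {"fit": fits}
    rows = []
    for label, f in fits.items():
        if not f.converged:
            logger.warning("heritability_report: fit %s did not converge", label)
        h2g = 100.0 * f.h2_g
        h2gxe = 100.0 * f.h2_gxe
        gxe_names = [c for c in f.component_names if c.startswith("Vgxe")]
        se_gxe = f.se_h2(gxe_names[0]) * 100.0 if len(gxe_names) == 1 else np.nan
        rows.append(
            {
                "model": label,
                "Vg": f.Vg,
                "se_Vg": f.se_vc[f._get("Vg")],
                "Vgxe": f.Vgxe,
                "Ve": f.Ve,
                "h2_g_pct": h2g,
                "se_h2_g_pct": 100.0 * f.se_h2("Vg"),
                "h2_gxe_pct": h2gxe,
                "se_h2_gxe_pct": se_gxe,
                "h2_total_pct": total_heritability(h2g, h2gxe),
                "lrt_p": f.lrt_p,
                "p_wald_gxe": f.p_wald_gxe,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    idx = max(int(math.ceil(q * v.size)) - 1, 0)
    return float(v[idx])


@dataclass
class BootstrapNull:
    """Null distribution of SNP-set GxE heritability from random SNP sets.

    ``pct95_h2`` is the nearest-rank 95th percentile of the null h2_gxe
    draws; ``pct95_p`` is the 95th percentile in the direction of increasing
    significance, i.e. the nearest-rank 5th percentile of the null p-values
    (an observed p below it is more extreme than 95% of random sets).
    """

    set_size: int
    n_sets: int
    h2_gxe_draws: np.ndarray
    p_draws: np.ndarray
    pct95_h2: float
    pct95_p: float
    seed: int
    n_failed: int = 0
    observed_h2_gxe: Optional[float] = None
    observed_p: Optional[float] = None
    h2_exceeds_pct95: Optional[bool] = None
    p_below_pct95: Optional[bool] = None


def bootstrap_null(
    genotypes: GenotypeMatrix,
    y,
    X,
    env: EnvFactor,
    set_size: int,
    n_sets: int,
    seed: int = 0,
    observed_fit: Optional[VCFit] = None,
    exclude_snps: Optional[Sequence[str]] = None,
    max_fail_frac: float = 0.05,
    **reml_opts,
) -> BootstrapNull:
    """Bootstrap null for a SNP-set GxE heritability estimate.

    Draws ``n_sets`` random SNP sets of ``set_size`` without replacement
    (seeded, so draws are reproducible), builds the subset GRM and its GxE
    kernel for each, fits the three-component model, and collects the null
    h2_gxe and LRT p-value draws with their nearest-rank 95th percentiles.
    When ``observed_fit`` is supplied, the comparison flags of the original
    estimate against the percentiles are filled in.
    """
    if set_size < 1 or set_size > genotypes.n_snps:
        raise ValueError("set_size must be in [1, panel size]")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    pool = np.asarray(genotypes.snp_ids)
    if exclude_snps:
        pool = pool[~np.isin(pool, list(exclude_snps))]
    rng = np.random.default_rng(seed)

    h2_draws, p_draws = [], []
    n_failed = 0
    for s in range(n_sets):
        snps = rng.choice(pool, size=set_size, replace=False)
        try:
            A_s = subset_grm(genotypes, snps)
            K_e = build_gxe_grm(A_s, env)
            fit = fit_gxe_model(y, X, A_s, {env.name: K_e}, **reml_opts)
            if not fit.converged:
                raise RuntimeError("non-convergence")
        except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
            n_failed += 1
            logger.warning("bootstrap set %d failed: %s", s, exc)
            continue
        h2_draws.append(fit.h2_gxe)
        p_draws.append(fit.lrt_p)
    if n_failed > max_fail_frac * n_sets:
        raise RuntimeError(
            f"{n_failed}/{n_sets} bootstrap fits failed (> {max_fail_frac:.0%}); "
            "inspect kernels and phenotype"
        )

    out = BootstrapNull(
        set_size=set_size,
        n_sets=n_sets,
        h2_gxe_draws=np.asarray(h2_draws),
        p_draws=np.asarray(p_draws),
        pct95_h2=nearest_rank_percentile(h2_draws, 0.95),
        pct95_p=nearest_rank_percentile(p_draws, 0.05),
        seed=seed,
        n_failed=n_failed,
    )
    if observed_fit is not None:
        out.observed_h2_gxe = observed_fit.h2_gxe
        out.observed_p = observed_fit.lrt_p
        out.h2_exceeds_pct95 = observed_fit.h2_gxe > out.pct95_h2
        out.p_below_pct95 = (observed_fit.lrt_p or 1.0) < out.pct95_p
    return out
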