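"""Mixed-model SNP and SNP-by-environment genome-wide scan.

Per SNP the model is

    y = X beta + beta_E e + beta_s x_s + beta_int (x_s * e) + u + eps,

with cov(u) = sigma2_u K for a relatedness kernel K (genomic or pedigree)
and an additive SNP coding.  Variance components are estimated once on the
null model (no SNP terms) and reused for every SNP: with V fixed, each SNP
test is generalized least squares, computed by whitening all columns with
the Cholesky factor of V-hat and running vectorized two-column regressions.
Wald tests give the main-effect and interaction p-values.  An exact mode
re-estimates the variance ratio per SNP through the eigen-rotation and is
intended for cross-checks on small panels.

The exposure enters the interaction as its ordinal quartile index (1..4) by
default, giving a single-df test; a continuous-exposure option exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix
from .prep import EnvFactor
from .reml import GREML, _prepare_X, _kernel_values

__all__ = ["GxEScan", "ScanSummary", "scan", "summarize_scan", "extract_snplist"]

logger = logging.getLogger(__name__)

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)


class GxEScan(BaseEstimator):
    """Genome-wide mixed-model scan for SNP main and interaction effects.

    Parameters
    ----------
    mode : {"with_gxe", "without_gxe"}
        Whether the exposure and SNP-by-exposure product enter the model.
    env_coding : {"ordinal", "continuous"}
        Interaction coding: quartile index (default) or raw exposure value.
    exact : bool
        Re-estimate the variance ratio per SNP (slow; for cross-checking).

    Attributes (after fit)
    ---------------------
    results_ : DataFrame with one row per SNP (beta/se/p for main effect and,
        in with_gxe mode, the interaction) and n_used.
    null_vc_ : variance components of the null model (sigma2_u, sigma2_e).
    """

    def __init__(self, mode: str = "with_gxe", env_coding: str = "ordinal",
                 exact: bool = False):
        self.mode = mode
        self.env_coding = env_coding
        self.exact = exact

    def fit(self, G: GenotypeMatrix, y, X=None, env: EnvFactor | None = None, K=None):
        if self.mode not in ("with_gxe", "without_gxe"):
            raise ValueError(f"unknown mode {self.mode!r}")
        with_gxe = self.mode == "with_gxe"
        if with_gxe:
            if env is None:
                raise ValueError("with_gxe mode requires an exposure")
            if self.env_coding == "ordinal" and not env.has_coding:
                raise ValueError("ordinal coding requires a quartile-coded exposure")
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if K is None:
            raise ValueError("a relatedness kernel K is required")
        Kv = _kernel_values(K)

        e = None
        if with_gxe:
            e = env.category if self.env_coding == "ordinal" else env.raw
            e = np.asarray(e, dtype=float)

        # complete cases across phenotype, covariates and exposure
        Xb = _prepare_X(X, n)
        ok = ~np.isnan(y) & ~np.isnan(Xb).any(axis=1)
        if e is not None:
            ok &= ~np.isnan(e)
        if not ok.all():
            logger.info("scan: dropping %d incomplete cases", int((~ok).sum()))
        y, Xb, Kv = y[ok], Xb[ok], Kv[np.ix_(ok, ok)]
        dosage = G.dosage[ok]
        if e is not None:
            e = e[ok]
        Xnull = np.column_stack([Xb, e]) if with_gxe else Xb
        nn, p0 = Xnull.shape

        # one-time null variance components (two-step approximation)
        eig = GREML.eigen_kernel(Kv)
        null = GREML().fit([Kv], y, X=Xnull, kernel_names=["Vu"], eig=eig)
        s2u, s2e = null.vc_
        self.null_vc_ = null.vc_
        self.null_fit_ = null.fit_

        V = s2u * Kv + s2e * np.eye(nn)
        L = sla.cholesky(V, lower=True, check_finite=False)

        def whiten(M):
            return sla.solve_triangular(L, M, lower=True, check_finite=False)

        yt = whiten(y)
        Xt = whiten(Xnull)
        Q, _ = np.linalg.qr(Xt)

        def residualize(M):
            return M - Q @ (Q.T @ M)

        rt = residualize(yt)

        rows = []
        if self.exact:
            rows = self._scan_exact(dosage, y, Xnull, e, eig, G, with_gxe)
        else:
            # per-SNP missing dosages: mean-impute for the whitening matmul,
            # track usable counts separately
            miss = np.isnan(dosage)
            snp_mean = np.nanmean(np.where(miss, np.nan, dosage), axis=0)
            filled = np.where(miss, snp_mean, dosage)
            Gw = whiten(filled)
            a1 = residualize(Gw)
            if with_gxe:
                inter = filled * e[:, None]
                a2 = residualize(whiten(inter))
            s11 = np.einsum("ij,ij->j", a1, a1)
            b1 = a1.T @ rt
            n_used = (~miss).sum(axis=0)
            mono = np.nanstd(np.where(miss, np.nan, dosage), axis=0) == 0
            if with_gxe:
                s12 = np.einsum("ij,ij->j", a1, a2)
                s22 = np.einsum("ij,ij->j", a2, a2)
                b2 = a2.T @ rt
                det = s11 * s22 - s12**2
                with np.errstate(divide="ignore", invalid="ignore"):
                    beta_s = (s22 * b1 - s12 * b2) / det
                    beta_i = (s11 * b2 - s12 * b1) / det
                    se_s = np.sqrt(s22 / det)
                    se_i = np.sqrt(s11 / det)
                bad = mono | (det <= 0) | ~np.isfinite(det)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    beta_s = b1 / s11
                    se_s = np.sqrt(1.0 / s11)
                beta_i = se_i = np.full(dosage.shape[1], np.nan)
                bad = mono | (s11 <= 0) | ~np.isfinite(s11)
            if bad.any():
                logger.info("scan: %d monomorphic/degenerate SNPs skipped", int(bad.sum()))
            with np.errstate(invalid="ignore", divide="ignore"):
                p_s = 2.0 * stats.norm.sf(np.abs(beta_s / se_s))
                p_i = 2.0 * stats.norm.sf(np.abs(beta_i / se_i))
            p_s = np.clip(p_s, np.nextafter(0, 1), 1.0)
            p_i = np.clip(p_i, np.nextafter(0, 1), 1.0)
            for c in (beta_s, se_s, p_s):
                c[bad] = np.nan
            if with_gxe:
                for c in (beta_i, se_i, p_i):
                    c[bad] = np.nan
            else:
                p_i = np.full_like(p_s, np.nan)
            rows = pd.DataFrame(
                {
                    "snp_id": G.snp_ids,
                    "beta_snp": beta_s,
                    "se_snp": se_s,
                    "p_snp": p_s,
                    "beta_int": beta_i,
                    "se_int": se_i,
                    "p_int": p_i,
                    "n_used": n_used,
                }
            )
        self.results_ = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
        return self

    def _scan_exact(self, dosage, y, Xnull, e, eig, G, with_gxe):
        """Per-SNP REML re-estimation through the eigen rotation (<= small panels)."""
        if dosage.shape[1] > 2000:
            raise ValueError("exact mode is intended for small panels (<= 2000 SNPs)")
        rows = []
        model = GREML()
        for j in range(dosage.shape[1]):
            x = dosage[:, j]
            okj = ~np.isnan(x)
            xo = x[okj]
            if np.std(xo) == 0:
                rows.append(dict(snp_id=G.snp_ids[j], beta_snp=np.nan, se_snp=np.nan,
                                 p_snp=np.nan, beta_int=np.nan, se_int=np.nan,
                                 p_int=np.nan, n_used=int(okj.sum())))
                continue
            cols = [Xnull[okj], xo[:, None]]
            if with_gxe:
                cols.append((xo * e[okj])[:, None])
            Xj = np.column_stack(cols)
            Kj = _kernel_values(eig[1] @ (eig[0][:, None] * eig[1].T))
            if okj.all():
                fit = model.fit([Kj], y, X=Xj, eig=eig)
                Kv = Kj
                yj = y
            else:
                Kv = Kj[np.ix_(okj, okj)]
                yj = y[okj]
                fit = model.fit([Kv], yj, X=Xj)
            s2u, s2e = fit.vc_
            V = s2u * Kv + s2e * np.eye(len(yj))
            L = sla.cholesky(V, lower=True, check_finite=False)
            Xt = sla.solve_triangular(L, Xj, lower=True, check_finite=False)
            yt = sla.solve_triangular(L, yj, lower=True, check_finite=False)
            XtX_inv = np.linalg.inv(Xt.T @ Xt)
            beta = XtX_inv @ (Xt.T @ yt)
            se = np.sqrt(np.diag(XtX_inv))
            k_main = Xnull.shape[1]
            z_main = beta[k_main] / se[k_main]
            row = dict(
                snp_id=G.snp_ids[j],
                beta_snp=beta[k_main], se_snp=se[k_main],
                p_snp=float(2 * stats.norm.sf(abs(z_main))),
                beta_int=np.nan, se_int=np.nan, p_int=np.nan,
                n_used=int(okj.sum()),
            )
            if with_gxe:
                z_int = beta[k_main + 1] / se[k_main + 1]
                row.update(beta_int=beta[k_main + 1], se_int=se[k_main + 1],
                           p_int=float(2 * stats.norm.sf(abs(z_int))))
            rows.append(row)
        return rows


def scan(genotypes: GenotypeMatrix, y, X, env: EnvFactor | None, mode: str = "with_gxe",
         K=None, **kwargs) -> pd.DataFrame:
    """Run the mixed-model scan; returns one row per SNP."""
    return GxEScan(mode=mode, **kwargs).fit(genotypes, y, X=X, env=env, K=K).results_


@dataclass
class ScanSummary:
    threshold: float
    n_sig_main: int
    n_sig_int: int
    n_sig_union: int
    lambda_gc: float
    qq_points: pd.DataFrame


def _lambda_gc(p: np.ndarray) -> float:
    p = p[~np.isnan(p)]
    if p.size == 0:
        return float("nan")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


def summarize_scan(results: pd.DataFrame, threshold: float = 1e-5) -> ScanSummary:
    """Significant-SNP counts at ``threshold``, genomic-control lambda (median
    chi-square ratio) and QQ coordinates for the interaction p-values when
    present, else the main-effect p-values."""
    if results.empty:
        raise ValueError("empty scan results")
    p_main = results["p_snp"].to_numpy(dtype=float)
    p_int = results["p_int"].to_numpy(dtype=float)
    has_int = ~np.all(np.isnan(p_int))
    sig_main = results.loc[p_main < threshold, "snp_id"]
    sig_int = results.loc[np.nan_to_num(p_int, nan=1.0) < threshold, "snp_id"]
    union = pd.unique(pd.concat([sig_main, sig_int]))

    p_for_qq = p_int if has_int else p_main
    obs = np.sort(p_for_qq[~np.isnan(p_for_qq)])
    exp = (np.arange(1, obs.size + 1) - 0.5) / obs.size
    qq = pd.DataFrame({"expected_neglog10": -np.log10(exp),
                       "observed_neglog10": -np.log10(obs)})
    return ScanSummary(
        threshold=threshold,
        n_sig_main=int(len(sig_main)),
        n_sig_int=int(len(sig_int)),
        n_sig_union=int(len(union)),
        lambda_gc=_lambda_gc(p_for_qq),
        qq_points=qq,
    )


def extract_snplist(results: pd.DataFrame, threshold: float, which: str = "union") -> list[str]:
    """Ordered, deduplicated significant-SNP ids for SNP-set GRM construction."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    p_main = results["p_snp"].to_numpy(dtype=float)
    p_int = results["p_int"].to_numpy(dtype=float)
    main = np.nan_to_num(p_main, nan=1.0) < threshold
    inter = np.nan_to_num(p_int, nan=1.0) < threshold
    if which == "main":
        mask = main
    elif which == "interaction":
        mask = inter
    elif which == "union":
        mask = main | inter
    else:
        raise ValueError(f"unknown selection {which!r}")
    out = list(dict.fromkeys(results.loc[mask, "snp_id"]))
    if not out:
        logger.warning("extract_snplist: no SNPs pass p < %g", threshold)
    return out
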