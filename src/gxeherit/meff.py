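"""Effective number of independent tests among correlated variables.

Correlated exposures (and traits) make a plain Bonferroni correction overly
conservative.  The spectral approach estimates the effective number of
independent variables M_eff from the eigenvalues of their correlation
matrix.  Two estimators are computed:

* Li & Ji:  M_eff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]
* Nyholt:   M_eff = 1 + (M - 1) * (1 - var(lambda) / M)

The corrected significance threshold divides alpha by the product of the
(integer-rounded) effective counts for exposures and traits, e.g.
0.05 / (13 * 3) reported to one significant digit as 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EffectiveTests", "effective_tests", "bonferroni_threshold", "correlation_from_table"]


@dataclass
class EffectiveTests:
    m_nominal: int
    m_eff: float
    m_eff_nyholt: float
    eigenvalues: np.ndarray
    method: str = "li_ji"


def effective_tests(corr, method: str = "li_ji") -> EffectiveTests:
    """Spectral effective-test count of a correlation matrix.

    ``corr`` must be symmetric with unit diagonal and positive semi-definite
    (within -1e-8).  ``m_eff`` carries the estimate of the chosen method;
    both estimators are always recorded.
    """
    corr = np.asarray(corr, dtype=float)
    m = corr.shape[0]
    if corr.shape != (m, m) or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")
    evals = np.clip(evals[::-1], 0.0, None)

    # guard the floor against eigenvalues like 4 - 1e-15
    frac = np.clip(evals - np.floor(evals + 1e-9), 0.0, None)
    li_ji = float(np.sum((evals >= 1.0 - 1e-9).astype(float) + frac))
    nyholt = float(1.0 + (m - 1) * (1.0 - np.var(evals, ddof=1) / m)) if m > 1 else 1.0
    if method not in ("li_ji", "nyholt"):
        raise ValueError(f"unknown method {method!r}")
    m_eff = li_ji if method == "li_ji" else nyholt
    m_eff = float(min(max(m_eff, 1.0), m))
    return EffectiveTests(m_nominal=m, m_eff=m_eff, m_eff_nyholt=nyholt,
                          eigenvalues=evals, method=method)


def bonferroni_threshold(m_eff_factors: float, m_eff_traits: float,
                         alpha: float = 0.05) -> tuple[float, float]:
    """Corrected threshold alpha / (round(m_eff_factors) * round(m_eff_traits)).

    Returns ``(raw, one_significant_digit)``; e.g. (13, 3, 0.05) gives
    (0.00128..., 0.001).
    """
    if min(m_eff_factors, m_eff_traits, alpha) <= 0:
        raise ValueError("all inputs must be positive")
    denom = round(m_eff_factors) * round(m_eff_traits)
    raw = alpha / denom
    return raw, float(f"{raw:.0e}")


def correlation_from_table(table: pd.DataFrame) -> np.ndarray:
    """Pairwise-complete Pearson correlation matrix of a variable table."""
    corr = table.corr(method="pearson", min_periods=2).to_numpy()
    if np.isnan(corr).any():
        raise ValueError("correlation undefined for some variable pair")
    np.fill_diagonal(corr, 1.0)
    return corr
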