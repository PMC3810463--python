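"""Trait transformation and exposure coding.

Traits with skewed distributions (insulin, glucose, HOMA indices) are Box-Cox
transformed toward normality before variance-component analysis.  Continuous
dietary and lifestyle exposures are expressed as percent of total energy
where applicable and coded into quartiles; smoking is a 3-level factor.
Population structure covariates are principal-component scores of the
genomic relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EnvFactor",
    "PhenotypeVector",
    "BoxCoxPhenotype",
    "QuartileCoder",
    "boxcox_transform",
    "quartile_code",
    "percent_energy",
    "grm_pcs",
]


@dataclass
class EnvFactor:
    """One environmental exposure: continuous values plus a group coding.

    ``category`` holds 1-based group labels as floats (NaN = missing);
    ``n_groups`` is 4 for quartile-coded exposures and 3 for smoking.
    """

    name: str
    raw: np.ndarray
    category: Optional[np.ndarray] = None
    n_groups: int = 4
    percent_energy: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.category is not None:
            self.category = np.asarray(self.category, dtype=float)
            if len(self.category) != len(self.raw):
                raise ValueError("category length mismatch")

    @property
    def has_coding(self) -> bool:
        return self.category is not None


@dataclass
class PhenotypeVector:
    trait_name: str
    values: np.ndarray
    boxcox_lambda: Optional[float] = None
    transform_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.transform_applied and self.boxcox_lambda is None:
            raise ValueError("transformed phenotype must record its lambda")


class BoxCoxPhenotype(TransformerMixin, BaseEstimator):
    """Box-Cox power transform with lambda chosen by profile likelihood.

    The profile log-likelihood is maximized over ``lambda_range`` by a coarse
    grid followed by bounded scalar refinement.  The transform is
    ``(y**lam - 1)/lam`` for lam != 0 and ``log y`` at lam = 0.

    Parameters
    ----------
    lambda_range : (low, high), default (-3, 3)
        Search interval for lambda.
    grid_step : float, default 0.01
        Coarse grid spacing.
    """

    def __init__(self, lambda_range: tuple[float, float] = (-3.0, 3.0), grid_step: float = 0.01):
        self.lambda_range = lambda_range
        self.grid_step = grid_step

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[~np.isnan(x)]
        if x.size < 2:
            raise ValueError("need at least 2 non-missing values")
        if np.any(x <= 0):
            raise ValueError(
                "Box-Cox requires strictly positive values; shift or exclude non-positives"
            )
        lo, hi = self.lambda_range
        grid = np.arange(lo, hi + self.grid_step / 2, self.grid_step)
        llf = np.array([stats.boxcox_llf(l, x) for l in grid])
        j = int(np.argmax(llf))
        a, b = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda l: -stats.boxcox_llf(l, x), bounds=(a, b), method="bounded"
        )
        self.lambda_ = float(res.x)
        self.llf_ = float(-res.fun)
        return self

    def transform(self, X):
        x = np.asarray(X, dtype=float)
        lam = self.lambda_
        with np.errstate(invalid="ignore"):
            if abs(lam) < 1e-12:
                return np.log(x)
            return (np.power(x, lam) - 1.0) / lam


def boxcox_transform(values, trait_name: str = "trait") -> PhenotypeVector:
    """Box-Cox transform a positive trait; records the fitted lambda."""
    t = BoxCoxPhenotype().fit(values)
    return PhenotypeVector(trait_name, t.transform(values), t.lambda_, True)


class QuartileCoder(TransformerMixin, BaseEstimator):
    """Code a continuous exposure into quartile groups 1..4.

    Boundaries are the empirical 25/50/75 percentiles of the non-missing
    training values; ties at a boundary go to the lower group, so the coding
    is invariant to strictly monotone transforms of the values.
    """

    def __init__(self, on_degenerate: str = "error"):
        self.on_degenerate = on_degenerate  # "error" | "warn"

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        obs = x[~np.isnan(x)]
        if obs.size < 8:
            raise ValueError("quartile coding needs >= 8 non-missing values")
        self.boundaries_ = np.percentile(obs, [25, 50, 75])
        if np.unique(self.boundaries_).size < 3:
            msg = "quartile boundaries are tied; groups collapse"
            if self.on_degenerate == "error":
                raise ValueError(msg)
            warnings.warn(msg)
        return self

    def transform(self, X):
        x = np.asarray(X, dtype=float)
        out = np.full(x.shape, np.nan)
        ok = ~np.isnan(x)
        # count of boundaries strictly below the value -> ties fall to the lower group
        out[ok] = 1.0 + np.searchsorted(self.boundaries_, x[ok], side="left")
        return out


def quartile_code(values, name: str = "exposure", on_degenerate: str = "error",
                  strata=None) -> EnvFactor:
    """Quartile-code a continuous exposure into an :class:`EnvFactor`.

    ``strata`` (e.g. sex) switches from pooled boundaries (the default) to
    boundaries computed within each stratum.
    """
    values = np.asarray(values, dtype=float)
    if strata is None:
        coder = QuartileCoder(on_degenerate=on_degenerate).fit(values)
        category = coder.transform(values)
    else:
        strata = np.asarray(strata)
        category = np.full(values.shape, np.nan)
        for s in np.unique(strata):
            mask = strata == s
            coder = QuartileCoder(on_degenerate=on_degenerate).fit(values[mask])
            category[mask] = coder.transform(values[mask])
    return EnvFactor(name=name, raw=values, category=category, n_groups=4)


def percent_energy(intake_kcal, total_kcal) -> np.ndarray:
    """Nutrient energy as percent of total energy intake: 100 * intake / total."""
    intake = np.asarray(intake_kcal, dtype=float)
    total = np.asarray(total_kcal, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total energy must be positive")
    return 100.0 * intake / total


def grm_pcs(grm, k: int) -> np.ndarray:
    """Top-k principal component scores of a genomic relationship matrix.

    Scores are eigenvectors scaled by the square root of their eigenvalues,
    ordered by descending eigenvalue.  The sign of each component is fixed by
    making its largest-magnitude entry positive.
    """
    values = grm.values if hasattr(grm, "values") else np.asarray(grm, dtype=float)
    n = values.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of individuals")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    evals, evecs = np.linalg.eigh(values)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] - evals[min(k, n - 1)] < 1e-8 * max(abs(evals[0]), 1.0):
        warnings.warn("GRM spectrum is (near-)degenerate; principal components are unidentifiable")
    scores = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))
    for j in range(k):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores
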