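"""Genomic relationship matrices and the GxE-stratified kernel.

The GRM entry for individuals j, k averages allele-frequency-standardized
dosage products over SNPs non-missing in both:

    A_jk = (1/m_jk) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with a finite-sample diagonal correction

    A_jj = 1 + (1/m_j) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i)).

Allele frequencies p_i come from the full sample.  The GxE kernel keeps
A_jk for pairs sharing the same exposure group and zeroes it otherwise;
its diagonal equals the base diagonal, i.e. it is the Schur product of the
GRM with the same-group indicator matrix (hence positive semi-definite).

The interchange format is the GCTA-style pair list: a gzip text file with one
line per lower-triangle pair ``j k nsnp value`` (1-based indices, j >= k) and
a companion ``.grm.id`` file with one ``FID IID`` line per individual.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .prep import EnvFactor

__all__ = ["GRM", "GxEGRM", "build_grm", "build_gxe_grm", "subset_grm", "write_grm", "read_grm"]

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Symmetric relatedness kernel with per-pair SNP counts."""

    ids: pd.DataFrame  # columns fid, iid
    values: np.ndarray = field(repr=False)
    nsnp: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nsnp = np.asarray(self.nsnp)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.nsnp.shape != (n, n):
            raise ValueError("GRM values and nsnp must be square and conformable")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric to 1e-10")
        if self.ids.duplicated(subset=["fid", "iid"]).any():
            raise ValueError("GRM ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GxEGRM:
    """GRM restricted to pairs sharing an exposure group (diagonal preserved)."""

    base: GRM
    env_groups: np.ndarray
    values: np.ndarray = field(repr=False)

    @property
    def ids(self) -> pd.DataFrame:
        return self.base.ids

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _standardize(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.nanmean(dosage, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        bad = int(np.sum((p <= 0) | (p >= 1)))
        raise ValueError(
            f"{bad} monomorphic SNP(s) reached GRM construction; run QC first"
        )
    w = 2.0 * p * (1.0 - p)
    z = (dosage - 2.0 * p) / np.sqrt(w)
    miss = np.isnan(dosage)
    z = np.where(miss, 0.0, z)
    return z, p, ~miss


def build_grm(genotypes: GenotypeMatrix) -> GRM:
    """Genome-wide relationship matrix with pairwise-complete missing handling."""
    if genotypes.n_samples < 2 or genotypes.n_snps < 1:
        raise ValueError("need >= 2 individuals and >= 1 SNP")
    dosage = genotypes.dosage
    z, p, obs = _standardize(dosage)
    nsnp = obs.astype(np.int64) @ obs.astype(np.int64).T
    if np.any(nsnp < 1):
        raise ValueError("some pair has no jointly observed SNPs")
    values = (z @ z.T) / nsnp

    # finite-sample diagonal correction, per-individual over observed SNPs
    w = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore"):
        diag_terms = (dosage**2 - (1.0 + 2.0 * p) * dosage + 2.0 * p**2) / w
    diag_terms = np.where(np.isnan(dosage), 0.0, diag_terms)
    m_j = obs.sum(axis=1)
    np.fill_diagonal(values, 1.0 + diag_terms.sum(axis=1) / m_j)

    ids = pd.DataFrame({"fid": genotypes.fid, "iid": genotypes.iid})
    return GRM(ids=ids, values=values, nsnp=nsnp)


def subset_grm(genotypes: GenotypeMatrix, snp_list) -> GRM:
    """GRM restricted to the listed SNPs (same formula, same full-sample p)."""
    snp_list = list(snp_list)
    if not snp_list:
        raise ValueError("snp_list must be non-empty")
    return build_grm(genotypes.subset_snps(snp_list))


def build_gxe_grm(grm: GRM, env: EnvFactor) -> GxEGRM:
    """Environment-stratified kernel: off-diagonals survive only within groups.

    Individuals with missing exposure coding are dropped (with a logged
    count); the returned matrix is restricted accordingly.
    """
    if not env.has_coding:
        raise ValueError(f"exposure {env.name!r} has no categorical coding")
    groups = np.asarray(env.category, dtype=float)
    if len(groups) != grm.n:
        raise ValueError("exposure length does not match GRM")
    ok = ~np.isnan(groups)
    if not ok.all():
        logger.info("build_gxe_grm: dropping %d individuals with missing %s",
                    int((~ok).sum()), env.name)
    g = groups[ok]
    base_vals = grm.values[np.ix_(ok, ok)]
    if np.unique(g).size == 1:
        warnings.warn(f"exposure {env.name!r} has a single group; GxE kernel equals the GRM")
    same = g[:, None] == g[None, :]
    values = np.where(same, base_vals, 0.0)
    np.fill_diagonal(values, np.diag(base_vals))
    base = GRM(ids=grm.ids.loc[ok].reset_index(drop=True), values=base_vals,
               nsnp=grm.nsnp[np.ix_(ok, ok)]) if not ok.all() else grm
    return GxEGRM(base=base, env_groups=g, values=values)


def write_grm(grm: GRM, prefix) -> None:
    """Write ``<prefix>.grm.gz`` and ``<prefix>.grm.id``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.grm.id", "w") as fh:
        for _, row in grm.ids.iterrows():
            fh.write(f"{row['fid']}\t{row['iid']}\n")
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for j in range(grm.n):
            for k in range(j + 1):
                fh.write(f"{j + 1}\t{k + 1}\t{int(grm.nsnp[j, k])}\t{grm.values[j, k]:.10e}\n")


def read_grm(prefix) -> GRM:
    """Read the pair-list GRM format written by :func:`write_grm`."""
    prefix = Path(prefix)
    id_path, gz_path = Path(f"{prefix}.grm.id"), Path(f"{prefix}.grm.gz")
    if not id_path.exists() or not gz_path.exists():
        raise FileNotFoundError(f"need both {id_path} and {gz_path}")
    ids = pd.read_csv(id_path, sep=r"\s+", header=None, names=["fid", "iid"], dtype=str)
    n = len(ids)
    values = np.zeros((n, n))
    nsnp = np.zeros((n, n), dtype=np.int64)
    with gzip.open(gz_path, "rt") as fh:
        for line in fh:
            j_s, k_s, m_s, v_s = line.split()
            j, k = int(j_s) - 1, int(k_s) - 1
            if not (0 <= k <= j < n):
                raise ValueError(f"GRM index out of range: line {line.strip()!r} for n={n}")
            values[j, k] = values[k, j] = float(v_s)
            nsnp[j, k] = nsnp[k, j] = int(m_s)
    return GRM(ids=ids, values=values, nsnp=nsnp)
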