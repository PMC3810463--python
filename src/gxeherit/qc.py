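"""SNP-level quality control for family genotype data.

Filters: minor allele frequency, call rate, Hardy-Weinberg equilibrium
(exact conditional test), and within-family Mendelian-error screening.
MAF and the HWE test use founders only, so family structure does not inflate
allele-frequency or disequilibrium statistics; the call-rate filter uses all
individuals.  A SNP passes QC iff it clears every filter (a conjunction, so
filter order is irrelevant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

__all__ = ["QCThresholds", "hwe_exact_test", "mendel_errors", "filter_snps"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Default thresholds: MAF >= 5%, call rate >= 96%, HWE p >= 1e-6, and
    exclusion of SNPs with Mendelian errors in more than 1% of informative
    families (the within-family screen is not quantified in most study
    reports; this default is configurable)."""

    maf_min: float = 0.05
    call_rate_min: float = 0.96
    hwe_p_min: float = 1e-6
    mendel_family_frac_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "mendel_family_frac_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must be in [0, 1]")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table (the Wigginton-style two-sided exact test).
    Symmetric in (n_AA, n_aa); returns 1.0 for monomorphic tables.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_Aa  # rarer-or-not allele count; symmetry makes label irrelevant
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # P(het = h | allele counts) proportional to  n! / (homr! h! homc!) * 2^h
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


# transmissible A1-allele count bounds per parental dosage:
# dosage 0 -> transmits 0 copies; 1 -> 0 or 1; 2 -> 1
_MIN_TRANSMIT = np.array([0, 0, 1])
_MAX_TRANSMIT = np.array([0, 1, 1])


def mendel_errors(
    genotypes: GenotypeMatrix, pedigree: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Count Mendelian-inconsistent transmissions per SNP and per family.

    A trio (both parents genotyped) is an error at a SNP iff the child dosage
    lies outside the transmissible range; with one genotyped parent (duo)
    only opposite-homozygote conflicts count.  Missing genotypes never count
    as errors.

    Returns
    -------
    per_snp : (m,) int array of error counts
    per_family : DataFrame with columns fid, errors, informative (a family is
        informative at the SNP level if it has >= 1 checkable offspring)
    """
    idx = {v: i for i, v in enumerate(genotypes.iid)}
    dosage = genotypes.dosage
    m = genotypes.n_snps
    per_snp = np.zeros(m, dtype=np.int64)
    fam_err: dict[str, np.ndarray] = {}
    fam_informative: set[str] = set()

    for _, row in pedigree.iterrows():
        cid = row["iid"]
        if cid not in idx or row["father"] in ("0", None) or row["mother"] in ("0", None):
            continue
        fi, mi = idx.get(row["father"]), idx.get(row["mother"])
        if fi is None and mi is None:
            continue
        c = dosage[idx[cid]]
        c_ok = ~np.isnan(c)
        fam_informative.add(row["fid"])
        if fi is not None and mi is not None:
            f, mo = dosage[fi], dosage[mi]
            both = c_ok & ~np.isnan(f) & ~np.isnan(mo)
            fi_d = f[both].astype(int)
            mo_d = mo[both].astype(int)
            lo = _MIN_TRANSMIT[fi_d] + _MIN_TRANSMIT[mo_d]
            hi = _MAX_TRANSMIT[fi_d] + _MAX_TRANSMIT[mo_d]
            err = np.zeros(m, dtype=bool)
            err[both] = (c[both] < lo) | (c[both] > hi)
            # duo checks where exactly one parent is observed
            for pi in (fi, mi):
                one = c_ok & ~np.isnan(dosage[pi]) & ~both
                err[one] |= np.abs(dosage[pi][one] - c[one]) == 2
        else:
            pi = fi if fi is not None else mi
            one = c_ok & ~np.isnan(dosage[pi])
            err = np.zeros(m, dtype=bool)
            err[one] = np.abs(dosage[pi][one] - c[one]) == 2
        per_snp += err
        acc = fam_err.setdefault(row["fid"], np.zeros(m, dtype=np.int64))
        acc += err

    fams = sorted(fam_informative)
    per_family = pd.DataFrame(
        {
            "fid": fams,
            "errors": [int(fam_err.get(f, np.zeros(1)).sum()) for f in fams],
            "informative": True,
        }
    )
    # per-SNP family-level error indicator matrix is recoverable from fam_err;
    # stash it for filter_snps
    per_family.attrs["snp_family_errors"] = (
        np.stack([fam_err[f] > 0 for f in fams]) if fams else np.zeros((0, m), dtype=bool)
    )
    return per_snp, per_family


def filter_snps(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply all SNP filters; returns retained genotypes and the full report.

    The report has one row per input SNP with maf, call_rate, hwe_p,
    mendel_errors (number of families with >= 1 error at the SNP), and the
    pass flag; thresholds used are recorded in ``report.attrs``.
    """
    dosage = genotypes.dosage
    n, m = dosage.shape
    call_rate = 1.0 - np.isnan(dosage).mean(axis=0)

    if pedigree is not None:
        founders = (pedigree["father"].isin(["0"]) & pedigree["mother"].isin(["0"])).to_numpy()
        founder_rows = np.isin(genotypes.iid, pedigree.loc[founders, "iid"].to_numpy())
        per_snp_err, per_family = mendel_errors(genotypes, pedigree)
        snp_fam_err = per_family.attrs["snp_family_errors"]
        n_fam = max(len(per_family), 1)
        fam_err_count = snp_fam_err.sum(axis=0) if len(per_family) else np.zeros(m, dtype=int)
        mendel_frac = fam_err_count / n_fam
    else:
        founder_rows = np.ones(n, dtype=bool)
        fam_err_count = np.zeros(m, dtype=np.int64)
        mendel_frac = np.zeros(m)

    fd = dosage[founder_rows]
    with np.errstate(invalid="ignore"):
        n_AA = np.nansum(fd == 2, axis=0)
        n_Aa = np.nansum(fd == 1, axis=0)
        n_aa = np.nansum(fd == 0, axis=0)
    total = n_AA + n_Aa + n_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(total > 0, (2 * n_AA + n_Aa) / (2 * total), 0.0)
    maf = np.minimum(p1, 1.0 - p1)
    maf = np.where(total > 0, maf, 0.0)
    hwe_p = np.array(
        [hwe_exact_test(a, b, c) if a + b + c > 0 else 0.0 for a, b, c in zip(n_AA, n_Aa, n_aa)]
    )

    passed = (
        (maf >= thresholds.maf_min)
        & (call_rate >= thresholds.call_rate_min)
        & (hwe_p >= thresholds.hwe_p_min)
        & (mendel_frac <= thresholds.mendel_family_frac_max)
    )
    report = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "mendel_errors": fam_err_count,
            "pass": passed,
        }
    )
    report.attrs["thresholds"] = thresholds
    if not passed.any():
        logger.warning("all %d SNPs failed QC", m)
    kept = genotypes.subset_snps(genotypes.snp_ids[passed])
    return kept, report
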