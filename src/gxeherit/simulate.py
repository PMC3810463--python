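"""Synthetic family study generator.

Emulates a two-center cohort of three-generation pedigrees with genome-wide
biallelic SNPs, correlated dietary/lifestyle exposures, and quantitative
diabetes-related traits generated under the variance-component model

    y = X beta + g + gxe + eps,

where cov(g) = sigma2_g * A (the genomic relationship matrix),
cov(gxe) = sigma2_gxe * A_E (the GRM restricted to pairs sharing the same
exposure group), and eps is iid noise.  Every generating value is recorded in
a :class:`TruthRecord` so downstream variance-component estimates can be
validated against known truth.

Genotypes are gene-dropped through the pedigree: founder allele frequencies
are uniform on a configurable range, founder genotypes are drawn at
Hardy-Weinberg proportions, and each non-founder allele is a fair draw from
each parent, so the data are Mendelian-consistent by construction.

Exposure panel defaults mirror a family nutrition cohort: 12 dietary factors
(mostly percent of total energy) plus alcohol, physical activity, and a
3-level smoking factor, with a factor-model correlation structure whose
strongest entry is r ~ 0.89 between n-6 PUFA and total PUFA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, write_plink
from .grm import GRM, build_grm, build_gxe_grm
from .pedigree import PedigreeSample, pedigree_to_frame, simulate_pedigrees
from .prep import EnvFactor, quartile_code

__all__ = [
    "TruthRecord",
    "ExposureDef",
    "ExposurePanel",
    "TraitSpec",
    "StudyData",
    "default_exposure_panel",
    "default_traits",
    "drop_genotypes",
    "simulate_exposures",
    "simulate_phenotype",
    "simulate_study",
    "write_study",
]


@dataclass
class TruthRecord:
    """Generating values for one simulated trait."""

    sigma2_g: float
    sigma2_gxe: float
    sigma2_e: float
    causal_snp_ids: list[str]
    interaction_env: Optional[str]
    beta_covariates: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_gxe, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class ExposureDef:
    name: str
    mean: float
    sd: float
    kind: str = "percent_energy"  # "percent_energy" | "score" | "categorical"


@dataclass
class ExposurePanel:
    """Continuous exposure definitions with their target correlation matrix,
    plus category probabilities for the smoking factor."""

    defs: list[ExposureDef]
    corr: np.ndarray
    smoking_probs: tuple[float, float, float] = (0.72, 0.20, 0.08)

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        k = len(self.defs)
        if self.corr.shape != (k, k):
            raise ValueError("correlation matrix does not match exposure list")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(self.corr)) < -1e-8:
            raise ValueError("correlation matrix must be positive semi-definite")


# factor loadings (fat pattern, PUFA axis, health behaviour) generating the
# default exposure correlation structure; rows sum-of-squares < 1 so the
# implied correlation matrix is PSD with unit diagonal by construction
_DEFAULT_EXPOSURES: list[tuple[ExposureDef, tuple[float, float, float]]] = [
    (ExposureDef("glycemic_load", 127.0, 72.0, "score"), (-0.20, 0.00, 0.00)),
    (ExposureDef("protein", 15.8, 2.75), (0.10, 0.00, 0.20)),
    (ExposureDef("total_fat", 35.5, 6.8), (0.85, 0.25, 0.00)),
    (ExposureDef("saturated_fat", 11.8, 2.65), (0.75, 0.00, 0.00)),
    (ExposureDef("mufa", 13.35, 2.8), (0.75, 0.10, 0.00)),
    (ExposureDef("pufa", 7.67, 2.17), (0.35, 0.90, 0.00)),
    (ExposureDef("n3_pufa", 0.715, 0.21), (0.10, 0.45, 0.40)),
    (ExposureDef("n6_pufa", 6.89, 2.0), (0.32, 0.86, -0.05)),
    (ExposureDef("n3_n6_ratio", 0.105, 0.02), (-0.10, -0.30, 0.60)),
    (ExposureDef("carbohydrate", 48.9, 8.35), (-0.75, -0.35, 0.10)),
    (ExposureDef("fiber", 1.96, 0.55), (-0.30, 0.00, 0.50)),
    (ExposureDef("trans_fat", 2.15, 0.62), (0.50, 0.00, -0.30)),
    (ExposureDef("alcohol", 2.06, 4.96), (0.00, 0.00, -0.25)),
    (ExposureDef("physical_activity", 34.0, 6.15, "score"), (0.00, 0.00, 0.35)),
]

SMOKING = "smoking"


def default_exposure_panel() -> ExposurePanel:
    """14 continuous exposures (factor-model correlations) + smoking."""
    defs = [d for d, _ in _DEFAULT_EXPOSURES]
    load = np.array([l for _, l in _DEFAULT_EXPOSURES])
    corr = load @ load.T
    np.fill_diagonal(corr, 1.0)
    return ExposurePanel(defs=defs, corr=corr)


def drop_genotypes(
    pedigree: list[PedigreeSample],
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop ``n_snps`` unlinked biallelic SNPs through a pedigree.

    Founder allele (A1) frequencies are uniform on ``maf_range``; founder
    genotypes are Binomial(2, p) (Hardy-Weinberg); each non-founder allele is
    a fair draw from the corresponding parent's two alleles.  Missingness is
    then applied independently at ``missing_rate``.
    """
    if not pedigree:
        raise ValueError("empty pedigree")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    n = len(pedigree)
    idx = {s.individual_id: i for i, s in enumerate(pedigree)}
    p = rng.uniform(lo, hi, size=n_snps)
    dosage = np.full((n, n_snps), np.nan)

    # founders at HWE, then children in generation order
    order = sorted(range(n), key=lambda i: pedigree[i].generation)
    for i in order:
        s = pedigree[i]
        if s.is_founder:
            dosage[i] = rng.binomial(2, p)
        else:
            f, m = idx[s.father_id], idx[s.mother_id]
            if np.isnan(dosage[f]).any() or np.isnan(dosage[m]).any():
                raise ValueError("pedigree order broken: parent genotyped after child")
            from_f = rng.random(n_snps) < dosage[f] / 2.0
            from_m = rng.random(n_snps) < dosage[m] / 2.0
            dosage[i] = from_f.astype(float) + from_m
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan

    digits = len(str(n_snps))
    return GenotypeMatrix(
        fid=[s.family_id for s in pedigree],
        iid=[s.individual_id for s in pedigree],
        snp_ids=[f"snp{j + 1:0{digits}d}" for j in range(n_snps)],
        chrom=["1"] * n_snps,
        pos=np.arange(1, n_snps + 1) * 1000,
        a1=["A"] * n_snps,
        a2=["B"] * n_snps,
        dosage=dosage,
    )


def simulate_exposures(
    pedigree: list[PedigreeSample],
    panel: Optional[ExposurePanel] = None,
    seed: int = 0,
    within_family_r: float = 0.0,
) -> list[EnvFactor]:
    """Draw the exposure panel for each pedigree member.

    Continuous exposures are a Gaussian copula achieving the panel's target
    correlations; ``within_family_r`` (default 0) is the share of latent
    variance from a family-level effect.  Smoking is returned already coded
    as a 3-level factor (1 = never, 2 = past, 3 = current).
    """
    if panel is None:
        panel = default_exposure_panel()
    if not (0.0 <= within_family_r < 1.0):
        raise ValueError("within_family_r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n, k = len(pedigree), len(panel.defs)

    # eigenvalue square root handles exactly singular target correlations
    evals, evecs = np.linalg.eigh(panel.corr)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    fam_ids = [s.family_id for s in pedigree]
    fams = sorted(set(fam_ids))
    fam_pos = {f: i for i, f in enumerate(fams)}
    fam_z = rng.standard_normal((len(fams), k)) @ root.T
    ind_z = rng.standard_normal((n, k)) @ root.T
    w = np.sqrt(within_family_r)
    latent = w * fam_z[[fam_pos[f] for f in fam_ids]] + np.sqrt(1 - within_family_r) * ind_z

    out = []
    for j, d in enumerate(panel.defs):
        raw = d.mean + d.sd * latent[:, j]
        if d.kind == "percent_energy":
            raw = np.clip(raw, 0.0, None)
        out.append(EnvFactor(name=d.name, raw=raw, n_groups=4))

    probs = np.asarray(panel.smoking_probs)
    cats = rng.choice([1.0, 2.0, 3.0], size=n, p=probs / probs.sum())
    out.append(EnvFactor(name=SMOKING, raw=cats.copy(), category=cats, n_groups=3))
    return out


def _safe_cholesky(a: np.ndarray) -> np.ndarray:
    jitter = 1e-10 * np.trace(a) / a.shape[0]
    for _ in range(12):
        try:
            return np.linalg.cholesky(a + jitter * np.eye(a.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError("kernel not positive semi-definite within jitter budget")


def _standardized_causal(genotypes: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    z = genotypes.subset_snps(snp_ids).dosage.copy()
    p = np.nanmean(z, axis=0) / 2.0
    z = (z - 2 * p) / np.sqrt(2 * p * (1 - p))
    return np.where(np.isnan(z), 0.0, z)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    env: Optional[EnvFactor],
    truth: TruthRecord,
    covariates: Optional[pd.DataFrame] = None,
    mechanism: str = "kernel",
    grm: Optional[GRM] = None,
) -> np.ndarray:
    """Generate one phenotype under the variance-component model.

    mechanism="kernel" draws the genetic and GxE terms directly from
    multivariate normals with covariances sigma2_g * A and sigma2_gxe * A_E,
    matching the estimation model exactly.  mechanism="causal" realizes them
    through per-SNP effects on ``truth.causal_snp_ids`` (environment-group-
    specific effects for the GxE term), which induces the same covariances
    with the causal-subset GRM in place of A.
    """
    n = genotypes.n_samples
    if mechanism not in ("kernel", "causal"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if truth.sigma2_gxe > 0:
        if env is None or not env.has_coding:
            raise ValueError("sigma2_gxe > 0 requires an exposure with categorical coding")
        if len(env.category) != n:
            raise ValueError("exposure length does not match genotypes")
    rng = np.random.default_rng(truth.seed)

    y = np.zeros(n)
    if covariates is not None and truth.beta_covariates:
        if len(covariates) != n:
            raise ValueError("covariate table length does not match genotypes")
        for col, beta in truth.beta_covariates.items():
            if col not in covariates.columns:
                raise ValueError(f"covariate {col!r} missing from table")
            y = y + beta * covariates[col].to_numpy(dtype=float)

    if mechanism == "kernel":
        need_grm = truth.sigma2_g > 0 or truth.sigma2_gxe > 0
        if need_grm:
            A = grm if grm is not None else build_grm(genotypes)
            if truth.sigma2_g > 0:
                y = y + np.sqrt(truth.sigma2_g) * (_safe_cholesky(A.values) @ rng.standard_normal(n))
            if truth.sigma2_gxe > 0:
                ae = build_gxe_grm(A, env).values
                y = y + np.sqrt(truth.sigma2_gxe) * (_safe_cholesky(ae) @ rng.standard_normal(n))
    else:
        if (truth.sigma2_g > 0 or truth.sigma2_gxe > 0) and not truth.causal_snp_ids:
            raise ValueError("causal mechanism needs causal_snp_ids")
        if truth.causal_snp_ids:
            z = _standardized_causal(genotypes, truth.causal_snp_ids)
            mc = z.shape[1]
            if truth.sigma2_g > 0:
                y = y + z @ rng.normal(0.0, np.sqrt(truth.sigma2_g / mc), size=mc)
            if truth.sigma2_gxe > 0:
                groups = np.unique(env.category[~np.isnan(env.category)])
                b = rng.normal(0.0, np.sqrt(truth.sigma2_gxe / mc), size=(len(groups), mc))
                for gi, gval in enumerate(groups):
                    mask = env.category == gval
                    y[mask] = y[mask] + z[mask] @ b[gi]

    return y + rng.normal(0.0, np.sqrt(truth.sigma2_e), size=n)


@dataclass(frozen=True)
class TraitSpec:
    """Target variance fractions for one simulated trait (total variance 1)."""

    h2_g: float
    h2_gxe: float = 0.0
    env: Optional[str] = None
    beta: dict[str, float] = field(default_factory=dict)
    n_causal: int = 50


def default_traits() -> dict[str, TraitSpec]:
    """Four diabetes-related traits at the magnitudes the pipeline targets:
    additive heritability ~0.09-0.20, GxE heritability ~0.24-0.39 for the
    three traits with an interacting exposure."""
    base = {"age": 0.01, "sex": 0.2, "center_b": 0.1}
    return {
        "glucose": TraitSpec(0.198, 0.0, None, dict(base)),
        "insulin": TraitSpec(0.136, 0.251, "carbohydrate", dict(base)),
        "homa_ir": TraitSpec(0.145, 0.242, "carbohydrate", dict(base)),
        "homa_b": TraitSpec(0.089, 0.390, "n6_pufa", {**base, "bmi": 0.02}),
    }


@dataclass
class StudyData:
    """In-memory bundle for one simulated study."""

    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    exposures: dict[str, EnvFactor]
    covariates: pd.DataFrame
    phenotypes: dict[str, np.ndarray]
    truth: dict[str, TruthRecord]
    grm: GRM


def _simulate_covariates(ped: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    gen = ped["generation"].to_numpy()
    age_mean = np.select([gen == 1, gen == 2], [72.0, 48.0], default=25.0)
    return pd.DataFrame(
        {
            "age": rng.normal(age_mean, 6.0),
            "sex": (ped["sex"].to_numpy() == 2).astype(float),
            "center_b": (ped["center"].to_numpy() == "B").astype(float),
            "bmi": rng.normal(28.5, 5.3, size=len(ped)),
        }
    )


def simulate_study(
    n_families: int = 60,
    generations: int = 3,
    mean_sibs: float = 2.0,
    n_snps: int = 2000,
    seed: int = 0,
    traits: Optional[dict[str, TraitSpec]] = None,
    panel: Optional[ExposurePanel] = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    mechanism: str = "kernel",
    within_family_r: float = 0.0,
) -> StudyData:
    """Simulate a complete study: pedigrees, genotypes, exposures, covariates
    and phenotypes, with per-trait truth records.

    All randomness flows from ``seed`` through deterministic sub-streams, so
    identical arguments reproduce the study exactly.
    """
    if traits is None:
        traits = default_traits()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + len(traits))]

    samples = simulate_pedigrees(n_families, generations, mean_sibs, seed=seeds[0])
    ped = pedigree_to_frame(samples)
    genotypes = drop_genotypes(samples, n_snps, maf_range, missing_rate, seed=seeds[1])
    env_list = simulate_exposures(samples, panel, seed=seeds[2], within_family_r=within_family_r)
    exposures = {e.name: e for e in env_list}
    for name, e in exposures.items():
        if not e.has_coding:
            exposures[name] = quartile_code(e.raw, name=name)
    covariates = _simulate_covariates(ped, np.random.default_rng(seeds[3]))
    A = build_grm(genotypes)

    phenos: dict[str, np.ndarray] = {}
    truths: dict[str, TruthRecord] = {}
    for i, (tname, spec) in enumerate(traits.items()):
        rng_t = np.random.default_rng(seeds[4 + i])
        causal = sorted(rng_t.choice(genotypes.snp_ids, size=min(spec.n_causal, n_snps),
                                     replace=False).tolist())
        truth = TruthRecord(
            sigma2_g=spec.h2_g,
            sigma2_gxe=spec.h2_gxe,
            sigma2_e=max(1.0 - spec.h2_g - spec.h2_gxe, 0.0),
            causal_snp_ids=causal,
            interaction_env=spec.env,
            beta_covariates=dict(spec.beta),
            seed=seeds[4 + i],
        )
        env = exposures[spec.env] if spec.env else None
        phenos[tname] = simulate_phenotype(
            genotypes, env, truth, covariates, mechanism=mechanism, grm=A
        )
        truths[tname] = truth

    return StudyData(ped, genotypes, exposures, covariates, phenos, truths, A)


def write_study(study: StudyData, prefix) -> None:
    """Write a study to disk: PLINK bed/bim/fam, whitespace-delimited
    phenotype/covariate/exposure tables (header ``FID IID <names>``, missing
    "NA"), and a truth JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_plink(study.genotypes, prefix, fam=study.pedigree)

    base = pd.DataFrame({"FID": study.genotypes.fid, "IID": study.genotypes.iid})

    pheno = base.copy()
    for t, y in study.phenotypes.items():
        pheno[t] = y
    pheno.to_csv(f"{prefix}.pheno.txt", sep=" ", index=False, na_rep="NA")

    covar = pd.concat([base, study.covariates.reset_index(drop=True)], axis=1)
    covar.to_csv(f"{prefix}.covar.txt", sep=" ", index=False, na_rep="NA")

    envtab = base.copy()
    for name, e in study.exposures.items():
        envtab[name] = e.raw
        if e.has_coding:
            envtab[f"{name}_q"] = e.category
    envtab.to_csv(f"{prefix}.env.txt", sep=" ", index=False, na_rep="NA")

    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump({t: asdict(tr) for t, tr in study.truth.items()}, fh, indent=2)
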