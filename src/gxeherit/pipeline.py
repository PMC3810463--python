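"""Study orchestration: QC -> preparation -> GRM -> GREML exposure screen ->
GxE GWAS on top exposures -> SNP-set GREML -> bootstrap null -> corrected
significance report.

Every stage logs a structured line with its seed and inputs so each number
in the final report is traceable; all randomness flows from the single seed
in the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .grm import GRM, build_gxe_grm, subset_grm, write_grm
from .gwas import GxEScan, extract_snplist, summarize_scan
from .meff import bonferroni_threshold, correlation_from_table, effective_tests
from .prep import EnvFactor, grm_pcs
from .qc import QCThresholds, filter_snps
from .reml import GREML, bootstrap_null, fit_gxe_model, heritability_report, reml_fit
from .simulate import StudyData, simulate_study

__all__ = ["RunConfig", "run_screen", "run_followup", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full analysis run.

    ``bootstrap_set_size=None`` means "auto": use the size of the extracted
    significant-SNP union, mirroring matched-set bootstrap designs.
    BMI enters the covariates only for the traits listed in ``bmi_traits``.
    """

    traits: Optional[list[str]] = None
    exposures: Optional[list[str]] = None
    control_exposure: str = "protein"
    bmi_traits: tuple = ("homa_b",)
    n_pcs: int = 3
    gwas_p: float = 1e-5
    alpha: float = 0.05
    bootstrap_sets: int = 200
    bootstrap_set_size: Optional[int] = None
    seed: int = 0
    qc: QCThresholds = field(default_factory=QCThresholds)

    def __post_init__(self) -> None:
        if not (0 < self.gwas_p < 1 and 0 < self.alpha < 1):
            raise ValueError("thresholds must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QCThresholds(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)


def _covariates_for(study: StudyData, trait: str, config: RunConfig,
                    pcs: np.ndarray) -> np.ndarray:
    cols = ["age", "sex", "center_b"]
    if trait in config.bmi_traits:
        cols.append("bmi")
    X = study.covariates[cols].to_numpy(dtype=float)
    return np.column_stack([X, pcs])


def run_screen(study: StudyData, config: RunConfig,
               grm: Optional[GRM] = None) -> pd.DataFrame:
    """GREML screen: one GxE fit per (trait, exposure) pair plus one
    additive-only fit per trait.  Returns a long table of variance
    components, heritabilities and GxE p-values."""
    traits = config.traits or list(study.phenotypes)
    exposures = config.exposures or [e for e in study.exposures]
    A = grm if grm is not None else study.grm
    eig = GREML.eigen_kernel(A)
    pcs = grm_pcs(A, config.n_pcs)

    gxe_kernels = {name: build_gxe_grm(A, study.exposures[name]) for name in exposures}

    rows = []
    for trait in traits:
        y = study.phenotypes[trait]
        X = _covariates_for(study, trait, config, pcs)
        add = reml_fit(y, X, [A], kernel_names=["Vg"], eig=eig)
        logger.info("screen trait=%s exposure=None logL=%.4f", trait, add.logL)
        rows.append(dict(trait=trait, exposure=None, model="additive",
                         **_fit_row(add)))
        for name in exposures:
            fit = fit_gxe_model(y, X, A, {name: gxe_kernels[name]}, grm_eig=eig)
            logger.info("screen trait=%s exposure=%s p=%.4g", trait, name, fit.lrt_p)
            rows.append(dict(trait=trait, exposure=name, model="gxe", **_fit_row(fit)))
    return pd.DataFrame(rows)


def _fit_row(fit) -> dict:
    return dict(
        Vg=fit.Vg, se_Vg=fit.se_vc[0], Vgxe=fit.Vgxe, Ve=fit.Ve,
        h2_g_pct=100 * fit.h2_g, h2_gxe_pct=100 * fit.h2_gxe,
        h2_total_pct=100 * fit.h2_total, lrt_p=fit.lrt_p,
        p_wald_gxe=fit.p_wald_gxe, logL=fit.logL, converged=fit.converged,
    )


def run_followup(study: StudyData, config: RunConfig, screen: pd.DataFrame,
                 grm: Optional[GRM] = None) -> dict:
    """For each trait's most significant exposure (plus the control): GxE
    GWAS in both modes, significant-SNP extraction at ``gwas_p``, SNP-set
    GREML with both exposures' GxE kernels, and the matched-size bootstrap
    null."""
    A = grm if grm is not None else study.grm
    eig = GREML.eigen_kernel(A)
    pcs = grm_pcs(A, config.n_pcs)
    gxe_rows = screen[screen["model"] == "gxe"]
    out: dict[str, dict] = {}

    for trait in gxe_rows["trait"].unique():
        sub = gxe_rows[gxe_rows["trait"] == trait]
        best = sub.loc[sub["lrt_p"].idxmin()]
        exposure = best["exposure"]
        y = study.phenotypes[trait]
        X = _covariates_for(study, trait, config, pcs)
        env = study.exposures[exposure]
        control = study.exposures[config.control_exposure]

        scans: dict[str, pd.DataFrame] = {}
        summaries = {}
        for label, e in (("significant", env), ("control", control)):
            for mode in ("with_gxe", "without_gxe"):
                s = GxEScan(mode=mode).fit(study.genotypes, y, X=X, env=e, K=A)
                scans[f"{label}_{mode}"] = s.results_
                summaries[f"{label}_{mode}"] = summarize_scan(s.results_, config.gwas_p)
        logger.info("followup trait=%s exposure=%s sig-union=%d", trait, exposure,
                    summaries["significant_with_gxe"].n_sig_union)

        snp_list = extract_snplist(scans["significant_with_gxe"], config.gwas_p, "union")
        entry = dict(
            exposure=exposure,
            screen_p=float(best["lrt_p"]),
            scan_summaries={k: asdict_summary(v) for k, v in summaries.items()},
            snp_list=snp_list,
        )
        if not snp_list:
            entry["note"] = "no SNPs passed the scan threshold; follow-up skipped"
            out[trait] = entry
            continue

        A_s = subset_grm(study.genotypes, snp_list)
        kernels = {
            exposure: build_gxe_grm(A_s, env),
            config.control_exposure: build_gxe_grm(A_s, control),
        }
        snpset_fit = fit_gxe_model(y, X, A_s, kernels)
        set_size = config.bootstrap_set_size or len(snp_list)
        # observed single-exposure fit matched to the bootstrap model shape
        observed = fit_gxe_model(y, X, A_s, {exposure: kernels[exposure]})
        boot = bootstrap_null(
            study.genotypes, y, X, env, set_size=set_size,
            n_sets=config.bootstrap_sets, seed=config.seed + 1,
            observed_fit=observed,
        )
        entry.update(
            snpset_fit=heritability_report({f"{trait}:{exposure}+{config.control_exposure}":
                                            snpset_fit}).to_dict("records")[0],
            snpset_h2_gxe_pct=dict(zip(
                [c for c in snpset_fit.component_names if c.startswith("Vgxe")],
                (100 * snpset_fit.vc[1:-1] / snpset_fit.total_variance).round(3),
            )),
            bootstrap=dict(
                set_size=boot.set_size, n_sets=boot.n_sets, seed=boot.seed,
                pct95_h2=boot.pct95_h2, pct95_p=boot.pct95_p,
                observed_h2_gxe=boot.observed_h2_gxe, observed_p=boot.observed_p,
                h2_exceeds_pct95=boot.h2_exceeds_pct95,
                p_below_pct95=boot.p_below_pct95, n_failed=boot.n_failed,
            ),
        )
        out[trait] = entry
    return out


def asdict_summary(s) -> dict:
    return dict(threshold=s.threshold, n_sig_main=s.n_sig_main, n_sig_int=s.n_sig_int,
                n_sig_union=s.n_sig_union, lambda_gc=s.lambda_gc)


def run_study(config: RunConfig, study: Optional[StudyData] = None,
              out_dir=None, sim_kwargs: Optional[dict] = None) -> dict:
    """Full desk-scale run: simulate (or take) a study, QC, screen, follow-up
    and corrected significance; optionally write TSV/JSON artifacts."""
    if study is None:
        study = simulate_study(seed=config.seed, **(sim_kwargs or {}))
    geno_qc, qc_report = filter_snps(study.genotypes, study.pedigree, config.qc)
    logger.info("qc retained %d/%d SNPs", geno_qc.n_snps, study.genotypes.n_snps)
    from .grm import build_grm

    A = build_grm(geno_qc)
    study_qc = StudyData(study.pedigree, geno_qc, study.exposures, study.covariates,
                         study.phenotypes, study.truth, A)
    screen = run_screen(study_qc, config, grm=A)
    followup = run_followup(study_qc, config, screen, grm=A)

    env_table = pd.DataFrame({n: e.raw for n, e in study.exposures.items()})
    trait_table = pd.DataFrame(study.phenotypes)
    m_env = effective_tests(correlation_from_table(env_table))
    m_tr = effective_tests(correlation_from_table(trait_table))
    raw_alpha, rounded_alpha = bonferroni_threshold(m_env.m_eff, m_tr.m_eff, config.alpha)
    report = dict(
        n_individuals=geno_qc.n_samples,
        n_snps_post_qc=geno_qc.n_snps,
        m_eff_exposures=m_env.m_eff,
        m_eff_traits=m_tr.m_eff,
        corrected_alpha_raw=raw_alpha,
        corrected_alpha=rounded_alpha,
        followup=followup,
    )

    if out_dir is not None:
        out = Path(out_dir)
        for sub in ("qc", "grm", "screen", "followup"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        qc_report.to_csv(out / "qc" / "snp_qc.tsv", sep="\t", index=False)
        write_grm(A, out / "grm" / "study")
        screen.to_csv(out / "screen" / "screen.tsv", sep="\t", index=False,
                      float_format="%.6g")
        with open(out / "followup" / "followup.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        with open(out / "summary.md", "w") as fh:
            fh.write(_summary_md(config, report, screen))
    report["screen"] = screen
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _summary_md(config: RunConfig, report: dict, screen: pd.DataFrame) -> str:
    lines = [
        "# GxE variance analysis summary",
        "",
        f"- individuals: {report['n_individuals']}, SNPs post-QC: {report['n_snps_post_qc']}",
        f"- effective tests: {report['m_eff_exposures']:.2f} exposures x "
        f"{report['m_eff_traits']:.2f} traits",
        f"- corrected significance threshold: {report['corrected_alpha']:g} "
        f"(raw {report['corrected_alpha_raw']:.4g}, alpha={config.alpha})",
        "",
        "## Screen (GxE LRT p-values)",
    ]
    gxe = screen[screen["model"] == "gxe"]
    for trait in gxe["trait"].unique():
        sub = gxe[gxe["trait"] == trait].sort_values("lrt_p")
        top = sub.iloc[0]
        lines.append(f"- {trait}: top exposure {top['exposure']} "
                     f"(p={top['lrt_p']:.3g}, h2_gxe={top['h2_gxe_pct']:.1f}%)")
    lines.append("")
    lines.append("## Follow-up")
    for trait, entry in report["followup"].items():
        if "bootstrap" in entry:
            b = entry["bootstrap"]
            lines.append(
                f"- {trait} x {entry['exposure']}: {len(entry['snp_list'])} SNPs, "
                f"observed p={b['observed_p']:.3g} vs null 95th pct {b['pct95_p']:.3g} "
                f"(beyond-chance: {b['p_below_pct95']})"
            )
        else:
            lines.append(f"- {trait}: {entry.get('note', 'no follow-up')}")
    return "\n".join(lines) + "\n"
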