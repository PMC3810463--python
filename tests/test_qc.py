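import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from gxeherit.genotypes import GenotypeMatrix
from gxeherit.pedigree import pedigree_to_frame, simulate_pedigrees
from gxeherit.qc import QCThresholds, filter_snps, hwe_exact_test, mendel_errors
from gxeherit.simulate import drop_genotypes


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent full enumeration of the exact conditional HWE test."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    log_probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        log_probs[h] = h * math.log(2) - gammaln(hr + 1) - gammaln(h + 1) - gammaln(hc + 1)
    mx = max(log_probs.values())
    tot = sum(math.exp(v - mx) for v in log_probs.values())
    probs = {h: math.exp(v - mx) / tot for h, v in log_probs.items()}
    p_obs = probs[n_Aa]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_monomorphic_gives_one(self):
        assert hwe_exact_test(25, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 10) == 1.0

    def test_against_enumeration_oracle_example(self):
        assert hwe_exact_test(57, 14, 50) == pytest.approx(
            hwe_enumeration_oracle(57, 14, 50), abs=1e-12
        )

    @given(
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_allele_label_symmetry(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(hwe_exact_test(c, b, a), abs=1e-14)

    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def _trio_matrix(father, mother, child, n_snps=None):
    """One family, one SNP per provided (f, m, c) triple."""
    trios = list(zip(father, mother, child))
    m = len(trios)
    dosage = np.array([[t[0] for t in trios],
                       [t[1] for t in trios],
                       [t[2] for t in trios]], dtype=float)
    gm = GenotypeMatrix(
        ["F1"] * 3, ["dad", "mom", "kid"], [f"s{i}" for i in range(m)],
        ["1"] * m, np.arange(1, m + 1), ["A"] * m, ["B"] * m, dosage,
    )
    ped = pd.DataFrame(
        {
            "fid": ["F1"] * 3,
            "iid": ["dad", "mom", "kid"],
            "father": ["0", "0", "dad"],
            "mother": ["0", "0", "mom"],
        }
    )
    return gm, ped


class TestMendel:
    @pytest.mark.parametrize(
        "f,m,c,errors",
        [
            (0, 0, 2, 1),  # impossible transmission
            (0, 0, 1, 1),
            (0, 2, 0, 1),  # opposite homozygotes must give het
            (0, 2, 1, 0),
            (1, 1, 0, 0),  # het x het permits everything
            (1, 1, 1, 0),
            (1, 1, 2, 0),
            (2, 2, 2, 0),
            (2, 0, 2, 1),
            (0, 1, 2, 1),
        ],
    )
    def test_trio_table(self, f, m, c, errors):
        gm, ped = _trio_matrix([f], [m], [c])
        per_snp, _ = mendel_errors(gm, ped)
        assert per_snp[0] == errors

    def test_missing_genotypes_never_count(self):
        gm, ped = _trio_matrix([0], [0], [2])
        gm.dosage[2, 0] = np.nan
        per_snp, _ = mendel_errors(gm, ped)
        assert per_snp[0] == 0

    def test_duo_only_opposite_homozygote_conflicts(self):
        gm, ped = _trio_matrix([0, 0, 2], [0, 0, 0], [2, 1, 0])
        gm.dosage[1, :] = np.nan  # mother ungenotyped -> duo with father
        per_snp, _ = mendel_errors(gm, ped)
        assert per_snp.tolist() == [1, 0, 1]

    def test_all_planted_opposite_homozygote_flips_found(self):
        """Flipping child homozygotes against opposite-homozygote parents
        plants errors that must all be detected."""
        ped_samples = simulate_pedigrees(12, 3, 2.0, seed=31)
        gm = drop_genotypes(ped_samples, 150, seed=31)
        ped = pedigree_to_frame(ped_samples)
        by_id = {v: i for i, v in enumerate(gm.iid)}
        rng = np.random.default_rng(0)
        planted = 0
        for s in ped_samples:
            if s.is_founder or planted >= 25:
                continue
            f, m, c = by_id[s.father_id], by_id[s.mother_id], by_id[s.individual_id]
            hom = np.where((gm.dosage[f] == 0) & (gm.dosage[m] == 0))[0]
            if hom.size:
                j = int(rng.choice(hom))
                gm.dosage[c, j] = 2.0
                planted += 1
        per_snp, _ = mendel_errors(gm, ped)
        assert planted > 0 and per_snp.sum() >= planted


class TestFilterSnps:
    def _founder_panel(self, columns):
        """Unrelated founders with hand-built per-SNP genotype columns."""
        n = len(columns[0])
        m = len(columns)
        dosage = np.array(columns, dtype=float).T
        gm = GenotypeMatrix(
            [f"F{i}" for i in range(n)], [f"I{i}" for i in range(n)],
            [f"s{j}" for j in range(m)], ["1"] * m, np.arange(1, m + 1),
            ["A"] * m, ["B"] * m, dosage,
        )
        ped = pd.DataFrame({"fid": gm.fid, "iid": gm.iid,
                            "father": ["0"] * n, "mother": ["0"] * n})
        return gm, ped

    def test_constructed_panel_counts(self):
        """6 SNPs built so exactly 2 fail MAF, 1 fails call rate, 1 fails
        HWE; 2 survive."""
        n = 100
        good = [1] * 50 + [0] * 30 + [2] * 20        # maf 0.45, in HWE-ish
        good2 = [0] * 40 + [1] * 40 + [2] * 20       # maf 0.4
        rare = [0] * 99 + [1]                        # maf 0.005 -> fails MAF
        mono = [0] * 100                             # maf 0 -> fails MAF
        lowcall = [np.nan] * 10 + [1] * 45 + [0] * 45  # call rate 0.90
        hwe_bad = [0] * 50 + [2] * 50                # no hets at p=0.5
        gm, ped = self._founder_panel([good, good2, rare, mono, lowcall, hwe_bad])
        kept, report = filter_snps(gm, ped)
        assert len(report) == 6
        assert kept.n_snps == 2
        assert set(kept.snp_ids) == {"s0", "s1"}
        assert not report.loc[report["snp_id"] == "s2", "pass"].iloc[0]
        assert report.loc[report["snp_id"] == "s4", "call_rate"].iloc[0] == pytest.approx(0.9)
        assert report.loc[report["snp_id"] == "s5", "hwe_p"].iloc[0] < 1e-6

    def test_vacuous_thresholds_retain_everything(self):
        gm, ped = self._founder_panel([[0] * 20, [1] * 10 + [0] * 10])
        kept, report = filter_snps(
            gm, ped, QCThresholds(0.0, 0.0, 0.0, 1.0)
        )
        assert kept.n_snps == gm.n_snps
        assert report["pass"].all()

    def test_fully_missing_snp_fails_call_rate(self):
        gm, ped = self._founder_panel([[1] * 6 + [0] * 6, [np.nan] * 12])
        _, report = filter_snps(gm, ped)
        assert report.loc[report["snp_id"] == "s1", "call_rate"].iloc[0] == 0.0
        assert not report.loc[report["snp_id"] == "s1", "pass"].iloc[0]

    def test_pass_is_conjunction_of_individual_filters(self, small_study):
        """Filter order cannot matter: pass equals the AND of the four
        per-filter verdicts recomputed from the report columns."""
        _, report = filter_snps(small_study.genotypes, small_study.pedigree)
        th = report.attrs["thresholds"]
        n_fam = small_study.pedigree["fid"].nunique()
        recomputed = (
            (report["maf"] >= th.maf_min)
            & (report["call_rate"] >= th.call_rate_min)
            & (report["hwe_p"] >= th.hwe_p_min)
            & (report["mendel_errors"] / n_fam <= th.mendel_family_frac_max)
        )
        assert (report["pass"] == recomputed).all()
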