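import gzip

import numpy as np
import pandas as pd
import pytest

from gxeherit.genotypes import GenotypeMatrix
from gxeherit.grm import GRM, build_grm, build_gxe_grm, read_grm, subset_grm, write_grm
from gxeherit.pedigree import pedigree_to_frame, simulate_pedigrees
from gxeherit.prep import EnvFactor, quartile_code
from gxeherit.simulate import drop_genotypes


def _matrix(dosage, fids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        fids or [f"F{i}" for i in range(n)], [f"I{i}" for i in range(n)],
        [f"s{j}" for j in range(m)], ["1"] * m, np.arange(1, m + 1),
        ["A"] * m, ["B"] * m, dosage,
    )


def grm_offdiag_oracle(dosage):
    """Direct hand-expanded formula for off-diagonal entries."""
    p = dosage.mean(axis=0) / 2
    w = 2 * p * (1 - p)
    n, m = dosage.shape
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            out[j, k] = np.mean((dosage[j] - 2 * p) * (dosage[k] - 2 * p) / w)
    return out


class TestBuildGrm:
    def test_three_by_two_hand_formula(self):
        dosage = [[0, 2], [1, 1], [2, 0]]
        A = build_grm(_matrix(dosage))
        oracle = grm_offdiag_oracle(np.array(dosage, dtype=float))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(A.values[off], oracle[off], atol=1e-12)
        # diagonal: 1 + mean[(x^2 - (1+2p)x + 2p^2) / 2p(1-p)]
        p = np.array([0.5, 0.5])
        w = 2 * p * (1 - p)
        for j in range(3):
            x = np.array(dosage[j], dtype=float)
            expect = 1 + np.mean((x**2 - (1 + 2 * p) * x + 2 * p**2) / w)
            assert A.values[j, j] == pytest.approx(expect, abs=1e-12)

    def test_identical_individuals_match_offdiagonal_self_value(self):
        dosage = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [1, 0, 1, 2]], dtype=float)
        A = build_grm(_matrix(dosage))
        oracle = grm_offdiag_oracle(dosage)
        assert A.values[0, 1] == pytest.approx(oracle[0, 0], abs=1e-12)

    def test_unrelated_founders_center_correctly(self):
        """Mean off-diagonal ~ 0 and mean diagonal ~ 1 for unrelated
        founders (3 SE sampling bands)."""
        ped = simulate_pedigrees(250, 1, 2.0, seed=13)  # 500 founders
        gm = drop_genotypes(ped, 4000, seed=13)
        A = build_grm(gm)
        off = A.values[~np.eye(A.n, dtype=bool)]
        # pairs within a simulated couple are still unrelated
        se_off = off.std(ddof=1) / np.sqrt(A.n)  # conservative (correlated pairs)
        assert abs(off.mean()) < 3 * se_off + 1e-3
        d = np.diag(A.values)
        assert abs(d.mean() - 1.0) < 3 * d.std(ddof=1) / np.sqrt(A.n)

    def test_relative_pair_expectations(self):
        """Full sibs and parent-offspring average ~0.5 relatedness."""
        ped = simulate_pedigrees(60, 2, 3.0, seed=17)
        gm = drop_genotypes(ped, 3000, seed=17)
        A = build_grm(gm)
        frame = pedigree_to_frame(ped)
        idx = {v: i for i, v in enumerate(gm.iid)}
        po, sib = [], []
        kids = frame[frame["father"] != "0"]
        for _, row in kids.iterrows():
            po.append(A.values[idx[row["iid"]], idx[row["father"]]])
            sibs = kids[(kids["father"] == row["father"]) & (kids["iid"] < row["iid"])]
            for _, s in sibs.iterrows():
                sib.append(A.values[idx[row["iid"]], idx[s["iid"]]])
        # centering at in-sample allele frequencies constrains Z row sums,
        # deflating every off-diagonal by O(1/n); allow for that on top of
        # the Monte-Carlo error
        deflation = 6.0 / A.n
        for vals in (po, sib):
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - 0.5) < 3 * se + deflation

    def test_monomorphic_snp_is_contract_breach(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm(_matrix([[0, 1], [0, 1], [0, 2]]))

    def test_psd_within_tolerance(self, small_study):
        evals = np.linalg.eigvalsh(small_study.grm.values)
        assert evals.min() > -0.05  # indefiniteness only from the diagonal correction
        assert np.allclose(small_study.grm.values, small_study.grm.values.T)


class TestGxEGrm:
    def test_single_group_equals_base(self, small_study):
        n = small_study.grm.n
        env = EnvFactor("e", np.zeros(n), category=np.ones(n), n_groups=1)
        with pytest.warns(UserWarning):
            K = build_gxe_grm(small_study.grm, env)
        assert np.array_equal(K.values, small_study.grm.values)

    def test_unique_groups_leave_diagonal_only(self, small_study):
        n = small_study.grm.n
        env = EnvFactor("e", np.zeros(n), category=np.arange(n, dtype=float), n_groups=n)
        K = build_gxe_grm(small_study.grm, env)
        assert np.array_equal(np.diag(K.values), np.diag(small_study.grm.values))
        assert np.all(K.values[~np.eye(n, dtype=bool)] == 0)

    def test_zero_pattern_matches_same_group_mask(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(6, 6))
        vals = (vals + vals.T) / 2
        ids = pd.DataFrame({"fid": list("AAABBB"), "iid": list("abcdef")})
        base = GRM(ids, vals, np.full((6, 6), 10))
        cat = np.array([1, 2, 1, 3, 2, 4], dtype=float)
        env = EnvFactor("e", cat.copy(), category=cat, n_groups=4)
        K = build_gxe_grm(base, env)
        same = cat[:, None] == cat[None, :]
        np.fill_diagonal(same, True)
        assert np.array_equal(K.values != 0, same & (vals != 0))
        assert np.allclose(K.values[same], vals[same])

    def test_idempotent_in_base(self, small_study):
        env = small_study.exposures["carbohydrate"]
        K1 = build_gxe_grm(small_study.grm, env)
        base2 = GRM(small_study.grm.ids, K1.values, small_study.grm.nsnp)
        K2 = build_gxe_grm(base2, env)
        assert np.array_equal(K1.values, K2.values)

    def test_missing_env_dropped(self, small_study):
        cat = small_study.exposures["carbohydrate"].category.copy()
        cat[:5] = np.nan
        env = EnvFactor("e", cat.copy(), category=cat, n_groups=4)
        K = build_gxe_grm(small_study.grm, env)
        assert K.n == small_study.grm.n - 5


class TestSubsetGrm:
    def test_full_subset_equals_build(self, small_study):
        A1 = subset_grm(small_study.genotypes, list(small_study.genotypes.snp_ids))
        assert np.allclose(A1.values, small_study.grm.values, atol=1e-12)

    def test_single_snp_rank_one_offdiagonal(self, small_study):
        snp = small_study.genotypes.snp_ids[0]
        A = subset_grm(small_study.genotypes, [snp])
        x = small_study.genotypes.dosage[:, 0]
        p = x.mean() / 2
        z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
        outer = np.outer(z, z)
        off = ~np.eye(len(x), dtype=bool)
        assert np.allclose(A.values[off], outer[off], atol=1e-10)

    def test_disjoint_additivity(self, small_study):
        snps = list(small_study.genotypes.snp_ids[:40])
        L1, L2 = snps[:15], snps[15:]
        A1 = subset_grm(small_study.genotypes, L1)
        A2 = subset_grm(small_study.genotypes, L2)
        A12 = subset_grm(small_study.genotypes, snps)
        off = ~np.eye(A1.n, dtype=bool)
        lhs = len(L1) * A1.values[off] + len(L2) * A2.values[off]
        assert np.allclose(lhs, len(snps) * A12.values[off], atol=1e-10)

    def test_unknown_snp_rejected_by_name(self, small_study):
        with pytest.raises(KeyError, match="rsFAKE"):
            subset_grm(small_study.genotypes, ["rsFAKE"])
        with pytest.raises(ValueError):
            subset_grm(small_study.genotypes, [])


class TestGrmIO:
    def test_round_trip(self, small_study, tmp_path):
        write_grm(small_study.grm, tmp_path / "g")
        back = read_grm(tmp_path / "g")
        assert np.max(np.abs(back.values - small_study.grm.values)) <= 1e-9
        assert np.array_equal(back.nsnp, small_study.grm.nsnp)
        assert list(back.ids["iid"]) == list(small_study.grm.ids["iid"])

    def test_two_individual_triangle_count(self, tmp_path):
        ids = pd.DataFrame({"fid": ["F1", "F2"], "iid": ["a", "b"]})
        g = GRM(ids, np.array([[1.0, 0.1], [0.1, 0.9]]), np.full((2, 2), 5))
        write_grm(g, tmp_path / "two")
        with gzip.open(tmp_path / "two.grm.gz", "rt") as fh:
            lines = fh.read().strip().split("\n")
        assert len(lines) == 3

    def test_hand_written_file_parses_literally(self, tmp_path):
        (tmp_path / "h.grm.id").write_text("F1\ta\nF1\tb\n")
        with gzip.open(tmp_path / "h.grm.gz", "wt") as fh:
            fh.write("1\t1\t100\t1.0125\n2\t1\t99\t-0.03125\n2\t2\t100\t0.9875\n")
        g = read_grm(tmp_path / "h")
        assert g.values[0, 0] == 1.0125
        assert g.values[1, 0] == g.values[0, 1] == -0.03125
        assert g.nsnp[1, 0] == 99

    def test_out_of_range_index_rejected(self, tmp_path):
        (tmp_path / "b.grm.id").write_text("F1\ta\n")
        with gzip.open(tmp_path / "b.grm.gz", "wt") as fh:
            fh.write("2\t1\t10\t0.5\n")
        with pytest.raises(ValueError, match="out of range"):
            read_grm(tmp_path / "b")
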