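import numpy as np
import pytest
from scipy import stats

from gxeherit.grm import build_gxe_grm, subset_grm
from gxeherit.reml import (
    GREML,
    VCFit,
    bootstrap_null,
    fit_gxe_model,
    gxe_lrt,
    heritability_report,
    nearest_rank_percentile,
    reml_fit,
    total_heritability,
)


def _toy_kernel(n, m, seed):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, m))
    return Z @ Z.T / m


def grid_search_logl(y, X, K, grid):
    """Independent brute-force REML surface evaluation over (s2g, s2e)."""
    n, p = X.shape
    best = -np.inf
    for s2g in grid:
        for s2e in grid:
            V = s2g * K + s2e * np.eye(n)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                continue
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            sign, ld = np.linalg.slogdet(XtViX)
            P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
            logl = -0.5 * (2 * np.log(np.diag(L)).sum() + ld + y @ P @ y)
            best = max(best, logl)
    return best


class TestRemlFit:
    def test_solution_beats_grid_search(self):
        """AI-REML logL on an n=30 single-kernel toy is at least the best of
        a 50x50 grid over (s2g, s2e), within 1e-6."""
        n = 30
        K = _toy_kernel(n, 60, seed=1)
        rng = np.random.default_rng(2)
        y = rng.multivariate_normal(np.zeros(n), 0.6 * K + 0.4 * np.eye(n))
        X = np.ones((n, 1))
        fit = reml_fit(y, X, [K], kernel_names=["Vg"])
        best_grid = grid_search_logl(y, X, K, np.linspace(0.02, 2.0, 50))
        assert fit.logL >= best_grid - 1e-6

    def test_eigen_and_general_paths_agree(self):
        n = 60
        K = _toy_kernel(n, 120, seed=3)
        rng = np.random.default_rng(4)
        y = rng.multivariate_normal(np.zeros(n), 0.5 * K + 0.5 * np.eye(n))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fast = reml_fit(y, X, [K], kernel_names=["Vg"])
        model = GREML()
        out = model._fit_general([K], X, y, np.array([0.5, 0.5]), 1e-8)
        assert fast.logL == pytest.approx(out[2], abs=1e-5)
        assert np.allclose(fast.vc, out[0], atol=1e-4)

    def test_null_kernel_estimates_near_zero(self):
        """y independent of the kernel: h2_g within 2 SE of 0 on average."""
        n = 200
        K = _toy_kernel(n, 400, seed=5)
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            y = rng.standard_normal(n)
            fit = reml_fit(y, None, [K], kernel_names=["Vg"])
            if fit.h2_g <= 2 * max(fit.se_h2("Vg"), 1e-6):
                hits += 1
        assert hits >= 16

    def test_identity_kernel_matches_ols_residual_variance(self):
        """With K = I the total variance equals the OLS residual variance
        (closed-form limit)."""
        n = 120
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ np.array([1.0, 0.5, -0.2]) + rng.standard_normal(n)
        fit = reml_fit(y, X[:, 1:], [np.eye(n)], kernel_names=["Vg"])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2_ols = resid @ resid / (n - 3)
        assert fit.total_variance == pytest.approx(s2_ols, rel=1e-8)

    def test_invariance_to_shift_and_covariate_rescale(self):
        n = 150
        K = _toy_kernel(n, 300, seed=8)
        rng = np.random.default_rng(9)
        X = rng.standard_normal((n, 2))
        y = rng.multivariate_normal(X @ [0.3, -0.4], 0.5 * K + 0.5 * np.eye(n))
        f1 = reml_fit(y, X, [K], kernel_names=["Vg"])
        f2 = reml_fit(y + 100.0, X * np.array([10.0, 0.01]), [K], kernel_names=["Vg"])
        assert np.allclose(f1.vc, f2.vc, rtol=1e-6)

    def test_h2_sum_identity_exact(self):
        fit = VCFit(["Vg", "Vgxe_e", "Ve"], np.array([0.2, 0.3, 0.5]),
                    np.zeros(3), np.zeros((3, 3)))
        assert fit.h2_total == fit.h2_g + fit.h2_gxe
        assert fit.h2_total == pytest.approx(0.5)

    def test_missing_phenotype_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            reml_fit(np.array([1.0, np.nan]), None, [np.eye(2)])


class TestLrt:
    def _fit_pair(self, lf, lr):
        a = VCFit(["Vg", "Vgxe", "Ve"], np.ones(3), np.ones(3), np.eye(3),
                  logL=lf, converged=True, n=100)
        b = VCFit(["Vg", "Ve"], np.ones(2), np.ones(2), np.eye(2),
                  logL=lr, converged=True, n=100)
        return a, b

    def test_boundary_mixture_at_zero(self):
        a, b = self._fit_pair(-10.0, -10.0)
        assert gxe_lrt(a, b) == 0.5

    def test_chi2_tail_value(self):
        a, b = self._fit_pair(-10.0, -10.0 - 2.706 / 2)
        assert gxe_lrt(a, b) == pytest.approx(0.5 * stats.chi2.sf(2.706, 1), rel=1e-12)
        assert gxe_lrt(a, b) == pytest.approx(0.05, abs=0.002)

    def test_pure_chi2_option(self):
        a, b = self._fit_pair(-10.0, -12.0)
        assert gxe_lrt(a, b, boundary_mixture=False) == pytest.approx(
            stats.chi2.sf(4.0, 1), rel=1e-12
        )

    def test_reduced_above_full_raises(self):
        a, b = self._fit_pair(-12.0, -10.0)
        with pytest.raises(ValueError, match="refit"):
            gxe_lrt(a, b)


class TestHeritabilityReport:
    @pytest.mark.parametrize(
        "h2g,h2gxe,total", [(13.6, 25.1, 38.7), (14.5, 24.2, 38.7), (8.9, 39.0, 47.9)]
    )
    def test_total_is_plain_sum(self, h2g, h2gxe, total):
        assert round(total_heritability(h2g, h2gxe), 1) == total

    def test_report_row_sums_and_zero_gxe(self):
        fit = VCFit(["Vg", "Vgxe_e", "Ve"], np.array([0.136, 0.251, 0.613]),
                    np.zeros(3), np.zeros((3, 3)), logL=0.0, converged=True, n=10)
        row = heritability_report({"insulin": fit}).iloc[0]
        assert row["h2_g_pct"] == pytest.approx(13.6)
        assert row["h2_gxe_pct"] == pytest.approx(25.1)
        assert row["h2_total_pct"] == pytest.approx(row["h2_g_pct"] + row["h2_gxe_pct"])
        fit0 = VCFit(["Vg", "Vgxe_e", "Ve"], np.array([0.2, 0.0, 0.8]),
                     np.zeros(3), np.zeros((3, 3)), logL=0.0, converged=True, n=10)
        row0 = heritability_report({"x": fit0}).iloc[0]
        assert row0["h2_gxe_pct"] == 0.0
        assert row0["h2_total_pct"] == row0["h2_g_pct"]


class TestBootstrap:
    def test_nearest_rank_convention(self):
        vals = np.arange(1, 1001)  # 1..1000
        assert nearest_rank_percentile(vals, 0.95) == 950
        assert nearest_rank_percentile(vals, 0.05) == 50

    def test_seeded_draws_reproducible(self, gxe_study):
        env = gxe_study.exposures["carbohydrate"]
        X = gxe_study.covariates[["age", "sex"]].to_numpy()
        y = gxe_study.phenotypes["t"]
        b1 = bootstrap_null(gxe_study.genotypes, y, X, env, set_size=20, n_sets=4, seed=9)
        b2 = bootstrap_null(gxe_study.genotypes, y, X, env, set_size=20, n_sets=4, seed=9)
        assert np.array_equal(b1.h2_gxe_draws, b2.h2_gxe_draws)
        assert np.array_equal(b1.p_draws, b2.p_draws)

    def test_observed_far_below_percentile_flags_significance(self, gxe_study):
        env = gxe_study.exposures["carbohydrate"]
        X = gxe_study.covariates[["age", "sex"]].to_numpy()
        y = gxe_study.phenotypes["t"]
        A_c = subset_grm(gxe_study.genotypes, gxe_study.truth["t"].causal_snp_ids)
        observed = fit_gxe_model(y, X, A_c, {"e": build_gxe_grm(A_c, env)})
        boot = bootstrap_null(gxe_study.genotypes, y, X, env, set_size=20, n_sets=25,
                              seed=3, observed_fit=observed)
        assert boot.observed_p == observed.lrt_p
        if observed.lrt_p < boot.pct95_p:
            assert boot.p_below_pct95
        assert boot.h2_gxe_draws.size + boot.n_failed == 25

    def test_invalid_sizes_rejected(self, gxe_study):
        env = gxe_study.exposures["carbohydrate"]
        with pytest.raises(ValueError):
            bootstrap_null(gxe_study.genotypes, gxe_study.phenotypes["t"], None, env,
                           set_size=0, n_sets=2)
        with pytest.raises(ValueError):
            bootstrap_null(gxe_study.genotypes, gxe_study.phenotypes["t"], None, env,
                           set_size=10**6, n_sets=2)


def test_single_environment_group_folds_gxe_into_additive(small_study):
    """With one exposure group for everyone, A_E = A, so the GxE term is
    indistinguishable from additive variance: the fitted total Vg + Vgxe
    matches the planted total within 2 SE."""
    import warnings

    from gxeherit.prep import EnvFactor
    from gxeherit.simulate import TruthRecord, simulate_phenotype

    gm = small_study.genotypes
    n = gm.n_samples
    env = EnvFactor("one", np.zeros(n), category=np.ones(n), n_groups=1)
    truth = TruthRecord(0.25, 0.25, 0.5, [], "one", {}, 77)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        y = simulate_phenotype(gm, env, truth, grm=small_study.grm)
        K = build_gxe_grm(small_study.grm, env)
        fit = fit_gxe_model(y, None, small_study.grm, {"one": K})
    total = fit.h2_g + fit.h2_gxe
    se = np.sqrt(fit.se_h2("Vg") ** 2 + fit.se_h2("Vgxe_one") ** 2)  # conservative
    if not np.isfinite(se):  # identical kernels make per-component SEs singular
        se = 0.15
    assert abs(total - 0.5) < 2 * max(se, 0.15)
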