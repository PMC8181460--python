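import numpy as np
import pytest

from secblup import (
    BivariateGBLUP,
    MultiKernelModel,
    UnivariateGBLUP,
    compute_grm,
    simulate_genotypes,
)

from helpers import dense_reml_loglik


@pytest.fixture(scope="module")
def K500():
    return compute_grm(simulate_genotypes(500, 800, 0.3, seed=21)).to_numpy()


@pytest.fixture(scope="module")
def eig500(K500):
    return np.linalg.eigh(K500)


def _draw_univariate(K, s2u, s2e, rng, beta0=0.0):
    w, q = np.linalg.eigh(K)
    L = q * np.sqrt(np.clip(w, 0, None))
    n = K.shape[0]
    return beta0 + L @ rng.standard_normal(n) * np.sqrt(s2u) + rng.standard_normal(
        n
    ) * np.sqrt(s2e)


class TestUnivariateREML:
    def test_parameter_recovery_low_heritability(self, K500, eig500):
        """Mean estimates over replicates recover (0.2, 0.8) within
        3 Monte-Carlo SD of the replicate means."""
        rng = np.random.default_rng(77)
        est = []
        for _ in range(100):
            y = _draw_univariate(K500, 0.2, 0.8, rng)
            fit = UnivariateGBLUP(y, eig=eig500).fit()
            est.append((fit.sigma2_u, fit.sigma2_e))
        est = np.array(est)
        mean = est.mean(axis=0)
        sd_mean = est.std(axis=0) / np.sqrt(len(est))
        assert abs(mean[0] - 0.2) < 3 * sd_mean[0] + 0.03
        assert abs(mean[1] - 0.8) < 3 * sd_mean[1] + 0.03

    def test_optimum_matches_heritability_grid_oracle(self, K500, eig500):
        rng = np.random.default_rng(5)
        y = _draw_univariate(K500, 0.4, 0.6, rng)
        model = UnivariateGBLUP(y, eig=eig500)
        fit = model.fit()
        grid = np.arange(0.001, 1.0, 0.001)
        best_grid = max(model.profile_loglik(h) for h in grid)
        assert fit.loglik >= best_grid - 1e-4

    def test_loglik_matches_dense_reml_evaluation(self, K500, eig500):
        rng = np.random.default_rng(9)
        y = _draw_univariate(K500[:60, :60], 0.5, 0.5, rng)
        model = UnivariateGBLUP(y, K=K500[:60, :60])
        fit = model.fit()
        V = fit.sigma2_u * K500[:60, :60] + fit.sigma2_e * np.eye(60)
        ll = dense_reml_loglik(y, np.ones((60, 1)), V)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_noiseless_trait_hits_boundary_with_flag(self, K500):
        rng = np.random.default_rng(13)
        K = K500[:50, :50]
        y = 3.0 * np.ones(50) + 1e-10 * rng.standard_normal(50)
        fit = UnivariateGBLUP(y, K=K).fit()
        assert fit.converged in (True, False)  # reported, not raised
        # no residual signal: the total variance collapses to the floor
        assert fit.sigma2_u <= 1e-6 and fit.sigma2_e <= 1e-6
        assert fit.beta[0] == pytest.approx(3.0, abs=1e-6)

    def test_shift_invariance_of_variance_components(self, K500, eig500):
        rng = np.random.default_rng(17)
        y = _draw_univariate(K500, 0.3, 0.7, rng)
        f1 = UnivariateGBLUP(y, eig=eig500).fit()
        f2 = UnivariateGBLUP(y + 5.0, eig=eig500).fit()
        assert f2.sigma2_u == pytest.approx(f1.sigma2_u, abs=1e-6)
        assert f2.sigma2_e == pytest.approx(f1.sigma2_e, abs=1e-6)
        assert f2.beta[0] == pytest.approx(f1.beta[0] + 5.0, abs=1e-6)

    def test_scaling_scales_variances_quadratically(self, K500, eig500):
        rng = np.random.default_rng(19)
        y = _draw_univariate(K500, 0.3, 0.7, rng)
        f1 = UnivariateGBLUP(y, eig=eig500).fit()
        f2 = UnivariateGBLUP(3.0 * y, eig=eig500).fit()
        assert f2.sigma2_u == pytest.approx(9.0 * f1.sigma2_u, rel=1e-4)
        assert f2.sigma2_e == pytest.approx(9.0 * f1.sigma2_e, rel=1e-4)

    def test_rank_deficient_design_rejected(self, K500):
        X = np.ones((50, 2))
        with pytest.raises(ValueError, match="rank"):
            UnivariateGBLUP(np.arange(50.0), K=K500[:50, :50], X=X)

    def test_nonfinite_trait_rejected(self, K500):
        y = np.arange(50.0)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            UnivariateGBLUP(y, K=K500[:50, :50])


def _draw_bivariate(K, Su, Se, rng):
    w, q = np.linalg.eigh(K)
    L = q * np.sqrt(np.clip(w, 0, None))
    n = K.shape[0]
    U = L @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(Su).T
    E = rng.standard_normal((n, 2)) @ np.linalg.cholesky(Se).T
    return U + E


SU_TRUE = np.array([[0.2, 0.187], [0.187, 0.7]])
SE_TRUE = np.diag([0.8, 0.3])


class TestBivariateREML:
    def test_genetic_correlation_recovery(self, K500, eig500):
        """rho_G = 0.187 / sqrt(0.2 * 0.7) = 0.5 recovered within 3 SD."""
        rng = np.random.default_rng(23)
        rhos = []
        for _ in range(50):
            Y = _draw_bivariate(K500, SU_TRUE, SE_TRUE, rng)
            cov = BivariateGBLUP(Y, K500, diagonal_residual=True, eig=eig500).fit()
            rhos.append(cov.genetic_correlation())
        rhos = np.array(rhos)
        assert abs(rhos.mean() - 0.5) < 3 * rhos.std(ddof=1) / np.sqrt(len(rhos)) + 0.02

    def test_independent_traits_give_zero_correlation(self, K500, eig500):
        rng = np.random.default_rng(29)
        covs = []
        for _ in range(30):
            Y = _draw_bivariate(K500, np.diag([0.2, 0.7]), SE_TRUE, rng)
            cov = BivariateGBLUP(Y, K500, diagonal_residual=True, eig=eig500).fit()
            covs.append(cov.Sigma_u[0, 1])
        covs = np.array(covs)
        assert abs(covs.mean()) < 3 * covs.std(ddof=1) / np.sqrt(len(covs)) + 0.01

    def test_optimum_at_least_as_good_as_truth(self, K500, eig500):
        rng = np.random.default_rng(31)
        Y = _draw_bivariate(K500, SU_TRUE, SE_TRUE, rng)
        model = BivariateGBLUP(Y, K500, diagonal_residual=True, eig=eig500)
        cov = model.fit()
        assert cov.loglik >= -model.negloglik(SU_TRUE, SE_TRUE) - 1e-6

    def test_balanced_loglik_matches_dense_oracle(self, K500):
        rng = np.random.default_rng(37)
        K = K500[:40, :40]
        Y = _draw_bivariate(K, SU_TRUE, SE_TRUE, rng)
        model = BivariateGBLUP(Y, K, diagonal_residual=False)
        Su = np.array([[0.3, 0.1], [0.1, 0.5]])
        Se = np.array([[0.6, 0.05], [0.05, 0.4]])
        V = np.kron(Su, K) + np.kron(Se, np.eye(40))
        Xd = np.zeros((80, 2))
        Xd[:40, 0] = 1.0
        Xd[40:, 1] = 1.0
        ll = dense_reml_loglik(Y.T.ravel(), Xd, V)
        assert -model.negloglik(Su, Se) == pytest.approx(ll, abs=1e-8)

    def test_unbalanced_marginalisation_matches_dense_oracle(self, K500):
        """Second trait observed on extra genotypes: the dense path must
        equal a hand-built marginal likelihood over observed cells."""
        rng = np.random.default_rng(41)
        K = K500[:30, :30]
        Y = _draw_bivariate(K, SU_TRUE, SE_TRUE, rng)
        Y[:10, 0] = np.nan  # focal missing on 10 genotypes
        model = BivariateGBLUP(Y, K, diagonal_residual=True)
        Su = np.array([[0.25, 0.12], [0.12, 0.6]])
        Se = np.diag([0.7, 0.35])
        i0 = np.arange(10, 30)
        i1 = np.arange(30)
        V = np.block(
            [
                [
                    Su[0, 0] * K[np.ix_(i0, i0)] + Se[0, 0] * np.eye(20),
                    Su[0, 1] * K[np.ix_(i0, i1)]
                    + Se[0, 1] * (i0[:, None] == i1[None, :]),
                ],
                [
                    Su[0, 1] * K[np.ix_(i1, i0)]
                    + Se[0, 1] * (i1[:, None] == i0[None, :]),
                    Su[1, 1] * K[np.ix_(i1, i1)] + Se[1, 1] * np.eye(30),
                ],
            ]
        )
        Xd = np.zeros((50, 2))
        Xd[:20, 0] = 1.0
        Xd[20:, 1] = 1.0
        yobs = np.concatenate([Y[i0, 0], Y[i1, 1]])
        ll = dense_reml_loglik(yobs, Xd, V)
        assert -model.negloglik(Su, Se) == pytest.approx(ll, abs=1e-8)

    def test_diagonal_residual_flag_forces_exact_zeros(self, K500, eig500):
        rng = np.random.default_rng(43)
        Y = _draw_bivariate(K500, SU_TRUE, np.array([[0.8, 0.3], [0.3, 0.3]]), rng)
        cov = BivariateGBLUP(Y, K500, diagonal_residual=True, eig=eig500).fit()
        assert cov.Sigma_e[0, 1] == 0.0

    def test_pure_noise_second_trait_keeps_focal_components(self, K500, eig500):
        rng = np.random.default_rng(47)
        y1 = _draw_univariate(K500, 0.3, 0.7, rng)
        y2 = rng.standard_normal(500)
        uni = UnivariateGBLUP(y1, eig=eig500).fit()
        biv = BivariateGBLUP(
            np.column_stack([y1, y2]), K500, diagonal_residual=True, eig=eig500
        ).fit()
        total = uni.sigma2_u + uni.sigma2_e
        assert abs(biv.Sigma_u[0, 0] - uni.sigma2_u) < 0.15 * total
        assert abs(biv.Sigma_e[0, 0] - uni.sigma2_e) < 0.15 * total

    def test_constant_trait_rejected(self, K500):
        Y = np.column_stack([np.ones(40), np.arange(40.0)])
        with pytest.raises(ValueError, match="constant"):
            BivariateGBLUP(Y, K500[:40, :40])


class TestMultiKernelREML:
    @pytest.fixture(scope="class")
    def kernels(self):
        K = compute_grm(simulate_genotypes(300, 500, 0.3, seed=51)).to_numpy()
        rng = np.random.default_rng(53)
        Z = rng.standard_normal((300, 40))
        M = Z @ Z.T / 40
        return K, M

    def test_zero_second_kernel_reduces_to_univariate(self, kernels):
        K, _ = kernels
        rng = np.random.default_rng(59)
        y = _draw_univariate(K, 0.4, 0.6, rng)
        uni = UnivariateGBLUP(y, K=K).fit()
        mk = MultiKernelModel(y, K, np.zeros_like(K)).fit()
        assert mk.sigma2_K == pytest.approx(uni.sigma2_u, abs=1e-4)
        assert mk.sigma2_E == pytest.approx(uni.sigma2_e, abs=1e-4)
        assert mk.loglik == pytest.approx(uni.loglik, abs=1e-5)

    def test_variance_component_recovery(self, kernels):
        K, M = kernels
        rng = np.random.default_rng(61)
        wK, qK = np.linalg.eigh(K)
        wM, qM = np.linalg.eigh(M)
        LK = qK * np.sqrt(np.clip(wK, 0, None))
        LM = qM * np.sqrt(np.clip(wM, 0, None))
        est = []
        for _ in range(50):
            y = (
                LK @ rng.standard_normal(300) * np.sqrt(0.3)
                + LM @ rng.standard_normal(300) * np.sqrt(0.4)
                + rng.standard_normal(300) * np.sqrt(0.3)
            )
            fit = MultiKernelModel(y, K, M).fit()
            est.append((fit.sigma2_K, fit.sigma2_M, fit.sigma2_E))
        est = np.array(est)
        mean = est.mean(axis=0)
        sd_mean = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for truth, mu, sd in zip((0.3, 0.4, 0.3), mean, sd_mean):
            assert abs(mu - truth) < 3 * sd + 0.03

    def test_loglik_matches_dense_reml_evaluation(self, kernels):
        K, M = kernels
        rng = np.random.default_rng(67)
        y = _draw_univariate(K[:80, :80], 0.5, 0.5, rng)
        model = MultiKernelModel(y, K[:80, :80], M[:80, :80])
        fit = model.fit()
        V = (
            fit.sigma2_K * K[:80, :80]
            + fit.sigma2_M * M[:80, :80]
            + fit.sigma2_E * np.eye(80)
        )
        assert fit.loglik == pytest.approx(
            dense_reml_loglik(y, np.ones((80, 1)), V), abs=1e-8
        )

    def test_collinear_kernels_warn(self, kernels):
        K, _ = kernels
        with pytest.warns(UserWarning, match="identifiable"):
            MultiKernelModel(np.arange(300.0), K, K.copy())
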