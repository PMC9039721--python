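"""LMM engine: profile-likelihood heritability and association score tests."""

import numpy as np
import pytest
from scipy import optimize, stats

from hwdlmm import (
    HWDSpec,
    KinshipMatrix,
    chisq1_pvalue,
    expected_h2_estimate,
    fit_h2_pairs,
    fit_null_lmm,
    indep_score_test,
    lmm_score_test,
)
from hwdlmm.experiments import ExperimentConfig, _replicate_chunks
from hwdlmm.lmm import lmm_score_many

from conftest import dense_sigma, dense_symmetric_score


def dense_loglik(y2, h2, method="ml"):
    """Independent dense-matrix profile log-likelihood for sib pairs."""
    y = np.asarray(y2, float).ravel()
    n = len(y)
    X = np.ones((n, 1))
    R = dense_sigma(n // 2, 0.5 * h2)
    Ri = np.linalg.inv(R)
    beta = np.linalg.solve(X.T @ Ri @ X, X.T @ Ri @ y)
    e = y - X @ beta
    rss = e @ Ri @ e
    sign, logdet_r = np.linalg.slogdet(R)
    if method == "ml":
        s2 = rss / n
        return -0.5 * (n * (np.log(2 * np.pi * s2) + 1) + logdet_r)
    s2 = rss / (n - 1)
    sign, logdet_x = np.linalg.slogdet(X.T @ Ri @ X)
    return -0.5 * ((n - 1) * (np.log(2 * np.pi * s2) + 1) + logdet_r + logdet_x)


class TestFitNullLmm:
    @pytest.mark.parametrize("method", ["ml", "reml"])
    def test_matches_dense_grid_search(self, toy_pairs, method):
        y, _, _ = toy_pairs
        fit = fit_null_lmm(y, mode="estimated", method=method)
        grid = np.arange(-1.9, 1.9001, 1e-3)
        vals = [dense_loglik(y, h, method) for h in grid]
        h_grid = grid[int(np.argmax(vals))]
        assert fit.h2_hat == pytest.approx(h_grid, abs=2e-3)
        # sigma profile at the optimum, dense route
        R = dense_sigma(y.shape[0], 0.5 * fit.h2_hat)
        Ri = np.linalg.inv(R)
        yf = y.ravel()
        e = yf - yf.mean()  # GLS intercept equals pooled mean for constant blocks
        rss = e @ Ri @ e
        dof = len(yf) if method == "ml" else len(yf) - 1
        assert fit.sigma_y2_hat == pytest.approx(rss / dof, rel=1e-6)

    @pytest.mark.parametrize("method", ["ml", "reml"])
    def test_vectorized_agrees_with_scalar_fit(self, rng, method):
        y = rng.normal(size=(40, 30, 2))
        y[:, :, 1] += 0.4 * y[:, :, 0]
        h2_vec, s2_vec = fit_h2_pairs(y, method=method)
        for i in range(0, 40, 8):
            fit = fit_null_lmm(y[i], mode="estimated", method=method)
            assert h2_vec[i] == pytest.approx(fit.h2_hat, abs=1e-6)
            assert s2_vec[i] == pytest.approx(fit.sigma_y2_hat, rel=1e-6)

    def test_equals_direct_correlation_mle(self, rng):
        """h2_hat = 2 x MLE of the intra-pair correlation (direct parameterization)."""
        y = rng.normal(size=(60, 2))
        y[:, 1] += 0.5 * y[:, 0]

        def neg_ll(theta):
            mu, log_s2, z = theta
            rho = np.tanh(z)
            s2 = np.exp(log_s2)
            cov = s2 * np.array([[1, rho], [rho, 1]])
            return -stats.multivariate_normal(mean=[mu, mu], cov=cov).logpdf(y).sum()

        res = optimize.minimize(neg_ll, [0.0, 0.0, 0.1], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        rho_mle = np.tanh(res.x[2])
        fit = fit_null_lmm(y, mode="estimated", method="ml")
        assert fit.h2_hat == pytest.approx(2 * rho_mle, abs=1e-6)

    def test_fixed_mode_plugs_in_h2(self, toy_pairs):
        y, _, _ = toy_pairs
        fit = fit_null_lmm(y, mode="fixed", h2=0.5)
        assert fit.h2_hat == 0.5 and fit.mode == "fixed" and fit.converged

    def test_identity_kinship_recovers_ols_variance(self, rng):
        y = rng.normal(size=(50, 2))
        kin = KinshipMatrix(n_pairs=50, phi=0.0)
        fit = fit_null_lmm(y, kinship=kin, mode="estimated", method="ml")
        assert fit.h2_hat == 0.0
        assert fit.sigma_y2_hat == pytest.approx(y.var(), rel=1e-10)

    def test_no_signal_gives_near_zero_h2(self):
        cfg = ExperimentConfig(delta_causal_grid=(0.0,), n_replicates=2000, seed=21)
        rng = np.random.default_rng(0)
        y = rng.normal(size=(2000, 65, 2))  # pure noise, no genetic signal
        h2_hat, _ = fit_h2_pairs(y, method="reml")
        assert abs(h2_hat.mean()) < 4 * h2_hat.std(ddof=1) / np.sqrt(len(h2_hat))

    def test_estimates_not_truncated_above_one(self):
        cfg = ExperimentConfig(delta_causal_grid=(0.16,), n_replicates=2000, seed=22)
        rng = np.random.default_rng(np.random.SeedSequence(22))
        chunks = [fit_h2_pairs(y, method="reml")[0]
                  for y, _ in _replicate_chunks(cfg, 0.16, rng, tested=False)]
        h2_hat = np.concatenate(chunks)
        assert (h2_hat > 1.0).mean() > 0.1  # E[h2_hat] = 1 here; mass above 1 expected


class TestParameterRecovery:
    @pytest.mark.parametrize("delta", [-0.04, 0.0, 0.06, 0.10, 0.16])
    def test_mean_estimate_tracks_closed_form(self, delta):
        """Mean h2_hat matches h2(pq+delta)/pq within 3 MC SE at large n_pairs.

        500 pairs per replicate keeps the estimator's O(1/n_pairs)
        small-sample bias well below the Monte Carlo resolution.
        """
        cfg = ExperimentConfig(
            delta_causal_grid=(delta,), n_pairs=500, n_replicates=2000, seed=30
        )
        rng = np.random.default_rng(np.random.SeedSequence(30))
        chunks = [fit_h2_pairs(y, method="reml")[0]
                  for y, _ in _replicate_chunks(cfg, delta, rng, tested=False)]
        h2_hat = np.concatenate(chunks)
        target = expected_h2_estimate(0.5, HWDSpec(p=0.2, delta=delta))
        mc_se = h2_hat.std(ddof=1) / np.sqrt(len(h2_hat))
        assert abs(h2_hat.mean() - target) < 3 * mc_se


class TestScoreTests:
    def test_reduces_to_indep_at_identity_kinship(self, rng):
        y = rng.normal(size=(30, 2))
        g = rng.integers(0, 3, size=(30, 2)).astype(float)
        kin = KinshipMatrix(n_pairs=30, phi=0.0)
        t_lmm = lmm_score_test(y, g, kinship=kin, mode="fixed", h2=0.0)
        t_ind = indep_score_test(y.ravel(), g.ravel())
        assert t_lmm.statistic == pytest.approx(t_ind.statistic, abs=1e-10)

    def test_matches_dense_projector_route(self, toy_pairs):
        y, g, z = toy_pairs
        for h2 in (0.0, 0.5, -0.8):
            res = lmm_score_test(y, g.astype(float), covariates=z, mode="fixed", h2=h2)
            X = np.column_stack([np.ones(6), z.ravel()])
            expected = dense_symmetric_score(
                y, g.astype(float), X, dense_sigma(3, 0.5 * h2)
            )
            assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_vectorized_matches_scalar(self, rng):
        y = rng.normal(size=(20, 40, 2))
        g = rng.integers(0, 3, size=(20, 40, 2)).astype(float)
        t_vec = lmm_score_many(y, g, 0.25)
        for i in (0, 7, 19):
            res = lmm_score_test(y[i], g[i], mode="fixed", h2=0.5)
            assert t_vec[i] == pytest.approx(res.statistic, rel=1e-10)

    def test_indep_two_route_and_range(self, toy_pairs):
        y, g, z = toy_pairs
        res = indep_score_test(y.ravel(), g.ravel(), z.ravel())
        # independent route: residual-on-residual squared correlation
        X = np.column_stack([np.ones(6), z.ravel()])
        Q, _ = np.linalg.qr(X)
        ry = y.ravel() - Q @ (Q.T @ y.ravel())
        rg = g.ravel().astype(float) - Q @ (Q.T @ g.ravel().astype(float))
        expected = 6 * (rg @ ry) ** 2 / ((rg @ rg) * (ry @ ry))
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert 0 <= res.statistic <= 6

    def test_indep_invariances(self, toy_pairs):
        y, g, z = toy_pairs
        base = indep_score_test(y.ravel(), g.ravel(), z.ravel()).statistic
        trans = indep_score_test(
            (3.2 * y - 1.1).ravel(), (2 - g).ravel(), (-0.7 * z + 4).ravel()
        ).statistic
        assert trans == pytest.approx(base, rel=1e-10)

    def test_indep_orthogonal_gives_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        g = np.array([1.0, 1.0, 2.0, 2.0])  # centered g orthogonal to centered y
        assert indep_score_test(y, g).statistic == pytest.approx(0.0, abs=1e-12)

    def test_indep_degenerate_rejected(self):
        y = np.arange(6.0)
        with pytest.raises(ValueError):
            indep_score_test(y, np.ones(6))

    def test_chisq1_pvalue(self):
        assert chisq1_pvalue(0.0) == 1.0
        assert chisq1_pvalue(3.841458820694124) == pytest.approx(0.05, abs=1e-9)
        assert chisq1_pvalue(6.6348966010212145) == pytest.approx(0.01, abs=1e-9)
        with pytest.raises(ValueError):
            chisq1_pvalue(-1.0)


class TestNullCalibration:
    def test_pvalues_uniform_under_full_null_fixed_true_h2(self):
        """KS test of p-value uniformity, delta_causal = delta_tested = 0."""
        cfg = ExperimentConfig(
            delta_causal_grid=(0.0,), delta_tested=0.0, n_replicates=10_000, seed=40
        )
        rng = np.random.default_rng(np.random.SeedSequence(40))
        stats_chunks = [
            lmm_score_many(y, g, 0.5 * 0.5)
            for y, g in _replicate_chunks(cfg, 0.0, rng, tested=True)
        ]
        p = stats.chi2.sf(np.concatenate(stats_chunks), df=1)
        assert stats.kstest(p, "uniform").pvalue > 0.001
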