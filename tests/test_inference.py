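"""PGLS fitting, diagnostics, Pagel's lambda, ANCOVA and the residual cascade."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import birdacuity as ba
from birdacuity.inference import (
    FitError,
    ancova_interaction,
    cooks_distance,
    fit_gls,
    pagels_lambda,
    residual_cascade,
)


def _random_instance(seed, n=30, p=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n)
    return X, y


class TestFitGls:
    def test_perfect_fit_ols_limit(self):
        X = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
        f = fit_gls(X, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(f.beta, [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(f.residuals, 0.0, atol=1e-12)
        assert f.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_covariance_equals_ols(self, seed):
        X, y = _random_instance(seed)
        f = fit_gls(X, y)
        o = sm.OLS(y, X).fit()
        np.testing.assert_allclose(f.beta, o.params, atol=1e-10)
        np.testing.assert_allclose(f.se, o.bse, atol=1e-10)
        np.testing.assert_allclose(f.t_stats, o.tvalues, atol=1e-8)
        np.testing.assert_allclose(f.r_squared, o.rsquared, atol=1e-10)

    @pytest.mark.parametrize("scale", [0.5, 1.0, 7.3])
    def test_scaled_identity_invariance(self, scale):
        X, y = _random_instance(7)
        f1 = fit_gls(X, y)
        f2 = fit_gls(X, y, scale * np.eye(len(y)))
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-10)
        np.testing.assert_allclose(f1.se, f2.se, atol=1e-10)
        np.testing.assert_allclose(f1.t_stats, f2.t_stats, atol=1e-8)

    def test_matches_explicit_inverse_gls(self, worked_tree):
        # closed-form oracle: beta = (X' C^-1 X)^-1 X' C^-1 y by direct inversion
        C = worked_tree.vcv()
        order = [C.taxa.index(t) for t in "ABC"]
        M = C.matrix[np.ix_(order, order)]
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 2.0, 3.0])
        X = np.column_stack([np.ones(3), x])
        Minv = np.linalg.inv(M)
        beta_oracle = np.linalg.inv(X.T @ Minv @ X) @ (X.T @ Minv @ y)
        f = fit_gls(X, y, M)
        np.testing.assert_allclose(f.beta, beta_oracle, atol=1e-12)

    def test_matches_statsmodels_gls(self, rng):
        tree = ba.simulate_yule_tree(25, seed=9)
        M = tree.vcv().matrix
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        y = rng.normal(size=25)
        f = fit_gls(X, y, M)
        g = sm.GLS(y, X, sigma=M).fit()
        np.testing.assert_allclose(f.beta, g.params, atol=1e-10)
        np.testing.assert_allclose(f.se, g.bse, atol=1e-10)

    def test_loglik_invariant_to_taxon_permutation(self, rng):
        tree = ba.simulate_yule_tree(15, seed=3)
        M = tree.vcv().matrix
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = rng.normal(size=15)
        f = fit_gls(X, y, M)
        perm = rng.permutation(15)
        f2 = fit_gls(X[perm], y[perm], M[np.ix_(perm, perm)])
        assert f.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert f.aic == pytest.approx(f2.aic, abs=1e-8)

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(FitError, match="rank"):
            fit_gls(X, np.arange(10.0))

    def test_mismatched_covariance_raises(self):
        X, y = _random_instance(0, n=10)
        with pytest.raises(FitError, match="mismatch|observations"):
            fit_gls(X, y, np.eye(8))


class TestCooksDistance:
    def test_identity_matches_statsmodels(self):
        X, y = _random_instance(11, n=25)
        f = fit_gls(X, y)
        sm_cooks = sm.OLS(y, X).fit().get_influence().cooks_distance[0]
        np.testing.assert_allclose(f.cooks_d, sm_cooks, atol=1e-10)
        np.testing.assert_allclose(cooks_distance(f, X, y), sm_cooks, atol=1e-10)

    def test_gross_outlier_has_max_distance(self):
        rng = np.random.default_rng(5)
        n = 40
        X = np.column_stack([np.ones(n), np.linspace(0, 1, n)])
        y = X @ [1.0, 2.0] + 0.05 * rng.normal(size=n)
        y[17] += 5.0
        f = fit_gls(X, y)
        assert np.argmax(f.cooks_d) == 17

    def test_leave_one_out_oracle(self):
        # D_i = sum_j (yhat_j - yhat_j(-i))^2 / (p * s2), refitting explicitly
        X, y = _random_instance(13, n=15, p=2)
        f = fit_gls(X, y)
        n, p = X.shape
        D = []
        for i in range(n):
            mask = np.arange(n) != i
            fi = fit_gls(X[mask], y[mask])
            D.append(np.sum((f.fitted - X @ fi.beta) ** 2) / (p * f.sigma2))
        np.testing.assert_allclose(f.cooks_d, D, atol=1e-8)

    def test_whitened_loo_oracle_under_phylogeny(self):
        tree = ba.simulate_yule_tree(12, seed=21)
        M = tree.vcv().matrix
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.multivariate_normal(X @ [0.0, 1.0], M)
        f = fit_gls(X, y, M)
        L = np.linalg.cholesky(M)
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        fw = fit_gls(Xw, yw)
        np.testing.assert_allclose(f.cooks_d, fw.cooks_d, atol=1e-10)


class TestPagelsLambda:
    def test_boundary_zero_lambda(self, star_tree_30):
        # near-star data on a structured tree can land at lambda_hat = 0
        tree = ba.simulate_yule_tree(50, seed=77)
        rng = np.random.default_rng(8)
        res = pagels_lambda(rng.normal(size=50), tree.vcv())
        assert 0.0 <= res.lambda_hat <= 1.0
        assert res.lrt_stat >= 0.0
        if res.lambda_hat == 0.0:
            assert res.p_value == 1.0

    def test_star_tree_unidentifiable(self, star_tree_30):
        with pytest.raises(FitError, match="unidentifiable"):
            pagels_lambda(np.random.default_rng(0).normal(size=30), star_tree_30.vcv())

    def test_constant_response_raises(self, worked_tree):
        tree = ba.simulate_yule_tree(10, seed=0)
        with pytest.raises(FitError, match="constant"):
            pagels_lambda(np.ones(10), tree.vcv())

    def test_recovers_brownian_signal(self):
        tree = ba.simulate_yule_tree(200, seed=31)
        C = tree.vcv()
        y = ba.simulate_bm(None, 1.0, lambda_gen=1.0, seed=32, C=C)
        res = pagels_lambda(y.to_numpy(), C)
        assert res.lambda_hat > 0.9
        assert res.p_value < 1e-6

    def test_near_zero_for_iid_trait(self):
        tree = ba.simulate_yule_tree(200, seed=33)
        C = tree.vcv()
        y = ba.simulate_bm(None, 1.0, lambda_gen=0.0, seed=34, C=C)
        res = pagels_lambda(y.to_numpy(), C)
        assert res.lambda_hat < 0.2

    def test_matches_phytools_frozen_values(self):
        # frozen from phytools::phylosig on the identical tree and trait
        # (80-tip Yule tree, seed 124, lambda_gen 0.3)
        rng = np.random.default_rng(124)
        tree = ba.simulate_yule_tree(80, rng=rng)
        C = tree.vcv()
        y = ba.simulate_bm(None, 1.0, lambda_gen=0.3, rng=rng, C=C)
        res = pagels_lambda(y.to_numpy(), C)
        assert res.lambda_hat == pytest.approx(0.595941, abs=5e-5)
        assert res.loglik_hat == pytest.approx(-164.7681, abs=5e-3)
        assert res.loglik_zero == pytest.approx(-169.8949, abs=5e-3)
        assert res.p_value == pytest.approx(0.001364, rel=1e-2)


class TestAncova:
    def test_identity_reduces_to_ols(self):
        rng = np.random.default_rng(17)
        n = 40
        x = rng.normal(size=n)
        f = np.repeat(["a", "b"], n // 2)
        y = 1.0 + 0.5 * x + (f == "b") * 0.3 + rng.normal(size=n)
        res = ancova_interaction(y, x, f)
        D = (f == "b").astype(float)
        X = np.column_stack([np.ones(n), x, D, x * D])
        o = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.fit.beta, o.params, atol=1e-10)
        assert res.p_interaction == pytest.approx(o.pvalues[3], abs=1e-10)
        assert res.interaction_test == "t"

    def test_detects_slope_difference(self):
        rng = np.random.default_rng(23)
        n = 60
        x = rng.normal(size=n)
        f = np.repeat(["a", "b"], n // 2)
        y = x * np.where(f == "a", 0.5, 2.0) + 0.2 * rng.normal(size=n)
        res = ancova_interaction(y, x, f)
        assert res.p_interaction < 1e-4

    def test_three_levels_uses_lrt(self):
        rng = np.random.default_rng(29)
        n = 60
        x = rng.normal(size=n)
        f = np.repeat(["a", "b", "c"], n // 3)
        y = 1.0 + x + rng.normal(size=n)
        res = ancova_interaction(y, x, f)
        assert res.interaction_test == "lrt"
        assert 0.0 <= res.p_interaction <= 1.0

    def test_small_level_raises(self):
        with pytest.raises(FitError, match="< 2"):
            ancova_interaction(np.arange(5.0), np.arange(5.0), ["a", "a", "a", "a", "b"])


class TestResidualCascade:
    def test_zero_noise_degenerate(self, rng):
        tree = ba.simulate_yule_tree(20, seed=41)
        C = tree.vcv()
        mass = ba.simulate_bm(None, 1.0, seed=42, C=C).to_numpy()
        eye = 1.0 + 0.23 * mass  # exactly allometric
        acuity = 0.5 + 0.81 * eye
        with pytest.raises(FitError):
            residual_cascade(acuity, eye, mass, C.matrix)

    def test_eye_investment_offset_detected(self):
        # species given extra eye investment must show higher relative eye size
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            tree = ba.simulate_yule_tree(60, rng=rng)
            C = tree.vcv()
            mass = ba.simulate_bm(None, 1.0, rng=rng, C=C).to_numpy()
            noise = ba.simulate_bm(None, 0.01, rng=rng, C=C).to_numpy()
            offset = np.zeros(60)
            marked = rng.choice(60, size=15, replace=False)
            offset[marked] = 3.0 * noise.std()
            eye = 1.0 + 0.23 * mass + noise + offset
            acuity = 0.5 + 0.81 * eye + ba.simulate_bm(None, 0.02, rng=rng, C=C).to_numpy()
            rel, resid, _ = residual_cascade(acuity, eye, mass, C.matrix)
            unmarked = np.setdiff1d(np.arange(60), marked)
            hits += rel[marked].mean() > rel[unmarked].mean()
        assert hits == 20

    def test_residuals_taxon_aligned(self, rng):
        tree = ba.simulate_yule_tree(30, seed=43)
        C = tree.vcv()
        mass = ba.simulate_bm(None, 1.0, seed=44, C=C).to_numpy()
        eye = 1.0 + 0.23 * mass + ba.simulate_bm(None, 0.05, seed=45, C=C).to_numpy()
        acuity = 0.5 + 0.81 * eye + ba.simulate_bm(None, 0.05, seed=46, C=C).to_numpy()
        rel, resid, (f1, f2) = residual_cascade(acuity, eye, mass, C.matrix)
        np.testing.assert_allclose(rel, eye - f1.fitted)
        np.testing.assert_allclose(resid, acuity - f2.fitted)
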