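"""Spatial lag model: ML estimation, prediction, cross-validation."""

import numpy as np
import pytest
from scipy import sparse

from greenheat.grid import GridSpec
from greenheat.slm import (
    SpatialLagRegressor,
    kfold_cv,
    ols_fit,
    slm_fit_ml,
    slm_predict,
)
from greenheat.synth import slm_dgp
from greenheat.weights import knn_weights


def grid_weights(n_rows, n_cols, k=8):
    x, y = GridSpec(n_rows, n_cols).centroids()
    return knn_weights(np.column_stack([x, y]), k=k)


def dense_concentrated_loglik(X, y, Wd, rho):
    """Textbook concentrated log-likelihood with dense determinants."""
    n = len(y)
    e = y - rho * (Wd @ y)
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    resid = e - X @ beta
    s2 = resid @ resid / n
    sign, logdet = np.linalg.slogdet(np.eye(n) - rho * Wd)
    assert sign > 0
    return -(n / 2) * (np.log(2 * np.pi) + 1) - (n / 2) * np.log(s2) + logdet, beta


class TestOls:
    def test_exact_linear_data_interpolated(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ [1.0, -2.0]
        beta, r2, mae = ols_fit(X, y)
        np.testing.assert_allclose(beta, [1.0, -2.0], atol=1e-10)
        assert r2 == pytest.approx(1.0)
        assert mae == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_outcome_gives_zero_slopes(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])  # orthogonal to 1 and x
        X = np.column_stack([np.ones(4), x])
        beta, _, _ = ols_fit(X, y)
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)

    def test_matches_normal_equations(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        beta, _, _ = ols_fit(X, y)
        longhand = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, longhand, atol=1e-10)

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            ols_fit(X, np.arange(10.0))


class TestSlmFitMl:
    def test_nonspatial_data_recovers_rho_near_zero(self):
        W = grid_weights(12, 12)
        rng = np.random.default_rng(2)
        x = rng.uniform(size=144)
        y = 3.0 + 2.0 * x + rng.normal(0, 0.3, 144)
        m = slm_fit_ml(x, y, W)
        # |rho| < 2 SE ~ 2 / sqrt(n)
        assert abs(m.rho_) < 2 / np.sqrt(144)
        beta_ols, _, _ = ols_fit(np.column_stack([np.ones(144), x]), y)
        # slope agrees tightly; the intercept absorbs the small rho estimate
        assert m.coef_[0] == pytest.approx(beta_ols[1], abs=0.05)
        assert m.intercept_ == pytest.approx(beta_ols[0], abs=0.5)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_dense_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        coords = rng.uniform(0, 30, size=(n, 2))
        W = knn_weights(coords, k=6)
        X = np.column_stack([np.ones(n), rng.uniform(size=n)])
        y = slm_dgp(X, W, [4.0, -2.0], rho=0.4, sigma=0.6, seed=seed + 10)
        m = SpatialLagRegressor().fit(X[:, 1:], y, W)

        Wd = W.matrix.toarray()
        grid = np.arange(-0.90, 0.995, 0.01)
        lls = [dense_concentrated_loglik(X, y, Wd, r)[0] for r in grid]
        rho_star = grid[int(np.argmax(lls))]
        assert abs(m.rho_ - rho_star) <= 0.01 + 1e-9
        # beta at the ML rho matches the dense computation
        _, beta_dense = dense_concentrated_loglik(X, y, Wd, m.rho_)
        np.testing.assert_allclose(m.beta_, beta_dense, atol=1e-8)

    def test_loglik_never_below_ols_submodel(self, rng):
        for seed in range(4):
            n = 64
            W = grid_weights(8, 8)
            X = rng.uniform(size=(n, 2))
            y = rng.normal(size=n) + X @ [1.0, -1.0]
            m = SpatialLagRegressor().fit(X, y, W)
            assert m.loglik_ >= m.log_likelihood_ols(X, y) - 1e-8

    def test_boundary_hit_flagged_nonconverged(self):
        W = grid_weights(7, 7)
        rng = np.random.default_rng(0)
        x = rng.uniform(size=49)
        y = slm_dgp(np.column_stack([np.ones(49), x]), W, [1.0, 1.0],
                    rho=0.9, sigma=0.05, seed=1)
        m = SpatialLagRegressor(rho_bounds=(-0.5, 0.5)).fit(x, y, W)
        assert not m.converged_

    def test_tsls_alternative_close_to_ml(self):
        W = grid_weights(20, 20)
        rng = np.random.default_rng(5)
        x = rng.uniform(size=400)
        y = slm_dgp(np.column_stack([np.ones(400), x]), W, [5.0, -3.0],
                    rho=0.5, sigma=0.3, seed=6)
        ml = SpatialLagRegressor().fit(x, y, W)
        ts = SpatialLagRegressor(method="tsls").fit(x, y, W)
        assert ts.rho_ == pytest.approx(ml.rho_, abs=0.15)
        assert ts.coef_[0] == pytest.approx(ml.coef_[0], abs=0.5)

    def test_sklearn_param_interface(self):
        m = SpatialLagRegressor(rho_bounds=(-0.5, 0.9))
        assert m.get_params()["rho_bounds"] == (-0.5, 0.9)
        m.set_params(method="tsls")
        assert m.method == "tsls"


class TestSlmPredict:
    def test_intercept_only_constant_closed_form(self):
        W = grid_weights(5, 5)
        m = SpatialLagRegressor()
        m.intercept_, m.coef_, m.rho_ = 10.0, np.zeros(1), 0.5
        yhat = slm_predict(m, np.zeros((25, 1)), W)
        np.testing.assert_allclose(yhat, 20.0, atol=1e-10)

    def test_rho_zero_reduces_to_linear_prediction(self, rng):
        W = grid_weights(4, 5)
        m = SpatialLagRegressor()
        m.intercept_, m.coef_, m.rho_ = 1.0, np.array([2.0, -1.0]), 0.0
        X = rng.uniform(size=(20, 2))
        np.testing.assert_allclose(
            slm_predict(m, X, W), 1.0 + X @ [2.0, -1.0], atol=1e-12
        )

    def test_matches_dense_inverse_on_8_pixels(self, rng):
        coords = rng.uniform(0, 5, size=(8, 2))
        W = knn_weights(coords, k=3)
        m = SpatialLagRegressor()
        m.intercept_, m.coef_, m.rho_ = 0.5, np.array([1.5]), 0.35
        X = rng.uniform(size=(8, 1))
        yhat = slm_predict(m, X, W)
        xb = 0.5 + X.ravel() * 1.5
        dense = np.linalg.inv(np.eye(8) - 0.35 * W.matrix.toarray()) @ xb
        np.testing.assert_allclose(yhat, dense, atol=1e-10)

    def test_clipping_logged(self):
        W = grid_weights(4, 4)
        m = SpatialLagRegressor()
        m.intercept_, m.coef_, m.rho_ = 100.0, np.zeros(1), 0.0
        yhat = slm_predict(m, np.zeros((16, 1)), W, clip=(0.0, 92.0))
        assert np.all(yhat == 92.0)
        assert m.last_n_clipped_ == 16


class TestKfoldCv:
    def test_noiseless_dgp_predicted_nearly_perfectly(self):
        W = grid_weights(15, 15)
        rng = np.random.default_rng(1)
        x = rng.uniform(size=225)
        y = slm_dgp(np.column_stack([np.ones(225), x]), W, [8.0, -4.0],
                    rho=0.4, sigma=0.0, seed=2)
        report = kfold_cv(x, y, W, n_folds=5, seed=0)
        assert (report.folds["r2_test"] > 0.95).all()

    def test_permuted_outcome_has_no_skill(self):
        W = grid_weights(12, 12)
        rng = np.random.default_rng(3)
        x = rng.uniform(size=144)
        y = slm_dgp(np.column_stack([np.ones(144), x]), W, [8.0, -4.0],
                    rho=0.5, sigma=0.3, seed=4)
        report = kfold_cv(x, rng.permutation(y), W, n_folds=4, seed=0)
        assert report.folds["r2_test"].mean() < 0.3

    def test_fold_scores_match_hand_computation(self):
        """Reproduce one fold end to end with dense algebra: restrict W,
        grid-search the concentrated likelihood, predict by dense inverse."""
        from sklearn.model_selection import KFold

        W = grid_weights(6, 7, k=4)
        n = 42
        rng = np.random.default_rng(7)
        x = rng.uniform(size=n)
        y = slm_dgp(np.column_stack([np.ones(n), x]), W, [5.0, -2.0],
                    rho=0.3, sigma=0.4, seed=8)
        report = kfold_cv(x, y, W, n_folds=2, seed=11)

        tr, te = next(iter(KFold(2, shuffle=True, random_state=11).split(x)))
        Wd = W.matrix.toarray()[np.ix_(tr, tr)]
        rs = Wd.sum(axis=1, keepdims=True)
        Wd = np.divide(Wd, rs, out=np.zeros_like(Wd), where=rs > 0)
        Xtr = np.column_stack([np.ones(len(tr)), x[tr]])
        grid = np.arange(-0.98, 0.985, 0.0005)
        lls = [dense_concentrated_loglik(Xtr, y[tr], Wd, r)[0] for r in grid]
        rho = grid[int(np.argmax(lls))]
        _, beta = dense_concentrated_loglik(Xtr, y[tr], Wd, rho)
        Xall = np.column_stack([np.ones(n), x])
        yhat = np.linalg.inv(np.eye(n) - rho * W.matrix.toarray()) @ (Xall @ beta)
        mae = np.abs(y[te] - yhat[te]).mean()
        assert report.folds["mae_test"].iloc[0] == pytest.approx(mae, rel=1e-2)

    def test_averaged_coefficients_are_fold_means(self):
        W = grid_weights(10, 10)
        rng = np.random.default_rng(9)
        x = rng.uniform(size=100)
        y = slm_dgp(np.column_stack([np.ones(100), x]), W, [6.0, -3.0],
                    rho=0.4, sigma=0.3, seed=10)
        report = kfold_cv(x, y, W, n_folds=4, seed=1)
        cols = [c for c in report.folds.columns if c.startswith("beta_")]
        np.testing.assert_allclose(
            report.mean_beta, report.folds[cols].mean().to_numpy()
        )
        assert report.mean_rho == pytest.approx(report.folds["rho"].mean())

    def test_fold_smaller_than_feature_count_rejected(self, rng):
        W = grid_weights(3, 3, k=3)
        X = rng.uniform(size=(9, 5))  # 6 columns with intercept > 4-pixel fold
        with pytest.raises(ValueError, match="fold"):
            kfold_cv(X, np.arange(9.0), W, n_folds=2)


class TestConsistency:
    def test_estimation_error_shrinks_with_sample_size(self):
        """RMSE of (beta, rho) estimates over repeated draws shrinks from
        n = 100 to n = 1600 (consistency of the ML estimator)."""
        rmse = {}
        truth = np.array([5.0, -4.0, 0.5])
        for side, n_rep in ((10, 8), (20, 8), (40, 4)):
            W = grid_weights(side, side)
            n = side * side
            errs = []
            rng = np.random.default_rng(100 + side)
            for r in range(n_rep):
                x = rng.uniform(size=n)
                y = slm_dgp(np.column_stack([np.ones(n), x]), W,
                            truth[:2], rho=truth[2], sigma=0.5,
                            seed=int(rng.integers(2**31)))
                m = SpatialLagRegressor().fit(x, y, W)
                errs.append([m.intercept_ - 5.0, m.coef_[0] + 4.0,
                             m.rho_ - 0.5])
            rmse[n] = np.sqrt(np.mean(np.square(errs), axis=0))
        assert np.all(rmse[1600] < rmse[100])
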