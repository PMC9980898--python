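"""Classical baselines: penalized fits against closed-form and generic-
optimizer oracles, kernel contracts, and grid selection."""

import numpy as np
import pytest
from scipy import optimize, stats

from connectomepred import linear


@pytest.fixture()
def regression_instance(rng):
    X = rng.normal(size=(60, 12))
    beta = rng.normal(size=12)
    y = X @ beta + 0.1 * rng.normal(size=60)
    return X, y, beta


class TestRidge:
    def test_huge_lambda_shrinks_to_zero(self, regression_instance):
        X, y, _ = regression_instance
        fit = linear.fit_ridge(X, y, lam=1e6)
        assert np.linalg.norm(fit.betas) < 1e-3

    def test_lambda_zero_equals_ols(self, regression_instance):
        X, y, _ = regression_instance
        fit = linear.fit_ridge(X, y, lam=0.0)
        design = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.abs(fit.betas - ols[1:]).max() < 1e-8
        assert fit.intercept == pytest.approx(ols[0], abs=1e-8)

    def test_noiseless_recovery(self, rng):
        X = rng.normal(size=(80, 10))
        beta = rng.normal(size=10)
        fit = linear.fit_ridge(X, X @ beta, lam=1e-8)
        assert np.corrcoef(fit.betas, beta)[0, 1] > 0.999

    def test_primal_and_dual_solves_agree(self, rng):
        X = rng.normal(size=(20, 50))  # n < p triggers the dual path
        y = rng.normal(size=20)
        dual = linear.fit_ridge(X, y, lam=2.0)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        primal = np.linalg.solve(Xc.T @ Xc + 2.0 * np.eye(50), Xc.T @ yc)
        assert np.abs(dual.betas - primal).max() < 1e-8

    def test_norm_monotone_in_lambda(self, regression_instance):
        X, y, _ = regression_instance
        norms = [np.linalg.norm(linear.fit_ridge(X, y, lam).betas)
                 for lam in [0.01, 0.1, 1.0, 10.0, 100.0]]
        assert np.all(np.diff(norms) < 0)

    def test_logistic_variant_separates(self, rng):
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] > 0).astype(float)
        fit = linear.fit_ridge(X, y, lam=1e-3, task="classification")
        assert np.mean((fit.decision(X) > 0) == (y > 0.5)) > 0.95

    def test_non_finite_rejected(self, regression_instance):
        X, y, _ = regression_instance
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            linear.fit_ridge(X, y, 1.0)


class TestLasso:
    def test_all_zero_above_critical_lambda(self, regression_instance):
        """In the summed-loss convention ||y-Xb||^2 + lam*||b||_1 the fit is
        all-zero iff lam >= 2*max|Xc' yc| (KKT condition at b=0)."""
        X, y, _ = regression_instance
        Xc = X - X.mean(axis=0)
        lam_max = 2.0 * np.abs(Xc.T @ (y - y.mean())).max()
        assert np.all(linear.fit_lasso(X, y, lam_max * 1.01).betas == 0.0)
        assert np.any(linear.fit_lasso(X, y, lam_max * 0.8).betas != 0.0)

    def test_planted_sparse_support_recovered(self, rng):
        X = rng.normal(size=(300, 60))
        beta = np.zeros(60)
        support = rng.choice(60, size=10, replace=False)
        beta[support] = rng.choice([-1.0, 1.0], size=10) * 2.0
        y = X @ beta + 0.2 * rng.normal(size=300)
        fit = linear.fit_lasso(X, y, lam=30.0)
        assert set(support) <= set(np.flatnonzero(fit.betas))

    def test_small_lambda_approaches_ols(self, regression_instance):
        X, y, _ = regression_instance
        fit = linear.fit_lasso(X, y, lam=1e-8)
        design = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.abs(fit.betas - ols[1:]).max() < 1e-3

    def test_support_size_non_increasing_in_lambda(self, regression_instance):
        X, y, _ = regression_instance
        sizes = [np.count_nonzero(linear.fit_lasso(X, y, lam).betas)
                 for lam in [0.01, 0.5, 5.0, 50.0, 500.0]]
        assert np.all(np.diff(sizes) <= 0)


class TestSVM:
    def test_separated_clouds_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 1, size=(30, 4)),
                       rng.normal(3, 1, size=(30, 4))])
        y = np.repeat([0.0, 1.0], 30)
        fit = linear.fit_linear_svm(X, y, lam=0.01)
        assert np.mean((fit.decision(X) > 0) == (y > 0.5)) == 1.0

    def test_huge_epsilon_tube_flattens_fit(self, rng):
        X = rng.normal(size=(50, 4))
        y = 0.01 * rng.normal(size=50)  # range << default tube? force it:
        fit = linear.fit_linear_svm(X, y, lam=1.0, task="regression",
                                    epsilon_divisor=1e-4)  # tube >> range(y)
        assert np.linalg.norm(fit.betas) < 1e-6

    def test_objective_matches_generic_qp_oracle(self, rng):
        """Hinge-loss primal solved by a generic constrained optimizer on a
        tiny instance reaches the same objective value."""
        X = rng.normal(size=(20, 3))
        y_pm = np.sign(X[:, 0] + 0.5 * rng.normal(size=20))
        y01 = (y_pm > 0).astype(float)
        lam = 0.5
        fit = linear.fit_linear_svm(X, y01, lam=lam)

        def objective(wb):
            w, b = wb[:3], wb[3]
            margins = y_pm * (X @ w + b)
            return lam * w @ w + np.maximum(0.0, 1.0 - margins).sum()

        ours = objective(np.concatenate([fit.betas, [fit.intercept]]))
        best = min(
            optimize.minimize(objective, x0, method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12,
                                       "maxiter": 20000}).fun
            for x0 in [np.zeros(4),
                       np.concatenate([fit.betas, [fit.intercept]])])
        assert ours == pytest.approx(best, rel=1e-3)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            linear.fit_linear_svm(X, np.ones(10), lam=1.0)


class TestKRR:
    def test_kernel_contract(self, rng):
        V = rng.normal(size=(25, 40))
        K = linear.pearson_kernel(V)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        # K + lam*I is PSD for any positive lam large enough to lift the
        # smallest eigenvalue above zero; check at lam = |min eig| + eps
        lam = abs(np.linalg.eigvalsh(K).min()) + 1e-8
        assert np.linalg.eigvalsh(K + lam * np.eye(25)).min() >= -1e-10

    def test_dual_matches_direct_linear_algebra_oracle(self, rng):
        V = rng.normal(size=(30, 50))
        y = rng.normal(size=30)
        fit = linear.fit_krr(V, y, lam=0.7)
        K = np.corrcoef(V)
        alpha = np.linalg.solve(K + 0.7 * np.eye(30), y)
        assert np.abs(fit.alphas - alpha).max() < 1e-6
        Vnew = rng.normal(size=(5, 50))
        Knew = np.array([[stats.pearsonr(a, b)[0] for b in V] for a in Vnew])
        assert np.abs(fit.predict(Vnew) - Knew @ alpha).max() < 1e-6

    def test_interpolation_limit(self, rng):
        V = rng.normal(size=(30, 60))
        y = rng.normal(size=30)
        fit = linear.fit_krr(V, y, lam=1e-10)
        assert np.abs(fit.predict(V) - y).max() < 1e-4

    def test_constant_vector_rejected(self, rng):
        V = rng.normal(size=(10, 20))
        V[3] = 2.0
        with pytest.raises(ValueError):
            linear.fit_krr(V, np.zeros(10), lam=1.0)


class TestLambdaSelection:
    def test_choice_equals_exhaustive_argmax(self, rng):
        X = rng.normal(size=(120, 30))
        beta = np.zeros(30)
        beta[:5] = 1.0
        y = X @ beta + 2.0 * rng.normal(size=120)
        grid = linear.lambda_grid(40)
        tr, va = np.arange(80), np.arange(80, 120)
        chosen, curves = linear.select_lambda("ridge", "regression", X, y,
                                              [(tr, va)], grid)
        # independent exhaustive oracle
        scores = []
        for lam in grid:
            fit = linear.fit_ridge(X[tr], y[tr], lam)
            scores.append(stats.pearsonr(fit.predict(X[va]), y[va])[0])
        scores = np.array(scores)
        best = np.flatnonzero(scores >= scores.max() - 1e-12)[-1]
        assert chosen[0] == grid[best]
        assert np.allclose(curves[0], scores)
        assert chosen[0] in grid

    def test_degenerate_target_picks_largest_lambda(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.zeros(40)  # every lambda ties
        grid = linear.lambda_grid(20)
        chosen, _ = linear.select_lambda("ridge", "regression", X, y,
                                         [(np.arange(30), np.arange(30, 40))],
                                         grid)
        assert chosen[0] == grid[-1]

    def test_empty_fold_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            linear.select_lambda("ridge", "regression", X, y,
                                 [(np.arange(10), np.arange(0))],
                                 linear.lambda_grid(5))


def test_covariate_betas_reported_separately(rng):
    X = rng.normal(size=(80, 10))
    cov = rng.normal(size=(80, 2))
    y = X[:, 0] + 3.0 * cov[:, 1] + 0.1 * rng.normal(size=80)
    fit = linear.fit_ridge(np.hstack([X, cov]), y, lam=1e-6, n_covariates=2)
    assert fit.betas.shape == (10,)
    assert fit.cov_betas.shape == (2,)
    assert fit.cov_betas[1] == pytest.approx(3.0, abs=0.1)
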