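"""Classical baselines on vectorized connectomes.

Ridge (linear/logistic), LASSO (linear/logistic), linear SVM
(classification and epsilon-insensitive regression) and Pearson-kernel
ridge regression, with a 300-value log-spaced regularization grid
(1e-6 .. 1e-1) selected per cross-validation fold on the validation
metric (accuracy for classification, Pearson correlation for regression;
ties favour the stronger regularization).

Objective conventions (summed losses, matching the penalized forms
``squareloss + lambda * penalty``):

* ridge regression: ``||y - Xb||^2 + lambda * ||b||^2`` (solved exactly,
  intercept unpenalized, primal or dual depending on n vs p);
* logistic ridge / lasso and the SVMs are fitted by scikit-learn with the
  grid value mapped onto the corresponding C/alpha parameter
  (logistic L2: C = 1/(2 lambda); logistic L1: C = 1/lambda;
  lasso regression: alpha = lambda/(2n); SVM: C = 1/(2 lambda));
* kernel ridge regression is solved in the dual, ``(K + lambda I) a = y``,
  with K the Pearson correlation between subjects' upper-triangle vectors.

Feature vectors are the canonical row-major upper-triangle edge order from
:mod:`connectomepred.preprocess`; optional covariate columns are appended
after the edge features and their betas reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.svm import LinearSVC, LinearSVR

#: divisor turning the interquartile range of y into the epsilon tube of
#: the support-vector regression (IQR/1.349 is a robust sd estimate; the
#: default tube is a tenth of that).
SVR_EPSILON_IQR_DIVISOR = 13.49


def lambda_grid(n_values: int = 300, low: float = 1e-6,
                high: float = 1e-1) -> np.ndarray:
    """Strictly increasing log-spaced regularization grid."""
    return np.logspace(np.log10(low), np.log10(high), n_values)


@dataclass
class LinearFit:
    """A fitted linear model with extractable edge coefficients."""

    betas: np.ndarray
    intercept: float
    lam: float
    model_family: str
    task: str
    cov_betas: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def decision(self, X: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
        d = X @ self.betas + self.intercept
        if cov is not None and self.cov_betas.size:
            d = d + cov @ self.cov_betas
        return d

    def predict(self, X: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
        d = self.decision(X, cov)
        if self.task == "classification":
            return 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500)))
        return d


def _check_finite(X: np.ndarray, y: np.ndarray) -> None:
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")


def _split_cov(betas: np.ndarray, n_covariates: int):
    if n_covariates:
        return betas[:-n_covariates], betas[-n_covariates:]
    return betas, np.zeros(0)


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float,
              task: str = "regression", n_covariates: int = 0) -> LinearFit:
    """L2-penalized least squares (exact) or penalized logistic regression.

    The intercept is unpenalized; for regression this is achieved by
    centering X and y before the penalized solve.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_finite(X, y)
    if task == "regression":
        xm, ym = X.mean(axis=0), y.mean()
        Xc, yc = X - xm, y - ym
        n, p = Xc.shape
        if n >= p:
            beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc)
        else:  # dual solve, identical solution, O(n^3)
            alpha = np.linalg.solve(Xc @ Xc.T + lam * np.eye(n), yc)
            beta = Xc.T @ alpha
        intercept = ym - xm @ beta
    elif task == "classification":
        clf = LogisticRegression(C=1.0 / (2.0 * lam), l1_ratio=0,
                                 solver="lbfgs", tol=1e-8, max_iter=5000)
        clf.fit(X, y)
        beta, intercept = clf.coef_[0], float(clf.intercept_[0])
    else:
        raise ValueError("task must be regression or classification")
    b, cb = _split_cov(beta, n_covariates)
    return LinearFit(betas=b, intercept=float(intercept), lam=lam,
                     model_family="ridge", task=task, cov_betas=cb)


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float,
              task: str = "regression", n_covariates: int = 0) -> LinearFit:
    """L1-penalized fit via coordinate descent; coefficients are exactly 0
    above the critical lambda (2 * max|Xc' yc| in the summed-loss
    convention used here)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_finite(X, y)
    n = X.shape[0]
    if task == "regression":
        mdl = Lasso(alpha=lam / (2.0 * n), tol=1e-7, max_iter=100000)
        mdl.fit(X, y)
        beta, intercept = mdl.coef_, float(mdl.intercept_)
    elif task == "classification":
        mdl = LogisticRegression(C=1.0 / lam, l1_ratio=1,
                                 solver="liblinear", tol=1e-8, max_iter=5000)
        mdl.fit(X, y)
        beta, intercept = mdl.coef_[0], float(mdl.intercept_[0])
    else:
        raise ValueError("task must be regression or classification")
    b, cb = _split_cov(beta, n_covariates)
    return LinearFit(betas=b, intercept=intercept, lam=lam,
                     model_family="lasso", task=task, cov_betas=cb)


def fit_linear_svm(X: np.ndarray, y: np.ndarray, lam: float,
                   task: str = "classification", n_covariates: int = 0,
                   epsilon_divisor: float = SVR_EPSILON_IQR_DIVISOR) -> LinearFit:
    """Linear support-vector machine (hinge loss) or epsilon-insensitive
    support-vector regression, L2-penalized.

    For regression the tube half-width is ``IQR(y) / epsilon_divisor``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_finite(X, y)
    C = 1.0 / (2.0 * lam)
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("classification needs two classes in y")
        # large intercept_scaling leaves the intercept effectively
        # unpenalized, matching the stated objective
        mdl = LinearSVC(C=C, loss="hinge", tol=1e-8, max_iter=200000,
                        intercept_scaling=100.0)
        mdl.fit(X, y)
        beta, intercept = mdl.coef_[0], float(mdl.intercept_[0])
    elif task == "regression":
        eps = float(stats.iqr(y)) / epsilon_divisor
        mdl = LinearSVR(C=C, epsilon=eps, loss="epsilon_insensitive",
                        tol=1e-8, max_iter=200000, intercept_scaling=100.0)
        mdl.fit(X, y)
        beta, intercept = mdl.coef_, float(mdl.intercept_[0])
    else:
        raise ValueError("task must be regression or classification")
    b, cb = _split_cov(beta, n_covariates)
    return LinearFit(betas=b, intercept=intercept, lam=lam,
                     model_family="svm", task=task, cov_betas=cb)


# ---------------------------------------------------------------------------
# kernel ridge regression (Pearson-correlation kernel)
# ---------------------------------------------------------------------------

def pearson_kernel(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Pearson correlation between row vectors of A (and B)."""
    A = np.asarray(A, float)
    Ac = A - A.mean(axis=1, keepdims=True)
    An = np.linalg.norm(Ac, axis=1)
    if np.any(An < 1e-12):
        raise ValueError("constant feature vector: Pearson kernel undefined")
    if B is None:
        Bc, Bn = Ac, An
    else:
        B = np.asarray(B, float)
        Bc = B - B.mean(axis=1, keepdims=True)
        Bn = np.linalg.norm(Bc, axis=1)
        if np.any(Bn < 1e-12):
            raise ValueError("constant feature vector: Pearson kernel undefined")
    return (Ac @ Bc.T) / np.outer(An, Bn)


@dataclass
class KernelFit:
    """Dual-form kernel ridge fit; training vectors are retained because
    the kernel must be evaluated against them at prediction time."""

    alphas: np.ndarray
    train_features: np.ndarray
    lam: float

    def predict(self, new_vectors: np.ndarray) -> np.ndarray:
        K = pearson_kernel(np.asarray(new_vectors, float), self.train_features)
        return K @ self.alphas


def fit_krr(train_vectors: np.ndarray, y: np.ndarray, lam: float) -> KernelFit:
    """Solve ``(K + lambda I) alpha = y`` with the Pearson kernel."""
    train_vectors = np.asarray(train_vectors, float)
    y = np.asarray(y, float)
    _check_finite(train_vectors, y)
    K = pearson_kernel(train_vectors)
    alphas = np.linalg.solve(K + lam * np.eye(len(y)), y)
    return KernelFit(alphas=alphas, train_features=train_vectors, lam=lam)


def predict_krr(fit: KernelFit, new_vectors: np.ndarray) -> np.ndarray:
    return fit.predict(new_vectors)


# ---------------------------------------------------------------------------
# lambda selection
# ---------------------------------------------------------------------------

def _fit_one(model_family: str, task: str, X, y, lam):
    if model_family == "ridge":
        return fit_ridge(X, y, lam, task)
    if model_family == "lasso":
        return fit_lasso(X, y, lam, task)
    if model_family == "svm":
        return fit_linear_svm(X, y, lam, task)
    if model_family == "krr":
        return fit_krr(X, y, lam)
    raise ValueError(f"unknown model family {model_family!r}")


def validation_metric(pred: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "classification":
        return float(np.mean((pred > 0.5) == (y > 0.5)))
    if np.std(pred) < 1e-12 or np.std(y) < 1e-12:
        return -np.inf
    return float(stats.pearsonr(pred, y)[0])


def select_lambda(model_family: str, task: str, X: np.ndarray, y: np.ndarray,
                  folds: list[tuple[np.ndarray, np.ndarray]],
                  grid: np.ndarray | None = None):
    """Per-fold regularization choice by exhaustive grid evaluation.

    ``folds`` is a list of (train_index, validation_index) pairs. For each
    fold every grid value is fitted on the training part and scored on the
    validation part; the argmax wins, ties going to the larger lambda.
    Returns (chosen lambdas, per-fold metric curves over the grid).
    """
    if grid is None:
        grid = lambda_grid()
    grid = np.asarray(grid, float)
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    chosen, curves = [], []
    for tr, va in folds:
        if len(tr) == 0 or len(va) == 0:
            raise ValueError("empty fold")
        scores = np.empty(len(grid))
        for i, lam in enumerate(grid):
            fit = _fit_one(model_family, task, X[tr], y[tr], lam)
            if model_family == "krr":
                pred = fit.predict(X[va])
            elif task == "classification":
                pred = (fit.decision(X[va]) > 0).astype(float)
            else:
                pred = fit.predict(X[va])
            scores[i] = validation_metric(pred, y[va], task)
        best = np.flatnonzero(scores >= scores.max() - 1e-12)[-1]
        chosen.append(float(grid[best]))
        curves.append(scores)
    return chosen, curves
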