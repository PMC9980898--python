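"""Latent phenotype factors.

Two one-factor summaries are derived from the behavioural battery:

* the cognitive **g-factor** — first unrotated principal component of the
  covariance of z-scored cognitive task scores, with per-subject scores
  formed as the loading-weighted sum of z-scored tasks and z-normalized on
  training statistics;
* the **MHQ-factor** — first unrotated principal component of the polychoric
  correlation matrix of ordinal mental-health questionnaire items, scored
  linearly in the z-scored numeric item codes (component scores from ordinal
  data are not uniquely defined; this linear rule is a documented choice).

Both fits are leakage-free: a ``FactorModel`` is estimated from training
rows only and carries every normalization constant needed to score unseen
subjects. Missing questionnaire entries are imputed with regularized
iterative PCA; subjects missing three or more items are dropped, not
imputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def drop_incomplete(table: pd.DataFrame, max_missing: int = 3) -> pd.DataFrame:
    """Drop rows with ``max_missing`` or more missing cells (the inclusion
    rule keeps subjects with *fewer than* ``max_missing`` missing items)."""
    keep = table.isna().sum(axis=1) < max_missing
    return table.loc[keep]


def impute_missing(table: pd.DataFrame, max_components: int = 2,
                   seed: int = 0, max_iter: int = 500,
                   tol: float = 1e-6) -> pd.DataFrame:
    """Regularized iterative-PCA imputation.

    Missing cells are initialized at column means, then refined by
    alternating a truncated, shrunk SVD reconstruction of the centered table
    with re-imputation of only the missing cells, until the imputed values
    stabilize. Observed cells are never altered. Deterministic given the
    input (the seed is accepted for interface stability; the mean start
    makes the iteration deterministic).
    """
    X = table.to_numpy(dtype=float)
    missing = np.isnan(X)
    if missing.all(axis=0).any():
        raise ValueError("a column is entirely missing")
    if not missing.any():
        return table.copy()
    col_means = np.nanmean(X, axis=0)
    X = np.where(missing, col_means[None, :], X)
    k = min(max_components, min(X.shape) - 1)
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # regularization: shrink retained singular values by the mean
        # residual variance, as in regularized iterative PCA; the small
        # constant floor breaks ties among exact-fit completions (rank-
        # deficient tables) toward the minimal-norm one
        noise = (s[k:] ** 2).sum() / max(len(s) - k, 1) + (0.01 * s[0]) ** 2
        shrunk = np.maximum(s[:k] - noise / np.maximum(s[:k], 1e-12), 0.0)
        recon = (U[:, :k] * shrunk) @ Vt[:k] + mu
        new_vals = recon[missing]
        delta = np.sqrt(np.mean((new_vals - X[missing]) ** 2))
        X[missing] = new_vals
        if delta < tol:
            break
    out = table.copy()
    out.iloc[:, :] = X
    return out


# ---------------------------------------------------------------------------
# factor model container
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """First-unrotated-component factor fitted on training data only.

    ``loadings`` are standardized loadings (unit eigenvector scaled by the
    square root of the first eigenvalue); scoring uses them as weights on
    z-scored variables, then z-normalizes by the training score mean/sd.
    """

    loadings: np.ndarray
    explained_variance: float
    train_means: np.ndarray
    train_sds: np.ndarray
    score_mean: float
    score_sd: float
    kind: str
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.train_means = np.asarray(self.train_means, dtype=float)
        self.train_sds = np.asarray(self.train_sds, dtype=float)
        if not 0 < self.explained_variance <= 1:
            raise ValueError("explained_variance must be in (0, 1]")
        if np.any(self.train_sds <= 0):
            raise ValueError("training sds must be positive")

    def to_json(self) -> str:
        return json.dumps({
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance,
            "train_means": self.train_means.tolist(),
            "train_sds": self.train_sds.tolist(),
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "kind": self.kind,
            "columns": list(self.columns),
        }, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "FactorModel":
        d = json.loads(s)
        return cls(loadings=np.array(d["loadings"]),
                   explained_variance=d["explained_variance"],
                   train_means=np.array(d["train_means"]),
                   train_sds=np.array(d["train_sds"]),
                   score_mean=d["score_mean"], score_sd=d["score_sd"],
                   kind=d["kind"], columns=d["columns"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "FactorModel":
        return cls.from_json(Path(path).read_text())


def _first_component(corr: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Unit first eigenvector, first eigenvalue, explained-variance fraction."""
    vals, vecs = np.linalg.eigh(corr)
    return vecs[:, -1], float(vals[-1]), float(vals[-1] / vals.sum())


def fit_gfactor(task_scores: pd.DataFrame) -> FactorModel:
    """Fit the cognitive g-factor on a 4-column training table.

    Any variance-stabilizing transforms (log for reaction time, log(x+1)
    for pairs matching) are the caller's responsibility. The sign is
    anchored so the first task (verbal-reasoning-like) loads positively.
    """
    if len(task_scores) < 50:
        raise ValueError("need at least 50 training subjects")
    # fixed memory layout so numerically identical inputs give bit-identical
    # models regardless of how the caller sliced the table
    X = np.ascontiguousarray(task_scores.to_numpy(dtype=float))
    if np.isnan(X).any():
        raise ValueError("task table must be complete (impute first)")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("constant task column")
    Z = (X - means) / sds
    cov = np.cov(Z, rowvar=False)
    vec, lam1, ev = _first_component(cov)
    if vec[0] < 0:
        vec = -vec
    loadings = vec * np.sqrt(lam1)
    raw = Z @ loadings
    return FactorModel(loadings=loadings, explained_variance=ev,
                       train_means=means, train_sds=sds,
                       score_mean=float(raw.mean()),
                       score_sd=float(raw.std(ddof=1)),
                       kind="g", columns=list(task_scores.columns))


def score_factor(model: FactorModel, table: pd.DataFrame) -> np.ndarray:
    """Score new subjects with a fitted factor model (training constants
    only; the result is z-scaled relative to the training set)."""
    if model.columns and list(table.columns) != list(model.columns):
        table = table[model.columns]
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values at scoring time: impute first")
    Z = (X - model.train_means) / model.train_sds
    raw = Z @ model.loadings
    return (raw - model.score_mean) / model.score_sd


# ---------------------------------------------------------------------------
# polychoric correlation
# ---------------------------------------------------------------------------

@dataclass
class PolychoricEstimate:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        if not -1 <= self.rho <= 1:
            raise ValueError("|rho| must be <= 1")


def _marginal_thresholds(codes: np.ndarray, levels: np.ndarray) -> np.ndarray:
    n = len(codes)
    counts = np.array([(codes == lv).sum() for lv in levels])
    cum = np.cumsum(counts)[:-1] / n
    return ndtri(cum)


def _bvn_rectangles(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a standard bivariate normal cut at the given
    thresholds, via differencing the CDF on the threshold grid."""
    gx = np.concatenate(([-np.inf], tx, [np.inf]))
    gy = np.concatenate(([-np.inf], ty, [np.inf]))
    big = 8.0  # effectively infinite for the standard normal
    gx = np.clip(gx, -big, big)
    gy = np.clip(gy, -big, big)
    pts = np.array([[x, y] for x in gx for y in gy])
    cdf = stats.multivariate_normal.cdf(
        pts, mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
    ).reshape(len(gx), len(gy))
    cells = (cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1])
    return np.clip(cells, 1e-12, None)


def polychoric(x, y) -> PolychoricEstimate:
    """Two-step polychoric correlation of two ordinal variables.

    Thresholds come from inverse-normal marginal cumulative frequencies;
    rho maximizes the bivariate-normal cell likelihood on [-0.999, 0.999].
    """
    x = np.asarray(pd.Series(x).to_numpy(), dtype=float)
    y = np.asarray(pd.Series(y).to_numpy(), dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 100:
        raise ValueError("need at least 100 complete observations")
    lx = np.unique(x)
    ly = np.unique(y)
    if len(lx) < 2 or len(ly) < 2:
        raise ValueError("each variable needs at least 2 observed levels")
    tx = _marginal_thresholds(x, lx)
    ty = _marginal_thresholds(y, ly)
    table = np.zeros((len(lx), len(ly)))
    for i, a in enumerate(lx):
        for j, b in enumerate(ly):
            table[i, j] = np.sum((x == a) & (y == b))
    if (table == 0).sum() > table.size // 2:
        warnings.warn("many empty contingency cells: polychoric likelihood "
                      "may be flat; estimate is approximate")

    def negll(rho: float) -> float:
        return -float(np.sum(table * np.log(_bvn_rectangles(tx, ty, rho))))

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999),
                                   method="bounded",
                                   options={"xatol": 1e-5})
    return PolychoricEstimate(rho=float(res.x), thresholds_x=tx,
                              thresholds_y=ty, loglik=-float(res.fun))


def polychoric_matrix(items: pd.DataFrame) -> np.ndarray:
    """Pairwise polychoric correlation matrix of an ordinal item table."""
    k = items.shape[1]
    R = np.eye(k)
    cols = list(items.columns)
    for i in range(k):
        for j in range(i + 1, k):
            R[i, j] = R[j, i] = polychoric(items[cols[i]], items[cols[j]]).rho
    return R


def nearest_psd(R: np.ndarray) -> np.ndarray:
    """Nearest positive-semidefinite repair by eigenvalue clipping, with
    unit diagonal restored."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= 0:
        return R
    repaired = (vecs * np.clip(vals, 1e-10, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    warnings.warn("polychoric matrix was not PSD; repaired "
                  f"(Frobenius distance {np.linalg.norm(R - repaired):.3g})")
    return repaired


def fit_mhqfactor(items: pd.DataFrame) -> FactorModel:
    """Fit the MHQ-factor on a complete (imputed) ordinal training table.

    PCA of the pairwise polychoric matrix; the sign is anchored so the
    largest-|loading| item loads positively. Per-subject scores are linear
    in z-scored numeric item codes (see module docstring).
    """
    X = np.ascontiguousarray(items.to_numpy(dtype=float))
    if np.isnan(X).any():
        raise ValueError("item table must be complete (impute first)")
    R = nearest_psd(polychoric_matrix(items))
    vec, lam1, ev = _first_component(R)
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    loadings = vec * np.sqrt(lam1)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("constant item column")
    raw = ((X - means) / sds) @ loadings
    return FactorModel(loadings=loadings, explained_variance=ev,
                       train_means=means, train_sds=sds,
                       score_mean=float(raw.mean()),
                       score_sd=float(raw.std(ddof=1)),
                       kind="mhq", columns=list(items.columns))
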