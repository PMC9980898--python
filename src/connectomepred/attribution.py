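"""Gradient attribution for trained networks and concordance analyses.

A gradient attribution (saliency) map is the matrix of partial derivatives
of a model output with respect to each input edge weight, averaged over a
subject set. Because the row and column weights of the edge-to-edge filters
are trained independently, the raw map of a symmetric input need not be
symmetric; each map is therefore summed with its transpose to yield one
estimate per region-to-region connection. Maps from repeated trainings and
cross-validation folds are averaged elementwise.

Node-level summaries: **predictive power** (signed sum of a node's edge
gradients — is the node's connectivity pushing predictions up or down) and
**importance** (sum of absolute gradients — is the node a hub of decision-
relevant connections). The kurtosis of the edge-gradient distribution
measures how concentrated the model's reliance is on a small edge subset;
it is reported in the Pearson (non-excess) convention where a normal
distribution scores 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dlmodel import BrainNetCNN
from .preprocess import vectorize_upper


@dataclass
class GradientMap:
    """A symmetrized, possibly run-averaged edge-attribution matrix."""

    grads: np.ndarray
    task: str = ""
    modality: str = ""
    n_models_averaged: int = 1
    per_fold_maps: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.grads = np.asarray(self.grads, dtype=float)
        if not np.allclose(self.grads, self.grads.T):
            raise ValueError("gradient map must be symmetric")
        if np.any(np.diag(self.grads) != 0):
            raise ValueError("gradient map must have zero diagonal")
        if self.n_models_averaged < 1:
            raise ValueError("n_models_averaged must be >= 1")


@dataclass
class NodeScores:
    predictive_power: np.ndarray
    importance: np.ndarray


def input_gradient(net: BrainNetCNN, X: np.ndarray,
                   cov: np.ndarray | None = None,
                   target: int | None = None) -> np.ndarray:
    """Raw (unsymmetrized) mean input gradient over a subject set.

    The target output is the positive-class logit for classification and
    the scalar output for regression.
    """
    if not net.trained:
        raise ValueError("network must be trained before attribution")
    return net.input_gradient(X, cov, target)


def symmetrize_gradient(G: np.ndarray, task: str = "", modality: str = "") -> GradientMap:
    """G + G.T with the diagonal zeroed — one estimate per connection."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("gradient must be square")
    out = G + G.T
    np.fill_diagonal(out, 0.0)
    return GradientMap(grads=out, task=task, modality=modality)


def average_maps(maps: list[GradientMap]) -> GradientMap:
    """Elementwise mean across trained-model gradient maps."""
    if not maps:
        raise ValueError("no maps to average")
    shapes = {m.grads.shape for m in maps}
    tasks = {m.task for m in maps}
    if len(shapes) > 1 or len(tasks) > 1:
        raise ValueError("maps must share shape and task")
    stack = np.stack([m.grads for m in maps])
    return GradientMap(grads=stack.mean(axis=0), task=maps[0].task,
                       modality=maps[0].modality,
                       n_models_averaged=len(maps),
                       per_fold_maps=[m.grads for m in maps])


def _as_matrix(m) -> np.ndarray:
    return m.grads if isinstance(m, GradientMap) else np.asarray(m, float)


def node_scores(gmap) -> NodeScores:
    """Signed and absolute per-node sums of edge gradients."""
    G = _as_matrix(gmap)
    return NodeScores(predictive_power=G.sum(axis=1),
                      importance=np.abs(G).sum(axis=1))


def gradient_kurtosis(gmap) -> float:
    """Pearson (non-excess) kurtosis of the upper-triangle edge gradients."""
    v = vectorize_upper(_as_matrix(gmap))
    if len(np.unique(v)) < 4:
        raise ValueError("need at least 4 distinct edge values")
    if np.std(v) < 1e-300:
        raise ValueError("zero variance gradient distribution")
    return float(stats.kurtosis(v, fisher=False, bias=True))


def map_concordance(map_a, map_b, method: str = "spearman") -> float:
    """Correlation between two edge maps over upper-triangle edges."""
    a = vectorize_upper(_as_matrix(map_a))
    b = vectorize_upper(_as_matrix(map_b))
    if a.shape != b.shape:
        raise ValueError("maps must have matching shapes")
    if np.std(a) < 1e-300 or np.std(b) < 1e-300:
        raise ValueError("constant map: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(a, b)[0])
    if method == "spearman":
        return float(stats.spearmanr(a, b)[0])
    raise ValueError("method must be pearson or spearman")


def top_region_overlap(scores_a: NodeScores, scores_b: NodeScores,
                       k: int = 10) -> float:
    """Fraction of shared nodes among the top-k by importance ranking."""
    top_a = set(np.argsort(scores_a.importance)[::-1][:k])
    top_b = set(np.argsort(scores_b.importance)[::-1][:k])
    return len(top_a & top_b) / k
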