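"""Connectome preprocessing: symmetrization, group proportional thresholding,
per-subject maximum-value normalization, and upper-triangle vectorization.

Pipeline order is fixed: symmetrize -> group proportional threshold (mask
computed from raw edge presence on the training portion only) -> per-subject
max-normalize. "Present" means a strictly positive weight; zeros encode
absent connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


def symmetrize(A: np.ndarray) -> np.ndarray:
    """(A + A.T) / 2 with the diagonal forced to zero.

    Accepts a single square matrix or a stack (..., n, n).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim < 2 or A.shape[-1] != A.shape[-2]:
        raise ValueError("input must be square")
    if np.any(A < 0):
        raise ValueError("edge weights must be non-negative")
    out = 0.5 * (A + np.swapaxes(A, -1, -2))
    idx = np.arange(A.shape[-1])
    out[..., idx, idx] = 0.0
    return out


@dataclass
class EdgeMask:
    """Boolean keep-mask from group proportional thresholding."""

    keep: np.ndarray
    fraction_threshold: float

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if not np.array_equal(self.keep, self.keep.T):
            raise ValueError("mask must be symmetric")
        np.fill_diagonal(self.keep, False)

    @property
    def density(self) -> float:
        """Fraction of off-diagonal edges kept."""
        n = self.keep.shape[0]
        return float(self.keep.sum() / (n * (n - 1)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.keep.astype(int), fmt="%d")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "fraction_threshold": self.fraction_threshold,
            "density": self.density,
        }))

    @classmethod
    def load(cls, path: str | Path) -> "EdgeMask":
        path = Path(path)
        keep = np.loadtxt(path).astype(bool)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(keep=keep, fraction_threshold=meta["fraction_threshold"])


def proportional_threshold(stack: np.ndarray, fraction: float = 2 / 3) -> EdgeMask:
    """Keep edges present (weight > 0) in at least ``fraction`` of subjects.

    The comparison is inclusive: count/N >= fraction keeps the edge.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("need a non-empty (n_subjects, n, n) stack")
    presence = (stack > 0).mean(axis=0)
    keep = presence >= fraction
    keep = keep & keep.T  # symmetrized inputs make this a no-op
    np.fill_diagonal(keep, False)
    return EdgeMask(keep=keep, fraction_threshold=fraction)


def apply_mask(stack: np.ndarray, mask: EdgeMask) -> np.ndarray:
    """Zero excluded edges in every subject."""
    stack = np.asarray(stack, dtype=float)
    return stack * mask.keep[None, :, :]


def max_normalize(A: np.ndarray) -> np.ndarray:
    """Divide every entry by the matrix's own maximum (per subject for a
    stack), so the largest edge weight becomes exactly 1."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        m = A.max()
        if m <= 0:
            raise ValueError("all-zero matrix: degenerate subject")
        return A / m
    m = A.max(axis=(-1, -2), keepdims=True)
    if np.any(m <= 0):
        raise ValueError("all-zero matrix in stack: degenerate subject")
    return A / m


def vectorize_upper(A: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Strictly-upper-triangle entries in row-major order.

    This ordering is the canonical feature order for every linear model,
    beta map, and gradient comparison in the package.
    """
    A = np.asarray(A, dtype=float)
    if np.abs(A - np.swapaxes(A, -1, -2)).max() > tol:
        raise ValueError("matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(A.shape[-1], k=1)
    return A[..., iu[0], iu[1]]


def matrix_from_upper(v: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (symmetric, zero diagonal)."""
    v = np.asarray(v, dtype=float)
    if n_nodes is None:
        n_nodes = int(round((1 + np.sqrt(1 + 8 * v.shape[-1])) / 2))
    iu = np.triu_indices(n_nodes, k=1)
    if len(iu[0]) != v.shape[-1]:
        raise ValueError("vector length is not n(n-1)/2")
    A = np.zeros(v.shape[:-1] + (n_nodes, n_nodes))
    A[..., iu[0], iu[1]] = v
    return A + np.swapaxes(A, -1, -2)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2
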