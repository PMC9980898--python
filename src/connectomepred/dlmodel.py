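"""A connectome-specific convolutional network (BrainNetCNN), in NumPy.

The network operates directly on weighted adjacency matrices through three
topology-aware layers:

* **E2E** (edge-to-edge): a cross-shaped filter whose (i, j) output is the
  weighted sum of row i plus the weighted sum of column j,

  ``out[n, i, j] = sum_f ( A[f, i, :] . w_r[f, n] + A[f, :, j] . w_c[f, n] )``

  with independently learnt row and column weight vectors per filter;
* **E2N** (edge-to-node): the row-filter half only, collapsing each node's
  edges to a node feature, ``out[n, i] = sum_f A[f, i, :] . w_r[f, n]``;
* **N2G** (node-to-graph): a dense layer collapsing node features to a
  graph-level representation.

The full architecture is E2E -> leaky ReLU -> E2N -> leaky ReLU -> dropout
-> N2G -> leaky ReLU -> [concatenate covariates] -> dense head (2 logits
for classification, 1 unit for regression). Training uses Adam with
(by default) learning rate 1e-3, gradient decay 0.9, squared-gradient
decay 0.9, mini-batches of 128 and 200 epochs; the weights of the epoch
with the best validation metric are kept.

Forward, backward (including gradients with respect to the *input* matrix,
needed for gradient attribution) and the optimizer are written out
explicitly so every quantity the attribution stage consumes is available
in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizes and options for one network instance."""

    n_nodes: int
    e2e_filters: int = 8
    e2n_filters: int = 16
    n2g_units: int = 30
    leaky_slope: float = 0.33
    dropout_rate: float = 0.5
    with_covariates: bool = False
    n_covariates: int = 0
    task: str = "classification"

    def __post_init__(self) -> None:
        if min(self.n_nodes, self.e2e_filters, self.e2n_filters, self.n2g_units) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be classification or regression")
        if self.with_covariates and self.n_covariates < 1:
            raise ValueError("covariates enabled but n_covariates is 0")

    @property
    def n_outputs(self) -> int:
        return 2 if self.task == "classification" else 1


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule settings (Adam)."""

    learning_rate: float = 1e-3
    grad_decay: float = 0.9
    sq_grad_decay: float = 0.9
    batch_size: int = 128
    epochs: int = 200
    validation_frequency: int = 50
    loss: str = "cross-entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.grad_decay, self.sq_grad_decay,
               self.batch_size, self.epochs, self.validation_frequency) <= 0:
            raise ValueError("all training settings must be positive")
        if self.loss not in ("cross-entropy", "mean-squared-error"):
            raise ValueError("unknown loss")


# ---------------------------------------------------------------------------
# layer primitives (pure functions, used by the network and by oracles/tests)
# ---------------------------------------------------------------------------

def e2e_forward(A: np.ndarray, row_weights: np.ndarray,
                col_weights: np.ndarray) -> np.ndarray:
    """Edge-to-edge cross filter.

    ``A``: (batch, f_in, n, n); ``row_weights``/``col_weights``:
    (f_in, f_out, n). Returns (batch, f_out, n, n).
    """
    A = np.asarray(A, dtype=float)
    if A.shape[-1] != A.shape[-2] or row_weights.shape[-1] != A.shape[-1]:
        raise ValueError("weight vectors must have length n_nodes")
    if row_weights.shape[0] != A.shape[1] or col_weights.shape != row_weights.shape:
        raise ValueError("filter count mismatch")
    row = np.einsum("bfiq,fmq->bmi", A, row_weights)
    col = np.einsum("bfqj,fmq->bmj", A, col_weights)
    return row[:, :, :, None] + col[:, :, None, :]


def e2n_forward(A: np.ndarray, row_weights: np.ndarray) -> np.ndarray:
    """Edge-to-node row filter: (batch, f_in, n, n) -> (batch, f_out, n)."""
    A = np.asarray(A, dtype=float)
    if A.shape[-1] != A.shape[-2] or row_weights.shape[-1] != A.shape[-1]:
        raise ValueError("weight vectors must have length n_nodes")
    if row_weights.shape[0] != A.shape[1]:
        raise ValueError("filter count mismatch")
    return np.einsum("bfiq,fmq->bmi", A, row_weights)


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class BrainNetCNN:
    """One trainable network instance. Parameters live in ``self.params``;
    ``forward``/``backward`` cache activations on the instance."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        n, f1, f2, h = spec.n_nodes, spec.e2e_filters, spec.e2n_filters, spec.n2g_units
        head_in = h + (spec.n_covariates if spec.with_covariates else 0)

        def init(*shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "e2e_wr": init(1, f1, n, fan_in=2 * n),
            "e2e_wc": init(1, f1, n, fan_in=2 * n),
            "e2e_b": np.zeros(f1),
            "e2n_wr": init(f1, f2, n, fan_in=f1 * n),
            "e2n_b": np.zeros(f2),
            "n2g_w": init(f2 * n, h, fan_in=f2 * n),
            "n2g_b": np.zeros(h),
            "head_w": init(head_in, spec.n_outputs, fan_in=head_in),
            "head_b": np.zeros(spec.n_outputs),
        }
        self.best_epoch: int | None = None
        self.history: dict[str, list[float]] = {}
        self.trained = False
        self._cache: dict = {}

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, cov: np.ndarray | None = None, *,
                train: bool = False,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """X: (batch, n, n) adjacency matrices; cov: (batch, n_covariates)
        z-scored covariates when the spec enables them. Returns logits
        (batch, 2) or values (batch, 1)."""
        spec, p, c = self.spec, self.params, self._cache
        if spec.with_covariates:
            if cov is None:
                raise ValueError("spec requires covariates")
            cov = np.asarray(cov, dtype=float)
        X = np.asarray(X, dtype=float)
        A0 = X[:, None, :, :]
        c["A0"] = A0
        z1 = e2e_forward(A0, p["e2e_wr"], p["e2e_wc"]) + p["e2e_b"][None, :, None, None]
        c["z1"] = z1
        a1 = _leaky(z1, spec.leaky_slope)
        c["a1"] = a1
        z2 = e2n_forward(a1, p["e2n_wr"]) + p["e2n_b"][None, :, None]
        c["z2"] = z2
        a2 = _leaky(z2, spec.leaky_slope)
        if train and spec.dropout_rate > 0:
            if dropout_rng is None:
                raise ValueError("training forward pass needs a dropout rng")
            mask = (dropout_rng.random(a2.shape) >= spec.dropout_rate)
            a2 = a2 * mask / (1.0 - spec.dropout_rate)
            c["drop_mask"] = mask
        else:
            c["drop_mask"] = None
        c["a2"] = a2
        flat = a2.reshape(a2.shape[0], -1)
        c["flat"] = flat
        z3 = flat @ p["n2g_w"] + p["n2g_b"]
        c["z3"] = z3
        a3 = _leaky(z3, spec.leaky_slope)
        if spec.with_covariates:
            a3 = np.concatenate([a3, cov], axis=1)
        c["a3"] = a3
        return a3 @ p["head_w"] + p["head_b"]

    # -- backward ---------------------------------------------------------

    def backward(self, dout: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backpropagate an output-gradient (batch, n_outputs). Returns
        (parameter gradients, gradient w.r.t. the input matrices)."""
        spec, p, c = self.spec, self.params, self._cache
        grads: dict[str, np.ndarray] = {}
        grads["head_w"] = c["a3"].T @ dout
        grads["head_b"] = dout.sum(axis=0)
        da3 = dout @ p["head_w"].T
        h = spec.n2g_units
        da3 = da3[:, :h]  # covariate columns carry no upstream parameters
        dz3 = da3 * _leaky_grad(c["z3"], spec.leaky_slope)
        grads["n2g_w"] = c["flat"].T @ dz3
        grads["n2g_b"] = dz3.sum(axis=0)
        dflat = dz3 @ p["n2g_w"].T
        da2 = dflat.reshape(c["a2"].shape)
        if c["drop_mask"] is not None:
            da2 = da2 * c["drop_mask"] / (1.0 - spec.dropout_rate)
        dz2 = da2 * _leaky_grad(c["z2"], spec.leaky_slope)
        grads["e2n_b"] = dz2.sum(axis=(0, 2))
        grads["e2n_wr"] = np.einsum("bmi,bfiq->fmq", dz2, c["a1"])
        da1 = np.einsum("bmi,fmq->bfiq", dz2, p["e2n_wr"])
        dz1 = da1 * _leaky_grad(c["z1"], spec.leaky_slope)
        grads["e2e_b"] = dz1.sum(axis=(0, 2, 3))
        grow = dz1.sum(axis=3)  # (b, m, i)
        gcol = dz1.sum(axis=2)  # (b, m, j)
        grads["e2e_wr"] = np.einsum("bmi,bfiq->fmq", grow, c["A0"])
        grads["e2e_wc"] = np.einsum("bmj,bfqj->fmq", gcol, c["A0"])
        dA0 = (np.einsum("bmi,fmq->bfiq", grow, p["e2e_wr"])
               + np.einsum("bmj,fmp->bfpj", gcol, p["e2e_wc"]))
        return grads, dA0[:, 0]

    # -- inference --------------------------------------------------------

    def predict(self, X: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
        """Class-"female" probability (classification) or continuous value
        (regression), per subject. Deterministic: dropout is off."""
        out = self.forward(X, cov, train=False)
        if self.spec.task == "classification":
            return softmax(out)[:, 1]
        return out[:, 0]

    def predict_proba(self, X: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
        if self.spec.task != "classification":
            raise ValueError("probabilities are defined for classification only")
        return softmax(self.forward(X, cov, train=False))

    def input_gradient(self, X: np.ndarray, cov: np.ndarray | None = None,
                       target: int | None = None) -> np.ndarray:
        """Mean over subjects of d(target output)/d(input edge weights).

        ``target`` defaults to the positive-class ("female") logit for
        classification and the single output for regression. Dropout is
        disabled; the gradient is of the raw (pre-softmax) output.
        """
        self.forward(X, cov, train=False)
        if target is None:
            target = 1 if self.spec.task == "classification" else 0
        dout = np.zeros((X.shape[0], self.spec.n_outputs))
        dout[:, target] = 1.0 / X.shape[0]
        _, dX = self.backward(dout)
        if not np.all(np.isfinite(dX)):
            raise FloatingPointError("non-finite input gradient")
        return dX.sum(axis=0)

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(spec: ArchitectureSpec, seed: int = 0) -> BrainNetCNN:
    """Construct an untrained network with seeded initialization."""
    return BrainNetCNN(spec, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_and_grad(net: BrainNetCNN, out: np.ndarray, y: np.ndarray,
                   loss: str) -> tuple[float, np.ndarray]:
    B = out.shape[0]
    if loss == "cross-entropy":
        probs = softmax(out)
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y.astype(int)] = 1.0
        ll = -np.log(np.clip(probs[np.arange(B), y.astype(int)], 1e-12, None))
        return float(ll.mean()), (probs - onehot) / B
    resid = out[:, 0] - y
    return float(np.mean(resid ** 2)), (2.0 * resid / B)[:, None]


def _val_metric(net: BrainNetCNN, X, y, cov, task: str) -> float:
    pred = net.predict(X, cov)
    if task == "classification":
        return float(np.mean((pred > 0.5) == (y > 0.5)))
    if np.std(pred) < 1e-12 or np.std(y) < 1e-12:
        return -1.0
    return float(stats.pearsonr(pred, y)[0])


def train_network(net: BrainNetCNN, train_set, val_set,
                  config: TrainingConfig) -> BrainNetCNN:
    """Train with Adam; keep the weights of the best validation epoch.

    ``train_set``/``val_set`` are ``(X, y)`` or ``(X, y, cov)`` tuples with
    disjoint subjects. The validation metric is accuracy (classification)
    or Pearson correlation (regression), evaluated once per epoch; ties
    keep the earlier epoch. Deterministic given ``config.seed``.
    """
    Xtr, ytr, ctr = (list(train_set) + [None])[:3]
    Xva, yva, cva = (list(val_set) + [None])[:3]
    task = net.spec.task
    expected = "cross-entropy" if task == "classification" else "mean-squared-error"
    if config.loss != expected:
        raise ValueError(f"loss {config.loss!r} does not match task {task!r}")
    rng = np.random.default_rng(config.seed)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in net.params.items()}
    b1, b2, eps = config.grad_decay, config.sq_grad_decay, 1e-8
    step = 0
    best_metric, best_weights, best_epoch = -np.inf, net.copy_weights(), 0
    hist_loss, hist_val = [], []
    n = Xtr.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            cov_b = ctr[idx] if ctr is not None else None
            out = net.forward(Xtr[idx], cov_b, train=True, dropout_rng=rng)
            loss, dout = _loss_and_grad(net, out, ytr[idx], config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}: exploding weights")
            epoch_loss += loss * len(idx)
            grads, _ = net.backward(dout)
            step += 1
            for k in net.params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                net.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        hist_loss.append(epoch_loss / n)
        metric = _val_metric(net, Xva, yva, cva, task)
        hist_val.append(metric)
        if metric > best_metric:
            best_metric, best_weights, best_epoch = metric, net.copy_weights(), epoch
    net.params = best_weights
    net.best_epoch = best_epoch
    net.history = {"train_loss": hist_loss, "val_metric": hist_val}
    net.trained = True
    return net
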