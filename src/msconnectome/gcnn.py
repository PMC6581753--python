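"""Graph-convolutional classifier for whole-connectome classification.

The network is one graph-convolution layer ``H = ReLU(A_hat X W)`` with
``k = 100`` output channels, dropout (rate 0.3), a flatten step, and one
fully connected softmax layer over the classes.  ``A_hat`` is the Kipf–Welling
renormalized adjacency ``D~^{-1/2} (A + I) D~^{-1/2}``.  For weighted graphs
the adjacency is scaled by its maximum weight before renormalization so raw
fiber counts do not swamp the unit self-loop.

Training minimizes categorical cross-entropy with Adam (default learning rate
0.001) and early stopping on a held-out validation split.  The implementation
is pure numpy with hand-derived gradients; a finite-difference check in the
test suite guards their correctness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import BrainGraph

__all__ = [
    "GCNClassifier",
    "TrainConfig",
    "TrainResult",
    "renormalize_adjacency",
    "renormalized_from_graph",
    "gc_layer_forward",
    "build_model",
    "count_parameters",
    "prepare_inputs",
    "train",
    "predict",
]


def renormalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Kipf–Welling renormalization: ``D~^{-1/2} (A + I) D~^{-1/2}``."""
    a = np.asarray(adjacency, dtype=float)
    if (a < 0).any():
        raise ValueError("adjacency must be non-negative")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def renormalized_from_graph(graph: BrainGraph) -> np.ndarray:
    """Renormalized adjacency of a brain graph.

    Weighted adjacencies are divided by their maximum weight first; with
    all-equal weights this coincides with the binary pipeline.
    """
    a = graph.adjacency
    if graph.weighted:
        amax = a.max(initial=0.0)
        if amax > 0:
            a = a / amax
    else:
        a = (a > 0).astype(float)
    return renormalize_adjacency(a)


def gc_layer_forward(a_hat: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Graph-convolution layer ``ReLU(A_hat X W)``."""
    if a_hat.shape[1] != x.shape[0] or x.shape[1] != w.shape[0]:
        raise ValueError(
            f"shape mismatch: A_hat {a_hat.shape}, X {x.shape}, W {w.shape}"
        )
    return np.maximum(a_hat @ x @ w, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class TrainConfig:
    """Hyperparameters of the Adam training loop."""

    learning_rate: float = 0.001
    max_epochs: int = 500
    patience: int = 20
    batch_size: int | None = None          # None = full batch
    validation_fraction: float = 0.1       # stratified early-stopping holdout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainResult:
    """Training history and early-stopping diagnostics returned by ``fit``."""

    model: "GCNClassifier"
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    n_epochs: int = 0

    def summary(self) -> str:
        lines = [
            "GCN training result",
            f"  epochs run          : {self.n_epochs}",
            f"  best epoch          : {self.best_epoch}",
            f"  final train loss    : {self.train_loss[-1]:.4f}" if self.train_loss else "",
            f"  best monitored loss : {min(self.val_loss):.4f}" if self.val_loss else "",
            f"  trainable parameters: {count_parameters(self.model)}",
        ]
        return "\n".join(line for line in lines if line)


class GCNClassifier:
    """One GC layer (k channels, no bias) -> ReLU -> dropout -> dense softmax.

    Parameters
    ----------
    q, d : int
        Number of graph nodes and node-feature dimension.
    k : int
        GC output channels (100 in the reference architecture).
    n_classes : int
        Output classes.
    dropout_rate : float
        Dropout on the GC activations during training (0.3 by default).
    seed : int
        Seed for Glorot-uniform weight initialization.
    """

    def __init__(self, q: int, d: int, k: int = 100, n_classes: int = 2,
                 dropout_rate: float = 0.3, seed: int = 0):
        if min(q, d, k, n_classes) < 1:
            raise ValueError("q, d, k and n_classes must all be >= 1")
        self.q, self.d, self.k, self.n_classes = q, d, k, n_classes
        self.dropout_rate = dropout_rate
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.w_gc = self._glorot(rng, d, k)
        self.w_dense = self._glorot(rng, q * k, n_classes)
        self.b_dense = np.zeros(n_classes)

    @staticmethod
    def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    # ------------------------------------------------------------------ #
    # forward / backward

    def _forward(self, m: np.ndarray, dropout_mask: np.ndarray | None = None):
        """Forward pass from precomputed ``M = A_hat X`` (batched, N x q x d)."""
        s = m @ self.w_gc                       # N x q x k pre-activation
        h = np.maximum(s, 0.0)
        if dropout_mask is not None:
            h = h * dropout_mask
        flat = h.reshape(h.shape[0], -1)
        probs = _softmax(flat @ self.w_dense + self.b_dense)
        return s, h, flat, probs

    def _loss_and_grads(self, m: np.ndarray, y_onehot: np.ndarray,
                        dropout_mask: np.ndarray | None = None):
        """Mean cross-entropy and gradients w.r.t. all trainable arrays."""
        n = m.shape[0]
        s, _, flat, probs = self._forward(m, dropout_mask)
        loss = -np.mean(np.log(np.clip((probs * y_onehot).sum(axis=1), 1e-300, None)))
        d_logits = (probs - y_onehot) / n
        g_b = d_logits.sum(axis=0)
        g_dense = flat.T @ d_logits
        d_h = (d_logits @ self.w_dense.T).reshape(n, self.q, self.k)
        if dropout_mask is not None:
            d_h = d_h * dropout_mask
        d_s = d_h * (s > 0)
        g_gc = np.einsum("nqd,nqk->dk", m, d_s)
        return loss, (g_gc, g_dense, g_b)

    def loss(self, m: np.ndarray, y: np.ndarray) -> float:
        y_onehot = np.eye(self.n_classes)[np.asarray(y)]
        _, _, _, probs = self._forward(np.asarray(m))
        return float(-np.mean(np.log(np.clip((probs * y_onehot).sum(axis=1), 1e-300, None))))

    def predict_proba(self, m: np.ndarray) -> np.ndarray:
        """Class probabilities for precomputed inputs (dropout disabled)."""
        m = np.asarray(m)
        single = m.ndim == 2
        if single:
            m = m[None]
        probs = self._forward(m)[3]
        return probs[0] if single else probs

    def predict(self, m: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(m)
        return np.argmax(probs, axis=-1)

    # ------------------------------------------------------------------ #
    # training

    def _params(self):
        return [self.w_gc, self.w_dense, self.b_dense]

    def _set_params(self, params):
        self.w_gc, self.w_dense, self.b_dense = [p.copy() for p in params]

    def fit(self, m: np.ndarray, y: np.ndarray,
            config: TrainConfig | None = None) -> TrainResult:
        """Train with Adam, cross-entropy loss and early stopping.

        Parameters
        ----------
        m : ndarray of shape (N, q, d)
            Precomputed ``A_hat @ X`` per sample (see :func:`prepare_inputs`).
        y : ndarray of shape (N,)
            Integer class labels in ``[0, n_classes)``.
        """
        config = config or TrainConfig()
        m = np.asarray(m, dtype=float)
        y = np.asarray(y, dtype=int)
        if m.shape[0] == 0:
            raise ValueError("empty training set")
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError("labels must lie in [0, n_classes)")
        if np.unique(y).size < 2:
            warnings.warn("training set contains a single class", stacklevel=2)

        rng = np.random.default_rng(config.seed)
        train_idx, val_idx = _stratified_holdout(y, config.validation_fraction, rng)
        m_tr, y_tr = m[train_idx], y[train_idx]
        m_val, y_val = m[val_idx], y[val_idx]
        y_tr_onehot = np.eye(self.n_classes)[y_tr]

        adam_state = [(np.zeros_like(p), np.zeros_like(p)) for p in self._params()]
        step = 0
        best_loss = np.inf
        best_params = [p.copy() for p in self._params()]
        best_epoch = 0
        result = TrainResult(model=self)
        n_tr = m_tr.shape[0]
        batch = config.batch_size or n_tr

        for epoch in range(config.max_epochs):
            order = rng.permutation(n_tr) if batch < n_tr else np.arange(n_tr)
            epoch_loss = 0.0
            for start in range(0, n_tr, batch):
                idx = order[start:start + batch]
                mask = None
                if self.dropout_rate > 0:
                    keep = 1.0 - self.dropout_rate
                    mask = (rng.random((idx.size, self.q, self.k)) < keep) / keep
                loss, grads = self._loss_and_grads(m_tr[idx], y_tr_onehot[idx], mask)
                epoch_loss += loss * idx.size
                step += 1
                for p, g, (m1, m2) in zip(self._params(), grads, adam_state):
                    m1 *= 0.9
                    m1 += 0.1 * g
                    m2 *= 0.999
                    m2 += 0.001 * g * g
                    m1_hat = m1 / (1 - 0.9 ** step)
                    m2_hat = m2 / (1 - 0.999 ** step)
                    p -= config.learning_rate * m1_hat / (np.sqrt(m2_hat) + 1e-8)
            result.train_loss.append(epoch_loss / n_tr)
            monitored = self.loss(m_val, y_val) if val_idx.size else result.train_loss[-1]
            result.val_loss.append(monitored)
            if monitored < best_loss - 1e-12:
                best_loss = monitored
                best_params = [p.copy() for p in self._params()]
                best_epoch = epoch
            elif epoch - best_epoch >= config.patience:
                break
        self._set_params(best_params)
        result.best_epoch = best_epoch
        result.n_epochs = len(result.train_loss)
        return result


def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class validation holdout; empty when fraction == 0 or data too small."""
    n = y.size
    if fraction <= 0 or n < 2:
        return np.arange(n), np.arange(0)
    val: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        n_val = int(round(members.size * fraction))
        if members.size >= 2 and n_val == 0:
            n_val = 1
        val.extend(rng.permutation(members)[:n_val])
    val_idx = np.sort(np.array(val, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    if train_idx.size == 0:  # degenerate: keep everything for training
        return np.arange(n), np.arange(0)
    return train_idx, val_idx


# ---------------------------------------------------------------------- #
# functional surface


def build_model(q: int, d: int, k: int, n_classes: int, seed: int = 0) -> GCNClassifier:
    """Construct the classifier with seeded Glorot-uniform initialization."""
    return GCNClassifier(q=q, d=d, k=k, n_classes=n_classes, seed=seed)


def count_parameters(model: GCNClassifier) -> int:
    """Exact count of trainable scalars: ``d*k + q*k*C + C``."""
    return model.w_gc.size + model.w_dense.size + model.b_dense.size


def prepare_inputs(a_hat: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Precompute ``A_hat @ X``, the fixed per-sample input of the GC layer."""
    return np.asarray(a_hat) @ np.asarray(x)


def train(model: GCNClassifier, dataset, config: TrainConfig | None = None) -> TrainResult:
    """Train on a list of ``(a_hat, x, label)`` triples."""
    if not dataset:
        raise ValueError("empty training set")
    m = np.stack([prepare_inputs(a_hat, x) for a_hat, x, _ in dataset])
    y = np.array([label for _, _, label in dataset])
    return model.fit(m, y, config)


def predict(model: GCNClassifier, a_hat: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Class-probability vector for one graph (sums to 1)."""
    return model.predict_proba(prepare_inputs(a_hat, x))
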