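"""Dense feed-forward classifier with softmax/sigmoid head, trained by
mini-batch RMSprop on cross-entropy loss.

This is the shared trainer behind both annotation modes: the flat multi-class
classifier uses a softmax output over the K cell types with categorical
cross-entropy; each bifurcation of the hierarchical tree reuses the same
stack with a single sigmoid output unit and binary cross-entropy.

Architecture: ReLU hidden layers of widths fixed by the model size
(small: 64; medium: 64, 128; big: 64, 128, 256), then a linear output layer
whose activations are mapped to probabilities by the head. Weights are
Glorot-uniform initialized from a seeded generator, so identical seeds yield
bitwise-identical models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import DataError, ExpressionMatrix, LabelVector
from .preprocess import align_to_gene_order

logger = logging.getLogger(__name__)

EPS = 1e-12

_HIDDEN_WIDTHS = {
    "small": (64,),
    "medium": (64, 128),
    "big": (64, 128, 256),
}


def softmax(eta: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized by max subtraction."""
    eta = np.asarray(eta, dtype=np.float64)
    z = eta - eta.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def categorical_cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Mean over cells of -log(probability at the true class).

    Probabilities are clamped at 1e-12 so a confidently wrong prediction
    yields a large finite loss rather than -inf.
    """
    p = np.clip(np.asarray(probs, dtype=np.float64), EPS, 1.0)
    onehot = np.asarray(onehot, dtype=np.float64)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def binary_cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean Bernoulli cross-entropy; equals the categorical form on the
    equivalent two-class one-hot encoding."""
    p = np.clip(np.asarray(probs, dtype=np.float64), EPS, 1.0 - EPS)
    t = np.asarray(targets, dtype=np.float64)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


@dataclass
class NetworkSpec:
    """Model-size preset: hidden layer widths and the activation (ReLU)."""

    size_name: str
    hidden_widths: tuple[int, ...]

    @classmethod
    def from_name(cls, name: str) -> "NetworkSpec":
        if name not in _HIDDEN_WIDTHS:
            raise ValueError(
                f"unknown model size {name!r}; choose from {sorted(_HIDDEN_WIDTHS)}"
            )
        return cls(size_name=name, hidden_widths=_HIDDEN_WIDTHS[name])


@dataclass
class TrainConfig:
    """Optimization hyperparameters (RMSprop, mini-batch)."""

    batch_size: int = 128
    epochs: int = 30
    learning_rate: float = 1e-3
    rms_decay: float = 0.9
    rms_eps: float = 1e-7
    rng_seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class DenseClassifier:
    """A (possibly trained) dense network.

    ``weights[l]`` maps layer l's input to its pre-activation; the final
    entry is the output layer. ``class_order`` lists the labels matching the
    softmax units (or, for a binary head, the left/right semantics are owned
    by the caller). ``gene_order`` records the feature ids seen at training.
    """

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    gene_order: list[str] | None = None
    class_order: list[str] | None = None
    loss_trace: list[float] = field(default_factory=list)
    val_loss_trace: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[1]

    @property
    def is_binary(self) -> bool:
        return self.n_outputs == 1

    # -- forward ---------------------------------------------------------

    def _forward(self, Xa: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Return (hidden activations per layer, output logits)."""
        acts = [Xa]
        a = Xa
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        return acts, logits

    def predict_proba_array(self, Xa: np.ndarray) -> np.ndarray:
        """Probabilities for a samples x features array."""
        _, logits = self._forward(np.asarray(Xa, dtype=np.float64))
        if self.is_binary:
            return sigmoid(logits)
        return softmax(logits)


def build_network(
    spec: NetworkSpec, n_features: int, n_classes: int, seed: int
) -> DenseClassifier:
    """Construct an untrained network with Glorot-uniform seeded weights.

    ``n_classes >= 2`` gives a softmax head; ``n_classes == 1`` a sigmoid
    head for binary left/right nodes.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_classes != 1 and n_classes < 2:
        raise ValueError("n_classes must be 1 (binary head) or >= 2")
    rng = np.random.default_rng(seed)
    dims = [n_features, *spec.hidden_widths, n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return DenseClassifier(spec=spec, weights=weights, biases=biases)


def _loss_and_grads(
    clf: DenseClassifier, Xa: np.ndarray, T: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Cross-entropy loss and its gradients for a batch.

    For both heads the gradient of the mean loss w.r.t. the logits is
    (p - t) / batch; backpropagation through the ReLU stack is standard.
    """
    acts, logits = clf._forward(Xa)
    n = Xa.shape[0]
    if clf.is_binary:
        p = sigmoid(logits)
        loss = binary_cross_entropy(p[:, 0], T[:, 0])
    else:
        p = softmax(logits)
        loss = categorical_cross_entropy(p, T)
    delta = (p - T) / n
    gW = [np.empty(0)] * len(clf.weights)
    gb = [np.empty(0)] * len(clf.biases)
    for l in range(len(clf.weights) - 1, -1, -1):
        gW[l] = acts[l].T @ delta
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ clf.weights[l].T) * (acts[l] > 0)
    return loss, gW, gb


def _fit_array(
    clf: DenseClassifier, Xa: np.ndarray, T: np.ndarray, cfg: TrainConfig
) -> DenseClassifier:
    """Mini-batch RMSprop training on a samples x features array, in place."""
    Xa = np.asarray(Xa, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if T.ndim == 1:
        T = T[:, None]
    n = Xa.shape[0]
    rng = np.random.default_rng(cfg.rng_seed)

    n_val = int(round(cfg.validation_fraction * n))
    if n_val > 0:
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xval, Tval = Xa[val_idx], T[val_idx]
        Xa, T = Xa[tr_idx], T[tr_idx]
        n = Xa.shape[0]

    cacheW = [np.zeros_like(W) for W in clf.weights]
    cacheb = [np.zeros_like(b) for b in clf.biases]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, gW, gb = _loss_and_grads(clf, Xa[idx], T[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; "
                    "try a smaller learning rate"
                )
            for l in range(len(clf.weights)):
                cacheW[l] = cfg.rms_decay * cacheW[l] + (1 - cfg.rms_decay) * gW[l] ** 2
                cacheb[l] = cfg.rms_decay * cacheb[l] + (1 - cfg.rms_decay) * gb[l] ** 2
                clf.weights[l] -= cfg.learning_rate * gW[l] / (np.sqrt(cacheW[l]) + cfg.rms_eps)
                clf.biases[l] -= cfg.learning_rate * gb[l] / (np.sqrt(cacheb[l]) + cfg.rms_eps)
        epoch_loss, _, _ = _loss_and_grads(clf, Xa, T)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite loss after epoch {_epoch}")
        clf.loss_trace.append(epoch_loss)
        if n_val > 0:
            vloss, _, _ = _loss_and_grads(clf, Xval, Tval)
            clf.val_loss_trace.append(vloss)
    return clf


def train(
    clf: DenseClassifier, X: ExpressionMatrix, y: LabelVector, cfg: TrainConfig
) -> DenseClassifier:
    """Train a multi-class classifier on a genes x cells matrix.

    Cells become samples (the matrix is transposed internally); the class
    order is the sorted label set, matching the softmax units.
    """
    if y.n_cells != X.n_cells:
        raise DataError("label vector does not match the matrix cell count")
    if clf.is_binary:
        raise DataError("use the hierarchical trainer for binary node networks")
    if clf.n_outputs != y.n_types:
        raise DataError(
            f"network has {clf.n_outputs} output units for {y.n_types} cell types"
        )
    class_index = {k: j for j, k in enumerate(y.label_set)}
    T = np.zeros((X.n_cells, y.n_types))
    for i, lab in enumerate(y.labels):
        T[i, class_index[lab]] = 1.0
    _fit_array(clf, X.values.T, T, cfg)
    clf.gene_order = list(X.gene_ids)
    clf.class_order = list(y.label_set)
    return clf


def predict(clf: DenseClassifier, X1: ExpressionMatrix) -> tuple[LabelVector, np.ndarray]:
    """Assign every test cell the argmax class; ties go to the lowest class index.

    Test genes are matched by id to the training gene order; genes seen in
    training but absent here are zero-imputed (with a logged warning).
    """
    if clf.gene_order is None or clf.class_order is None:
        raise DataError("classifier has not been trained")
    vals, _missing = align_to_gene_order(X1, clf.gene_order)
    probs = clf.predict_proba_array(vals.T)
    best = probs.argmax(axis=1)  # np.argmax returns the first (lowest) index on ties
    labels = [clf.class_order[j] for j in best]
    return LabelVector(labels, label_set=list(clf.class_order)), probs
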