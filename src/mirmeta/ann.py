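"""Shallow fully-connected network with tanh units and a two-node
exponential-normalized output.

The architecture is fixed by design: two hidden layers of 10 and 20
nodes, two output nodes, hyperbolic-tangent activation on every node
*including* the output layer, whose (tanh-bounded) values are then
exponential-normalized::

    O_i^T = exp(O_i) / sum_j exp(O_j)

so predictions are a two-component probability vector.  Positive
samples carry the target [1, 0], negatives [0, 1].  Training minimizes
(optionally class-weighted) cross-entropy by plain gradient descent;
everything — forward pass, backprop, early stopping — is implemented in
numpy so the model stays a transparent bag of small matrices that
serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "AnnConfig",
    "AnnModel",
    "init_model",
    "forward",
    "loss_and_grads",
    "train",
    "predict",
    "TanhSoftmaxANN",
]


@dataclass
class AnnConfig:
    input_dim: int
    hidden: tuple[int, int] = (10, 20)
    output_dim: int = 2
    learning_rate: float = 0.01
    epochs: int = 2000
    batch_size: int | None = None  # None = full batch
    class_weighting: str = "inverse_frequency"  # or "none"
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError(f"input_dim must be >= 1, got {self.input_dim}")
        if self.output_dim != 2:
            raise ValueError("the output layer has exactly two nodes")
        if self.class_weighting not in ("none", "inverse_frequency"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass
class AnnModel:
    config: AnnConfig
    weights: list[np.ndarray]  # W1, b1, W2, b2, W3, b3
    train_report: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "input_dim", "output_dim", "learning_rate", "epochs",
                    "batch_size", "class_weighting", "patience", "seed")},
                "hidden": list(self.config.hidden),
            },
            "weights": [w.tolist() for w in self.weights],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AnnModel":
        payload = json.loads(text)
        cfg = payload["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        return cls(AnnConfig(**cfg), [np.asarray(w, dtype=float) for w in payload["weights"]])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "AnnModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def init_model(config: AnnConfig) -> AnnModel:
    """Glorot-uniform initial weights, deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)
    dims = [config.input_dim, *config.hidden, config.output_dim]
    weights: list[np.ndarray] = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        scale = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-scale, scale, size=(d_in, d_out)))
        weights.append(np.zeros(d_out))
    return AnnModel(config, weights)


def _forward_pass(weights, X):
    W1, b1, W2, b2, W3, b3 = weights
    a1 = np.tanh(X @ W1 + b1)
    a2 = np.tanh(a1 @ W2 + b2)
    z = np.tanh(a2 @ W3 + b3)
    # exponential normalization of the tanh-bounded outputs
    e = np.exp(z - z.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    return a1, a2, z, p


def forward(model: AnnModel, features) -> np.ndarray:
    """Probability vector(s) (p_true, p_false); rows sum to one."""
    X = np.asarray(features, dtype=float)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"expected {model.config.input_dim} features, got {X.shape[1]}"
        )
    _, _, _, p = _forward_pass(model.weights, X)
    return p[0] if squeeze else p


def loss_and_grads(weights, X, Y, sample_weight=None):
    """Weighted cross-entropy and its analytic gradients.

    Y holds one row per sample: [1, 0] for positives, [0, 1] for
    negatives.  Gradients are exact; a finite-difference check is part
    of the test suite.
    """
    W1, b1, W2, b2, W3, b3 = weights
    a1, a2, z, p = _forward_pass(weights, X)
    w = np.ones(len(X)) if sample_weight is None else np.asarray(sample_weight, float)
    wsum = w.sum()
    eps = 1e-12
    loss = float(-(w[:, None] * Y * np.log(p + eps)).sum() / wsum)

    dz_pre = (w[:, None] * (p - Y) / wsum) * (1.0 - z**2)  # through tanh output
    gW3 = a2.T @ dz_pre
    gb3 = dz_pre.sum(axis=0)
    d2 = (dz_pre @ W3.T) * (1.0 - a2**2)
    gW2 = a1.T @ d2
    gb2 = d2.sum(axis=0)
    d1 = (d2 @ W2.T) * (1.0 - a1**2)
    gW1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    return loss, [gW1, gb1, gW2, gb2, gW3, gb3]


def train(model: AnnModel, features, labels, validation=None) -> AnnModel:
    """Gradient-descent training with optional early stopping.

    ``labels`` is binary (1 = positive) or two-column one-hot.  When a
    ``(X_val, y_val)`` tuple is given, validation accuracy is tracked
    each epoch and training stops after ``patience`` epochs without
    improvement, restoring the best weights seen.
    """
    cfg = model.config
    X = np.asarray(features, dtype=float)
    Y = _one_hot(labels)
    if len(np.unique(Y[:, 0])) < 2:
        raise ValueError("training set contains a single class")
    w = _sample_weights(Y, cfg.class_weighting)

    val = None
    if validation is not None:
        Xv = np.asarray(validation[0], dtype=float)
        Yv = _one_hot(validation[1])
        val = (Xv, Yv)

    rng = np.random.default_rng(cfg.seed + 1)
    weights = [w_.copy() for w_ in model.weights]
    best = [w_.copy() for w_ in weights]
    best_val, since_best = -np.inf, 0
    losses, val_accs = [], []

    for _ in range(cfg.epochs):
        if cfg.batch_size is None or cfg.batch_size >= len(X):
            batches = [np.arange(len(X))]
        else:
            order = rng.permutation(len(X))
            batches = np.array_split(order, int(np.ceil(len(X) / cfg.batch_size)))
        epoch_loss = 0.0
        for idx in batches:
            loss, grads = loss_and_grads(weights, X[idx], Y[idx], w[idx])
            epoch_loss += loss * len(idx)
            for w_, g in zip(weights, grads):
                w_ -= cfg.learning_rate * g
        losses.append(epoch_loss / len(X))

        if val is not None:
            _, _, _, pv = _forward_pass(weights, val[0])
            acc = float(((pv[:, 0] > 0.5) == (val[1][:, 0] > 0.5)).mean())
            val_accs.append(acc)
            if acc > best_val:
                best_val, since_best = acc, 0
                best = [w_.copy() for w_ in weights]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break

    final = best if val is not None and best_val > -np.inf else weights
    report = {"loss": losses, "val_accuracy": val_accs}
    return AnnModel(cfg, final, report)


def predict(model: AnnModel, features):
    """(label, score): positive iff p_true > 0.5; score is p_true."""
    p = forward(model, features)
    if p.ndim == 1:
        return bool(p[0] > 0.5), float(p[0])
    return p[:, 0] > 0.5, p[:, 0]


def _one_hot(labels) -> np.ndarray:
    Y = np.asarray(labels)
    if Y.ndim == 2:
        return Y.astype(float)
    y = Y.astype(int)
    return np.column_stack([y, 1 - y]).astype(float)


def _sample_weights(Y: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return np.ones(len(Y))
    pos = Y[:, 0] > 0.5
    n, n_pos = len(Y), int(pos.sum())
    w = np.where(pos, n / (2.0 * max(n_pos, 1)), n / (2.0 * max(n - n_pos, 1)))
    return w


class TanhSoftmaxANN(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper around the fixed 10/20/2 tanh network.

    Parameters mirror :class:`AnnConfig`; ``validation_fraction`` > 0
    carves an internal stratified validation split used for early
    stopping.  ``y`` is binary with 1 = positive interaction.
    """

    def __init__(
        self,
        hidden: tuple[int, int] = (10, 20),
        learning_rate: float = 0.01,
        epochs: int = 2000,
        batch_size: int | None = None,
        class_weighting: str = "inverse_frequency",
        patience: int = 50,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.class_weighting = class_weighting
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def fit(self, X, y):
        from sklearn.model_selection import train_test_split

        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        cfg = AnnConfig(
            input_dim=X.shape[1],
            hidden=tuple(self.hidden),
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            class_weighting=self.class_weighting,
            patience=self.patience,
            seed=self.seed,
        )
        model = init_model(cfg)
        validation = None
        Xt, yt = X, y
        if self.validation_fraction and len(X) >= 20:
            Xt, Xv, yt, yv = train_test_split(
                X, y, test_size=self.validation_fraction,
                random_state=self.seed, stratify=y,
            )
            validation = (Xv, yv)
        self.model_ = train(model, Xt, yt, validation)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        p = forward(self.model_, np.atleast_2d(np.asarray(X, dtype=float)))
        # sklearn column order follows classes_ = [0, 1] = [negative, positive]
        return np.column_stack([p[:, 1], p[:, 0]])

    def predict(self, X) -> np.ndarray:
        p = forward(self.model_, np.atleast_2d(np.asarray(X, dtype=float)))
        return (p[:, 0] > 0.5).astype(int)
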