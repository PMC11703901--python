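"""Shared neural-network engine.

A single hidden layer sigmoid multilayer perceptron (N-2-1 by default)
trained by per-sample backpropagation with momentum, uniform weight
initialisation, a train/validation/test split, early stopping against the
validation MSE, and Monte Carlo cross-validation for single-predictor
screening.  This small engine is shared by the stepwise screening stage and
the swarm inference stage; both only vary its hyperparameters.

Hyperparameter defaults: learning rate 0.1, momentum 0.5, initial weights
uniform in [-1, 1], 60:20:20 train/validation/test split with 50 MCCV
iterations, at most 3000 epochs with a 1000-epoch no-improvement patience
window and an MSE improvement threshold of 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _backprop
from ._util import derive_seeds

__all__ = [
    "MLPConfig",
    "TrainedMLP",
    "split_indices",
    "train_mlp",
    "predict",
    "mccv_mse",
    "mse_loss_gradients",
]


class ParameterError(ValueError):
    """Invalid hyperparameter or inconsistent input sizes."""


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of one N-`n_hidden`-1 sigmoid perceptron fit."""

    n_hidden: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.5
    init_weight_range: tuple[float, float] = (-1.0, 1.0)
    max_epochs: int = 3000
    patience_epochs: int = 1000
    mse_improvement_threshold: float = 0.01
    mse_target: float | None = None
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    mccv_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ParameterError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.momentum < 0:
            raise ParameterError("momentum must be non-negative")
        if self.max_epochs < 1 or self.patience_epochs < 1:
            raise ParameterError("max_epochs and patience_epochs must be >= 1")
        if self.mse_improvement_threshold <= 0:
            raise ParameterError("mse_improvement_threshold must be positive")
        if self.mse_target is not None and self.mse_target < 0:
            raise ParameterError("mse_target must be non-negative (or None)")
        if self.mccv_iterations < 1:
            raise ParameterError("mccv_iterations must be >= 1")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")
        lo, hi = self.init_weight_range
        if lo > hi:
            raise ParameterError("init_weight_range must satisfy lo <= hi")
        if self.train_fraction <= 0 or self.val_fraction <= 0 or self.test_fraction < 0:
            raise ParameterError("train/val fractions must be positive, test non-negative")
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"split fractions must sum to 1, got {total}")

    def with_seed(self, seed: int) -> "MLPConfig":
        return replace(self, seed=int(seed))


_STOP_REASONS = {
    _backprop.STOP_MAX_EPOCHS: "max_epochs",
    _backprop.STOP_PATIENCE: "patience",
    _backprop.STOP_THRESHOLD: "threshold",
}


@dataclass
class TrainedMLP:
    """A fitted N-`h`-1 perceptron with the weights of its best-validation epoch."""

    input_gene_ids: tuple[str, ...]
    W_in_hidden: np.ndarray  # (n_inputs, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    W_hidden_out: np.ndarray  # (n_hidden,)
    b_out: float
    epochs_run: int
    stop_reason: str
    train_mse: float
    val_mse: float
    val_pearson_r: float

    @property
    def n_inputs(self) -> int:
        return self.W_in_hidden.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W_in_hidden.shape[1]

    def to_json(self) -> str:
        doc = {
            "format": "swarmnet.TrainedMLP",
            "version": 1,
            "input_gene_ids": list(self.input_gene_ids),
            "W_in_hidden": self.W_in_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "W_hidden_out": self.W_hidden_out.tolist(),
            "b_out": self.b_out,
            "epochs_run": self.epochs_run,
            "stop_reason": self.stop_reason,
            "train_mse": self.train_mse,
            "val_mse": self.val_mse,
            "val_pearson_r": self.val_pearson_r,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedMLP":
        doc = json.loads(text)
        if doc.get("format") != "swarmnet.TrainedMLP":
            raise ValueError("not a serialized TrainedMLP document")
        return cls(
            input_gene_ids=tuple(doc["input_gene_ids"]),
            W_in_hidden=np.asarray(doc["W_in_hidden"], dtype=float),
            b_hidden=np.asarray(doc["b_hidden"], dtype=float),
            W_hidden_out=np.asarray(doc["W_hidden_out"], dtype=float),
            b_out=float(doc["b_out"]),
            epochs_run=int(doc["epochs_run"]),
            stop_reason=str(doc["stop_reason"]),
            train_mse=float(doc["train_mse"]),
            val_mse=float(doc["val_mse"]),
            val_pearson_r=float(doc["val_pearson_r"]),
        )


def split_indices(
    n_samples: int, config: MLPConfig, split_seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random train/validation/test index partition for one MCCV iteration."""
    rng = np.random.default_rng(split_seed)
    return _split(rng, n_samples, config)


def _split(rng, n_samples, config):
    perm = rng.permutation(n_samples)
    n_tr = int(round(config.train_fraction * n_samples))
    n_val = int(round(config.val_fraction * n_samples))
    n_te = n_samples - n_tr - n_val
    if n_tr < 1 or n_val < 1 or (config.test_fraction > 0 and n_te < 1):
        raise ParameterError(
            f"{n_samples} samples cannot populate a "
            f"{config.train_fraction}:{config.val_fraction}:{config.test_fraction} split"
        )
    return perm[:n_tr], perm[n_tr : n_tr + n_val], perm[n_tr + n_val :]


def _init_weights(config: MLPConfig, n_inputs: int, init_seed: int):
    lo, hi = config.init_weight_range
    rng = np.random.default_rng(init_seed)
    W1 = rng.uniform(lo, hi, size=(n_inputs, config.n_hidden))
    b1 = rng.uniform(lo, hi, size=config.n_hidden)
    W2 = rng.uniform(lo, hi, size=config.n_hidden)
    b2 = float(rng.uniform(lo, hi))
    return W1, b1, W2, b2


def _forward(W1, b1, W2, b2, X):
    hidden = 1.0 / (1.0 + np.exp(-(X @ W1 + b1)))
    return 1.0 / (1.0 + np.exp(-(hidden @ W2 + b2)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _check_xy(X, y):
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError("X must be 2-D (samples x inputs)")
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise ParameterError("y must be 1-D with one value per sample")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ParameterError("X and y must be finite")
    if X.shape[0] < 10:
        raise ParameterError("at least 10 samples are required")
    return X, y


def _fit(X, y, config, tr, va, init_seed, order_rng, input_ids):
    """Train on precomputed partitions; shared by train_mlp and mccv_mse."""
    W1, b1, W2, b2 = _init_weights(config, X.shape[1], init_seed)
    order = order_rng.permutation(tr.size)
    Xtr = np.ascontiguousarray(X[tr][order])
    ytr = np.ascontiguousarray(y[tr][order])
    Xval = np.ascontiguousarray(X[va])
    yval = np.ascontiguousarray(y[va])
    bW1, bb1, bW2, bb2, best_val, epochs_run, stop = _backprop.train_backprop(
        Xtr, ytr, Xval, yval, W1, b1, W2, b2,
        config.learning_rate, config.momentum,
        config.max_epochs, config.patience_epochs,
        config.mse_improvement_threshold,
        -1.0 if config.mse_target is None else config.mse_target,
    )
    if stop == _backprop.STOP_NONFINITE:
        raise FloatingPointError(
            f"non-finite validation loss at epoch {epochs_run}"
        )
    pred_tr = _forward(bW1, bb1, bW2, bb2, Xtr)
    pred_val = _forward(bW1, bb1, bW2, bb2, Xval)
    return TrainedMLP(
        input_gene_ids=tuple(input_ids),
        W_in_hidden=bW1,
        b_hidden=bb1,
        W_hidden_out=bW2,
        b_out=float(bb2),
        epochs_run=int(epochs_run),
        stop_reason=_STOP_REASONS[stop],
        train_mse=float(np.mean((pred_tr - ytr) ** 2)),
        val_mse=float(best_val),
        val_pearson_r=_pearson(pred_val, yval),
    )


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    config: MLPConfig,
    split_seed: int,
    init_seed: int,
    input_gene_ids: tuple[str, ...] | None = None,
) -> TrainedMLP:
    """Fit one perceptron.

    ``split_seed`` controls the sample partition and the (fixed) within-epoch
    presentation order; ``init_seed`` controls the initial weights.  The two
    streams are independent, so changing one leaves the other untouched.
    The test partition implied by ``config.test_fraction`` is reserved for
    the caller (MCCV scoring) and is not touched here.
    """
    X, y = _check_xy(X, y)
    if input_gene_ids is None:
        input_gene_ids = tuple(f"x{i}" for i in range(X.shape[1]))
    if len(input_gene_ids) != X.shape[1]:
        raise ParameterError("input_gene_ids length must match X columns")
    split_rng = np.random.default_rng(split_seed)
    tr, va, _te = _split(split_rng, X.shape[0], config)
    return _fit(X, y, config, tr, va, init_seed, split_rng, input_gene_ids)


def predict(mlp: TrainedMLP, X: np.ndarray) -> np.ndarray:
    """Forward pass; sigmoid output in (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != mlp.n_inputs:
        raise ParameterError(
            f"X has {X.shape[1]} columns but the model expects {mlp.n_inputs}"
        )
    return _forward(mlp.W_in_hidden, mlp.b_hidden, mlp.W_hidden_out, mlp.b_out, X)


def mccv_mse(X: np.ndarray, y: np.ndarray, config: MLPConfig) -> float:
    """Mean held-out-test MSE over Monte Carlo cross-validation splits.

    For each of ``config.mccv_iterations`` random train/validation/test
    partitions (seeds derived from ``config.seed`` and the iteration index),
    trains a perceptron and scores it on the untouched test partition.
    Lower means a stronger predictor.
    """
    X, y = _check_xy(X, y)
    if config.test_fraction <= 0:
        raise ParameterError("mccv_mse requires a positive test_fraction")
    ids = tuple(f"x{i}" for i in range(X.shape[1]))
    total = 0.0
    for i in range(config.mccv_iterations):
        split_seed, init_seed = derive_seeds(config.seed, i)
        split_rng = np.random.default_rng(split_seed)
        tr, va, te = _split(split_rng, X.shape[0], config)
        mlp = _fit(X, y, config, tr, va, init_seed, split_rng, ids)
        pred = predict(mlp, X[te])
        total += float(np.mean((pred - y[te]) ** 2))
    return total / config.mccv_iterations


def mse_loss_gradients(W1, b1, W2, b2, X, y):
    """Exact gradient of L = mean((yhat - y)^2) w.r.t. all parameters.

    Used as the analytic side of the finite-difference gradient check; the
    training kernel's per-sample deltas are the classic scaled form of the
    same derivatives.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    z1 = X @ W1 + b1
    h = 1.0 / (1.0 + np.exp(-z1))
    z2 = h @ W2 + b2
    o = 1.0 / (1.0 + np.exp(-z2))
    loss = float(np.mean((o - y) ** 2))
    d_z2 = (2.0 / n) * (o - y) * o * (1.0 - o)  # (n,)
    gb2 = float(np.sum(d_z2))
    gW2 = h.T @ d_z2
    d_h = np.outer(d_z2, W2)
    d_z1 = d_h * h * (1.0 - h)
    gW1 = X.T @ d_z1
    gb1 = d_z1.sum(axis=0)
    return loss, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}
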