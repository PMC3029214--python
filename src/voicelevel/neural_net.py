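"""Small dense MLP with tanh hidden units and logistic outputs.

The same network family is used twice in the system: as the word-feature
classifier (5 inputs - 10 hidden - 4 outputs) and as the stacked-fusion
meta-classifier (6 - 10 - 4).  Training is plain full-batch gradient
descent on mean squared error against one-hot level targets — deliberately
simple backpropagation, deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MLPModel",
    "init_mlp",
    "train_mlp",
    "predict_level",
    "one_hot_levels",
    "mlp_to_dict",
    "mlp_from_dict",
]


@dataclass
class MLPModel:
    """One-hidden-layer perceptron: tanh hidden, logistic output."""

    W1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray
    W2: np.ndarray  # (n_hidden, n_out)
    b2: np.ndarray
    input_mean: np.ndarray | None = None
    input_std: np.ndarray | None = None
    trained: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return self.W1.shape[0], self.W1.shape[1], self.W2.shape[1]

    def forward(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"input dimension {X.shape[1]} != network input {self.W1.shape[0]}"
            )
        if self.input_mean is not None:
            X = (X - self.input_mean) / self.input_std
        H = np.tanh(X @ self.W1 + self.b1)
        out = _logistic(H @ self.W2 + self.b2)
        return X, H, out


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def one_hot_levels(levels: np.ndarray, n_levels: int = 4) -> np.ndarray:
    levels = np.asarray(levels, dtype=int)
    if np.any((levels < 1) | (levels > n_levels)):
        raise ValueError("levels must be in 1..n_levels")
    Y = np.zeros((levels.size, n_levels))
    Y[np.arange(levels.size), levels - 1] = 1.0
    return Y


def init_mlp(
    n_in: int, n_hidden: int = 10, n_out: int = 4, seed: int = 0
) -> MLPModel:
    """Small-random (Glorot-scaled) initialization, deterministic per seed."""
    rng = np.random.default_rng(int(seed) % (2**31))
    s1 = np.sqrt(2.0 / (n_in + n_hidden))
    s2 = np.sqrt(2.0 / (n_hidden + n_out))
    return MLPModel(
        W1=rng.normal(0.0, s1, size=(n_in, n_hidden)),
        b1=np.zeros(n_hidden),
        W2=rng.normal(0.0, s2, size=(n_hidden, n_out)),
        b2=np.zeros(n_out),
    )


def mlp_gradients(model: MLPModel, X: np.ndarray, Y: np.ndarray):
    """MSE loss and gradients for one batch (used by training and tests)."""
    Xn, H, out = model.forward(X)
    n = Xn.shape[0]
    err = out - Y
    loss = float(np.mean(err**2))
    # d loss / d pre-activation of output: 2/(n*k) * err * out * (1-out)
    k = Y.shape[1]
    delta_out = (2.0 / (n * k)) * err * out * (1.0 - out)
    gW2 = H.T @ delta_out
    gb2 = delta_out.sum(axis=0)
    delta_h = (delta_out @ model.W2.T) * (1.0 - H**2)
    gW1 = Xn.T @ delta_h
    gb1 = delta_h.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def train_mlp(
    model: MLPModel,
    inputs: np.ndarray,
    targets: np.ndarray,
    epochs: int = 2000,
    lr: float = 0.01,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    patience: int = 200,
    normalize_inputs: bool = True,
) -> tuple[MLPModel, list[float]]:
    """Full-batch gradient-descent backprop on MSE; returns per-epoch losses.

    With a ``validation`` pair, training stops early when validation MSE has
    not improved for ``patience`` epochs.  Raises if the loss diverges.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and targets must be aligned")
    if normalize_inputs and model.input_mean is None:
        std = X.std(axis=0)
        model.input_mean = X.mean(axis=0)
        model.input_std = np.where(std > 1e-12, std, 1.0)

    losses: list[float] = []
    best_val = np.inf
    best_params = None
    stale = 0
    for _ in range(epochs):
        loss, (gW1, gb1, gW2, gb2) = mlp_gradients(model, X, Y)
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged (NaN loss); lower the learning rate")
        losses.append(loss)
        model.W1 -= lr * gW1
        model.b1 -= lr * gb1
        model.W2 -= lr * gW2
        model.b2 -= lr * gb2
        if validation is not None:
            _, _, vout = model.forward(validation[0])
            vloss = float(np.mean((vout - validation[1]) ** 2))
            if vloss < best_val - 1e-9:
                best_val = vloss
                best_params = (model.W1.copy(), model.b1.copy(), model.W2.copy(), model.b2.copy())
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_params is not None:
        model.W1, model.b1, model.W2, model.b2 = best_params
    model.trained = True
    return model, losses


def mlp_to_dict(model: MLPModel) -> dict:
    """JSON-serializable snapshot of the network."""
    return {
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "input_mean": None if model.input_mean is None else model.input_mean.tolist(),
        "input_std": None if model.input_std is None else model.input_std.tolist(),
        "trained": model.trained,
        "meta": model.meta,
    }


def mlp_from_dict(payload: dict) -> MLPModel:
    im, isd = payload.get("input_mean"), payload.get("input_std")
    return MLPModel(
        W1=np.asarray(payload["W1"]),
        b1=np.asarray(payload["b1"]),
        W2=np.asarray(payload["W2"]),
        b2=np.asarray(payload["b2"]),
        input_mean=None if im is None else np.asarray(im),
        input_std=None if isd is None else np.asarray(isd),
        trained=bool(payload.get("trained", False)),
        meta=payload.get("meta", {}),
    )


def predict_level(model: MLPModel, x: np.ndarray):
    """Level decision (argmax output unit, ties toward the lower level)."""
    _, _, out = model.forward(np.atleast_2d(x))
    soft = out[0]
    return int(np.argmax(soft)) + 1, soft
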