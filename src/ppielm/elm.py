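"""Extreme learning machine (ELM) for binary classification.

A single-hidden-layer feed-forward network whose input weights ``w_i`` and
biases ``b_i`` are drawn once at random (uniform on [-1, 1]) and never
adjusted; training reduces to the linear least-squares problem H beta = T,
where H[j, i] = g(w_i . x_j + b_i) is the hidden-layer output matrix, and
is solved in closed form by the Moore-Penrose pseudoinverse,
beta = pinv(H) T — the minimum-norm least-squares solution.  Targets are
coded +/-1 and the decision threshold is 0, so the raw scores H beta double
as ROC inputs.

Inputs are min-max scaled to [0, 1] per feature using statistics from the
training data only; random projections are scale-sensitive and the CTD
percentages (0-100) would otherwise dominate the AAC fractions (0-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import scipy.linalg

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "hardlim": lambda z: (z >= 0).astype(np.float64),
    "gaussian": lambda z: np.exp(-np.square(z)),
    "sine": np.sin,
    "tribas": lambda z: np.maximum(0.0, 1.0 - np.abs(z)),
}

#: Default hidden-layer size as a fraction of the training-sample count.
AUTO_HIDDEN_FRACTION = 0.09


@dataclass
class MinMaxScaler:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0."""

    data_min: np.ndarray
    data_range: np.ndarray  # max - min, with zeros replaced by 1

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        rng[rng == 0] = 1.0
        return cls(lo, rng)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.data_min) / self.data_range


@dataclass
class ElmModel:
    """A (possibly partially) fitted ELM.

    ``output_weights`` and ``scaler`` are None until :func:`fit` completes.
    """

    input_weights: np.ndarray          # (L, n)
    biases: np.ndarray                 # (L,)
    activation: str
    seed: int
    output_weights: np.ndarray | None = None   # (L, m)
    scaler: MinMaxScaler | None = None
    ridge: float = 0.0

    @property
    def L(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


def auto_hidden_count(n_samples: int) -> int:
    """Default hidden-neuron count: 9% of the sample count (rounded,
    at least 1)."""
    return max(1, round(AUTO_HIDDEN_FRACTION * n_samples))


def init_hidden_layer(n_features: int, L: int, activation: str = "sigmoid",
                      seed: int = 0) -> ElmModel:
    """Draw input weights and biases i.i.d. uniform on [-1, 1]."""
    if L < 1:
        raise ValueError("hidden-neuron count L must be >= 1")
    if activation not in ACTIVATIONS:
        raise ValueError(
            f"unknown activation {activation!r}; choose from "
            f"{sorted(ACTIVATIONS)}"
        )
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, n_features))
    b = rng.uniform(-1.0, 1.0, size=L)
    return ElmModel(W, b, activation, seed)


def hidden_output(model: ElmModel, X_scaled: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix H[j, i] = g(w_i . x_j + b_i).

    ``X_scaled`` must already be on the model's scale.
    """
    X_scaled = np.atleast_2d(np.asarray(X_scaled, dtype=np.float64))
    if X_scaled.shape[1] != model.n_features:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features}, "
            f"got {X_scaled.shape[1]}"
        )
    g = ACTIVATIONS[model.activation]
    return g(X_scaled @ model.input_weights.T + model.biases)


def solve_output_weights(H: np.ndarray, T: np.ndarray,
                         ridge: float = 0.0) -> np.ndarray:
    """Minimum-norm least-squares output weights beta = pinv(H) T.

    With ridge > 0 solves the regularized normal equations
    (H'H + ridge I) beta = H'T instead.
    """
    H = np.asarray(H, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if T.ndim == 1:
        T = T[:, None]
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T must have equal row counts")
    if not np.all(np.isfinite(H)):
        raise ValueError("hidden matrix contains non-finite entries")
    if ridge > 0:
        L = H.shape[1]
        return np.linalg.solve(H.T @ H + ridge * np.eye(L), H.T @ T)
    # gelsd returns the minimum-norm solution for rank-deficient H
    beta, *_ = scipy.linalg.lstsq(H, T, lapack_driver="gelsd")
    return beta


def fit(X: np.ndarray, y: np.ndarray, L: int | str = "auto",
        activation: str = "sigmoid", seed: int = 0,
        ridge: float = 0.0) -> ElmModel:
    """Train an ELM on inputs ``X`` and binary labels ``y`` (0/1 or +/-1).

    ``L="auto"`` sets the hidden-layer size to 9% of the sample count.
    The min-max scaler is fitted on ``X`` (training data only).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training targets contain a single class")
    if classes.size > 2:
        raise ValueError("binary targets required")
    t = np.where(y == classes.max(), 1.0, -1.0)  # +/-1 coding
    if L == "auto":
        L = auto_hidden_count(X.shape[0])
    model = init_hidden_layer(X.shape[1], int(L), activation, seed)
    model.ridge = float(ridge)
    model.scaler = MinMaxScaler.fit(X)
    H = hidden_output(model, model.scaler.transform(X))
    model.output_weights = solve_output_weights(H, t, ridge=ridge)
    return model


def decision_scores(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Continuous confidence scores H beta (one per sample); the predicted
    class is interacting iff the score is >= 0."""
    if model.output_weights is None or model.scaler is None:
        raise ValueError("model is not fitted")
    H = hidden_output(model, model.scaler.transform(np.asarray(X, dtype=np.float64)))
    return (H @ model.output_weights).ravel()


def predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Binary predictions (1 = interacting) by thresholding scores at 0."""
    return (decision_scores(model, X) >= 0).astype(np.int64)


def save_model(model: ElmModel, path: str | Path) -> None:
    """Persist a fitted model as a single npz archive (lossless)."""
    if model.output_weights is None or model.scaler is None:
        raise ValueError("refusing to save an unfitted model")
    meta = json.dumps({"activation": model.activation, "seed": model.seed,
                       "ridge": model.ridge})
    np.savez(
        path,
        input_weights=model.input_weights,
        biases=model.biases,
        output_weights=model.output_weights,
        scaler_min=model.scaler.data_min,
        scaler_range=model.scaler.data_range,
        meta=np.array(meta),
    )


def load_model(path: str | Path) -> ElmModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        return ElmModel(
            input_weights=archive["input_weights"],
            biases=archive["biases"],
            activation=meta["activation"],
            seed=int(meta["seed"]),
            output_weights=archive["output_weights"],
            scaler=MinMaxScaler(archive["scaler_min"], archive["scaler_range"]),
            ridge=float(meta["ridge"]),
        )
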