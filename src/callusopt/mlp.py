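"""Multilayer-perceptron surrogate for callus-induction percentage and speed.

A feed-forward network (default: one hidden layer of 11 tanh units, linear
output) maps the 10-dimensional condition encoding to a single response.
Training minimises mean squared error plus an L2 weight penalty — the
deterministic core of Bayesian-regularised backpropagation — using the
analytic backprop gradient under a quasi-Newton line-search optimiser, so a
fixed seed gives bit-identical weights and the recorded loss history is
non-increasing over accepted epochs.

Inputs and the target are min–max scaled to [0, 1] for training and the
scaling inverted for prediction; percentage predictions are clipped to
[0, 100] at the interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import summary_features, summary_target


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss); carries the loss history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass
class MLPConfig:
    hidden_units: tuple[int, ...] = (11,)
    activation: str = "tanh"
    max_epochs: int = 2000
    l2_alpha: float = 3e-3
    seed: int = 0
    train_fraction: float = 0.9

    def __post_init__(self) -> None:
        if isinstance(self.hidden_units, int):
            self.hidden_units = (self.hidden_units,)
        if not self.hidden_units or any(h < 1 for h in self.hidden_units):
            raise ValueError("hidden_units must be >= 1 per layer")
        if self.activation not in ("tanh", "logistic"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.l2_alpha < 0:
            raise ValueError("l2_alpha must be >= 0")


def split_train_test(
    summaries: pd.DataFrame, fraction: float = 0.9, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint/exhaustive split with round(n * fraction) training rows."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(summaries)
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * fraction))
    return (
        summaries.iloc[np.sort(idx[:n_train])].reset_index(drop=True),
        summaries.iloc[np.sort(idx[n_train:])].reset_index(drop=True),
    )


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else 1.0 / (1.0 + np.exp(-z))


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed in terms of the activation value a
    return 1.0 - a * a if kind == "tanh" else a * (1.0 - a)


class TrainedMLP:
    """A trained network: layer weights, scalers, config and loss history."""

    kind = "mlp"

    def __init__(
        self,
        weights: list[np.ndarray],
        biases: list[np.ndarray],
        x_min: np.ndarray,
        x_range: np.ndarray,
        y_min: float,
        y_range: float,
        config: MLPConfig,
        target: str,
        history: list[float],
    ):
        self.weights = weights
        self.biases = biases
        self.x_min = x_min
        self.x_range = x_range
        self.y_min = y_min
        self.y_range = y_range
        self.config = config
        self.target = target
        self.history = history

    # -- prediction ---------------------------------------------------------

    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        a = Xs
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _act(a @ W + b, self.config.activation)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict on raw (unscaled) feature rows; clips percentage to [0, 100]."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.x_min.size:
            raise ValueError(
                f"expected {self.x_min.size} features, got {X.shape[1]}"
            )
        ys = self._forward((X - self.x_min) / self.x_range)
        y = ys * self.y_range + self.y_min
        if self.target == "percentage":
            y = np.clip(y, 0.0, 100.0)
        return y[0] if single else y

    def weight_norm(self) -> float:
        return float(np.sqrt(sum(float((W * W).sum()) for W in self.weights)))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "target": self.target,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_min": self.x_min.tolist(),
            "x_range": self.x_range.tolist(),
            "y_min": self.y_min,
            "y_range": self.y_range,
            "config": {
                "hidden_units": list(self.config.hidden_units),
                "activation": self.config.activation,
                "max_epochs": self.config.max_epochs,
                "l2_alpha": self.config.l2_alpha,
                "seed": self.config.seed,
                "train_fraction": self.config.train_fraction,
            },
            "history": self.history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedMLP":
        cfg = MLPConfig(
            hidden_units=tuple(d["config"]["hidden_units"]),
            activation=d["config"]["activation"],
            max_epochs=d["config"]["max_epochs"],
            l2_alpha=d["config"]["l2_alpha"],
            seed=d["config"]["seed"],
            train_fraction=d["config"]["train_fraction"],
        )
        return cls(
            [np.array(W) for W in d["weights"]],
            [np.array(b) for b in d["biases"]],
            np.array(d["x_min"]),
            np.array(d["x_range"]),
            float(d["y_min"]),
            float(d["y_range"]),
            cfg,
            d["target"],
            list(d["history"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TrainedMLP":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _layer_sizes(n_in: int, hidden: tuple[int, ...]) -> list[tuple[int, int]]:
    dims = [n_in, *hidden, 1]
    return list(zip(dims[:-1], dims[1:]))


def _unpack(theta: np.ndarray, shapes) -> tuple[list[np.ndarray], list[np.ndarray]]:
    Ws, bs, k = [], [], 0
    for n_in, n_out in shapes:
        Ws.append(theta[k : k + n_in * n_out].reshape(n_in, n_out))
        k += n_in * n_out
        bs.append(theta[k : k + n_out])
        k += n_out
    return Ws, bs


def _loss_grad(theta, shapes, Xs, ys, alpha, activation):
    Ws, bs = _unpack(theta, shapes)
    n = Xs.shape[0]
    acts = [Xs]
    a = Xs
    for W, b in zip(Ws[:-1], bs[:-1]):
        a = _act(a @ W + b, activation)
        acts.append(a)
    out = (a @ Ws[-1] + bs[-1]).ravel()
    resid = out - ys
    loss = float(resid @ resid) / n + alpha * sum(float((W * W).sum()) for W in Ws)

    gWs = [np.empty_like(W) for W in Ws]
    gbs = [np.empty_like(b) for b in bs]
    delta = (2.0 / n) * resid[:, None]          # d loss / d output
    gWs[-1] = acts[-1].T @ delta + 2.0 * alpha * Ws[-1]
    gbs[-1] = delta.sum(axis=0)
    for layer in range(len(Ws) - 2, -1, -1):
        delta = (delta @ Ws[layer + 1].T) * _act_grad(acts[layer + 1], activation)
        gWs[layer] = acts[layer].T @ delta + 2.0 * alpha * Ws[layer]
        gbs[layer] = delta.sum(axis=0)
    grad = np.concatenate([np.concatenate([W.ravel(), b]) for W, b in zip(gWs, gbs)])
    return loss, grad


def fit_mlp_arrays(
    X: np.ndarray, y: np.ndarray, cfg: MLPConfig, target: str = "percentage"
) -> TrainedMLP:
    """Fit the network on raw feature rows X and responses y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
        raise ValueError("X must be a non-empty 2-D array aligned with y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("features and targets must be finite")

    x_min = X.min(axis=0)
    ptp = np.ptp(X, axis=0)
    x_range = np.where(ptp > 0, ptp, 1.0)
    y_min = float(y.min())
    y_range = float(y.max() - y.min()) or 1.0
    Xs = (X - x_min) / x_range
    ys = (y - y_min) / y_range

    shapes = _layer_sizes(X.shape[1], cfg.hidden_units)
    rng = np.random.default_rng(cfg.seed)
    theta0 = np.concatenate(
        [
            np.concatenate(
                [
                    rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), n_in * n_out),
                    np.zeros(n_out),
                ]
            )
            for n_in, n_out in shapes
        ]
    )

    history: list[float] = [
        _loss_grad(theta0, shapes, Xs, ys, cfg.l2_alpha, cfg.activation)[0]
    ]

    def record(theta_k):
        history.append(
            _loss_grad(theta_k, shapes, Xs, ys, cfg.l2_alpha, cfg.activation)[0]
        )

    res = minimize(
        _loss_grad,
        theta0,
        args=(shapes, Xs, ys, cfg.l2_alpha, cfg.activation),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": cfg.max_epochs, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise TrainingError("training diverged to a non-finite loss", history)
    Ws, bs = _unpack(res.x, shapes)
    return TrainedMLP(Ws, bs, x_min, x_range, y_min, y_range, cfg, target, history)


def train_mlp(
    train: pd.DataFrame, target: str = "percentage", cfg: MLPConfig | None = None
) -> TrainedMLP:
    """Train on a condition-summary table for ``target`` in {percentage, speed}."""
    cfg = cfg or MLPConfig()
    return fit_mlp_arrays(summary_features(train), summary_target(train, target), cfg, target)


def predict_mlp(model: TrainedMLP, x: np.ndarray) -> np.ndarray | float:
    return model.predict(x)
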