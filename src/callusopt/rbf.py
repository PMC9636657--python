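"""Radial-basis-function network surrogate.

The network places a Gaussian kernel on each training point (or on a k-means
subset of them) and predicts by a weighted sum plus bias,

    Y(x) = w0 + sum_b w_b * exp(-(||x - X_b|| * 0.8326 / h)^2),

where h is the *spread*: with the 0.8326 factor (~ sqrt(ln 2)), a point at
distance h from a center receives kernel value ~0.5.  Distances are computed
on min–max-scaled features so h is dimensionless and the explant indicator
block cannot dominate the hormone concentrations.

Weights solve a ridge-regularised linear least-squares problem on the kernel
design matrix (the bias is not penalised); with all-training-point centers
and zero ridge the fit interpolates distinct training targets exactly.  When
no spread is supplied it is chosen by leave-one-out cross-validation over a
logarithmic grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .design import summary_features, summary_target

#: Kernel sharpness factor: distance h maps to exp(-0.8326^2) ~ 0.5.
KERNEL_FACTOR = 0.8326

_H_GRID = np.logspace(-1.2, 0.9, 22)


def gaussian_kernel(x_r: np.ndarray, x_b: np.ndarray, h: float) -> float:
    """Gaussian transfer function exp(-(||x_r - x_b|| * 0.8326 / h)^2)."""
    if h <= 0:
        raise ValueError(f"spread h must be positive, got {h}")
    x_r = np.asarray(x_r, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_r.shape != x_b.shape:
        raise ValueError("kernel arguments must have the same shape")
    d = float(np.linalg.norm(x_r - x_b))
    return float(np.exp(-((d * KERNEL_FACTOR / h) ** 2)))


@dataclass
class RBFConfig:
    h: float | None = None          # None -> leave-one-out grid search
    centers: str = "all_training_points"
    n_centers: int | None = None
    ridge_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h is not None and self.h <= 0:
            raise ValueError("spread h must be positive")
        if self.centers not in ("all_training_points", "kmeans_subset"):
            raise ValueError(f"unknown center selection {self.centers!r}")
        if self.centers == "kmeans_subset" and not self.n_centers:
            raise ValueError("kmeans_subset requires n_centers")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")


class SolverError(RuntimeError):
    pass


class TrainedRBF:
    """Centers (scaled space), weights, bias, spread and input scalers."""

    kind = "rbf"

    def __init__(self, centers, weights, bias, h, x_min, x_range, config, target):
        self.centers = centers
        self.weights = weights
        self.bias = float(bias)
        self.h = float(h)
        self.x_min = x_min
        self.x_range = x_range
        self.config = config
        self.target = target

    def _design(self, Xs: np.ndarray) -> np.ndarray:
        d = cdist(Xs, self.centers)
        return np.exp(-((d * KERNEL_FACTOR / self.h) ** 2))

    def predict(self, X: np.ndarray) -> np.ndarray | float:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.x_min.size:
            raise ValueError(f"expected {self.x_min.size} features, got {X.shape[1]}")
        Xs = (X - self.x_min) / self.x_range
        y = self._design(Xs) @ self.weights + self.bias
        if self.target == "percentage":
            y = np.clip(y, 0.0, 100.0)
        return float(y[0]) if single else y

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "target": self.target,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "h": self.h,
            "x_min": self.x_min.tolist(),
            "x_range": self.x_range.tolist(),
            "config": {
                "h": self.config.h,
                "centers": self.config.centers,
                "n_centers": self.config.n_centers,
                "ridge_lambda": self.config.ridge_lambda,
                "seed": self.config.seed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedRBF":
        cfg = RBFConfig(**d["config"])
        return cls(
            np.array(d["centers"]),
            np.array(d["weights"]),
            d["bias"],
            d["h"],
            np.array(d["x_min"]),
            np.array(d["x_range"]),
            cfg,
            d["target"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TrainedRBF":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _kernel_matrix(Xs: np.ndarray, centers: np.ndarray, h: float) -> np.ndarray:
    return np.exp(-((cdist(Xs, centers) * KERNEL_FACTOR / h) ** 2))


def _solve_weights(A: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve for [bias, weights] on design A = [1 | G]; bias unpenalised."""
    if lam == 0.0:
        # duplicate rows with conflicting targets make the system inconsistent
        _, inv = np.unique(np.round(A, 12), axis=0, return_inverse=True)
        for g in np.unique(inv):
            members = y[inv == g]
            if members.size > 1 and np.ptp(members) > 1e-12:
                raise SolverError(
                    "kernel system is singular with ridge_lambda=0 (duplicate "
                    "training points with different targets); set ridge_lambda > 0"
                )
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return coef
    # stacked form [A; sqrt(lam) P] w ~ [y; 0] avoids squaring the condition
    P = np.eye(A.shape[1])
    P[0, 0] = 0.0
    Aa = np.vstack([A, np.sqrt(lam) * P])
    ya = np.concatenate([y, np.zeros(A.shape[1])])
    coef, *_ = np.linalg.lstsq(Aa, ya, rcond=None)
    if not np.isfinite(coef).all():
        raise SolverError("ridge system singular; increase ridge_lambda")
    return coef


def _loo_rmse(A: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Closed-form leave-one-out RMSE of the ridge fit (hat-matrix identity)."""
    P = np.eye(A.shape[1])
    P[0, 0] = 0.0
    M = A.T @ A + lam * P
    try:
        Minv_At = np.linalg.solve(M, A.T)
    except np.linalg.LinAlgError:
        return np.inf
    H = A @ Minv_At
    resid = y - H @ y
    denom = 1.0 - np.diag(H)
    denom = np.where(np.abs(denom) < 1e-10, np.nan, denom)
    loo = resid / denom
    if np.isnan(loo).any():
        return np.inf
    return float(np.sqrt(np.mean(loo**2)))


def fit_rbf_arrays(
    X: np.ndarray, y: np.ndarray, cfg: RBFConfig | None = None, target: str = "percentage"
) -> TrainedRBF:
    cfg = cfg or RBFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
        raise ValueError("X must be a non-empty 2-D array aligned with y")

    x_min = X.min(axis=0)
    ptp = np.ptp(X, axis=0)
    x_range = np.where(ptp > 0, ptp, 1.0)
    Xs = (X - x_min) / x_range

    if cfg.centers == "kmeans_subset":
        from sklearn.cluster import KMeans

        if cfg.n_centers > len(Xs):
            raise ValueError("n_centers cannot exceed the number of training points")
        km = KMeans(n_clusters=cfg.n_centers, random_state=cfg.seed, n_init=10)
        km.fit(Xs)
        centers = km.cluster_centers_
    else:
        centers = Xs.copy()

    if cfg.h is None:
        scores = []
        if cfg.centers == "all_training_points":
            # Rippa's closed-form LOO for interpolation-style fits:
            # e_i = (K^-1 y)_i / (K^-1)_ii on the (ridged) kernel matrix.
            lam_sel = max(cfg.ridge_lambda, 1e-8)
            yc = y - y.mean()
            for h in _H_GRID:
                K = _kernel_matrix(Xs, centers, h) + lam_sel * np.eye(len(Xs))
                try:
                    Kinv = np.linalg.inv(K)
                except np.linalg.LinAlgError:
                    scores.append(np.inf)
                    continue
                e = (Kinv @ yc) / np.diag(Kinv)
                scores.append(float(np.sqrt(np.mean(e**2))))
        else:
            lam_sel = max(cfg.ridge_lambda, 1e-6)
            for h in _H_GRID:
                G = _kernel_matrix(Xs, centers, h)
                A = np.hstack([np.ones((len(Xs), 1)), G])
                scores.append(_loo_rmse(A, y, lam_sel))
        h = float(_H_GRID[int(np.argmin(scores))])
    else:
        h = float(cfg.h)

    G = _kernel_matrix(Xs, centers, h)
    A = np.hstack([np.ones((len(Xs), 1)), G])
    coef = _solve_weights(A, y, cfg.ridge_lambda)
    return TrainedRBF(centers, coef[1:], coef[0], h, x_min, x_range, cfg, target)


def fit_rbf(
    train: pd.DataFrame, target: str = "percentage", cfg: RBFConfig | None = None
) -> TrainedRBF:
    """Fit on a condition-summary table for ``target`` in {percentage, speed}."""
    return fit_rbf_arrays(summary_features(train), summary_target(train, target), cfg, target)


def predict_rbf(model: TrainedRBF, x: np.ndarray) -> np.ndarray | float:
    return model.predict(x)
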