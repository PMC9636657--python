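"""Model metrics and variable-sensitivity analysis.

RMSE and the coefficient of determination follow their standard definitions,
RMSE = sqrt(SS_res / n) and R^2 = 1 - SS_res / SS_tot (perfect fit: 0 and 1).

Input importance is ranked by the variable sensitivity error (VSE): the
model's RMSE when an input group is withheld and the model retrained with
otherwise identical hyperparameters and seed (leave-one-covariate-out), and
the variable sensitivity ratio VSR = VSE / baseline RMSE.  A more essential
input has a higher VSR; an uninformative one leaves the error unchanged
(VSR ~ 1).  Inputs are grouped semantically — the four hormone
concentrations, the MS-medium multiplier, the sampling day and the explant
one-hot block — so a categorical factor is removed as a whole.  A
permutation-importance mode (shuffle the group's columns instead of
retraining) is available as a cheaper alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import FEATURE_GROUPS, summary_features, summary_target


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("rmse needs at least one observation")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("r_squared needs at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared undefined for constant observations")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass(frozen=True)
class MetricReport:
    rmse: float
    r2: float
    n: int
    split: str


def evaluate_model(model, summaries: pd.DataFrame, target: str, split: str) -> MetricReport:
    """RMSE/R^2 of a trained surrogate on a condition-summary table."""
    y = summary_target(summaries, target)
    yhat = np.asarray(model.predict(summary_features(summaries)))
    return MetricReport(rmse(y, yhat), r_squared(y, yhat), len(y), split)


def _fitter(model_family: str, cfg) -> Callable[[np.ndarray, np.ndarray, str], object]:
    if model_family == "mlp":
        from .mlp import MLPConfig, fit_mlp_arrays

        cfg = cfg or MLPConfig()
        return lambda X, y, target: fit_mlp_arrays(X, y, cfg, target)
    if model_family == "rbf":
        from .rbf import RBFConfig, fit_rbf_arrays

        cfg = cfg or RBFConfig()
        return lambda X, y, target: fit_rbf_arrays(X, y, cfg, target)
    raise ValueError(f"model_family must be 'mlp' or 'rbf', got {model_family!r}")


def sensitivity_from_arrays(
    X: np.ndarray,
    y: np.ndarray,
    groups: Mapping[str, Sequence[int]],
    fit: Callable[[np.ndarray, np.ndarray, str], object],
    target: str = "percentage",
    mode: str = "loco",
    seed: int = 0,
) -> pd.DataFrame:
    """VSE/VSR table for arbitrary feature columns and a fitting callable."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_features = X.shape[1]
    all_cols = sorted({c for cols in groups.values() for c in cols})
    if any(c < 0 or c >= n_features for c in all_cols):
        raise ValueError("group column index out of range")
    baseline_model = fit(X, y, target)
    baseline = rmse(y, np.asarray(baseline_model.predict(X)))
    rows = []
    rng = np.random.default_rng(seed)
    for name, cols in groups.items():
        cols = list(cols)
        if len(cols) >= n_features:
            raise ValueError(f"removing group {name!r} would empty the feature set")
        if mode == "loco":
            keep = [c for c in range(n_features) if c not in cols]
            model_g = fit(X[:, keep], y, target)
            vse = rmse(y, np.asarray(model_g.predict(X[:, keep])))
        elif mode == "permutation":
            Xp = X.copy()
            Xp[:, cols] = Xp[rng.permutation(len(X))][:, cols]
            vse = rmse(y, np.asarray(baseline_model.predict(Xp)))
        else:
            raise ValueError(f"mode must be 'loco' or 'permutation', got {mode!r}")
        rows.append({"group": name, "vse": vse, "vsr": vse / baseline})
    report = pd.DataFrame(rows)
    report["rank"] = (
        report["vsr"].rank(ascending=False, method="first").astype(int)
    )
    report.attrs["baseline_rmse"] = baseline
    return report.sort_values("rank").reset_index(drop=True)


def sensitivity_analysis(
    data: pd.DataFrame,
    target: str = "percentage",
    model_family: str = "mlp",
    cfg=None,
    groups: Mapping[str, Sequence[int]] | None = None,
    mode: str = "loco",
    seed: int = 0,
) -> pd.DataFrame:
    """Rank input groups of a condition-summary table by VSR (highest first).

    The baseline error and each leave-one-covariate-out retrain share the
    same hyperparameters and seed, and both are evaluated on the full table,
    isolating the effect of withholding the variable.
    """
    groups = FEATURE_GROUPS if groups is None else groups
    X = summary_features(data)
    y = summary_target(data, target)
    return sensitivity_from_arrays(
        X, y, groups, _fitter(model_family, cfg), target, mode, seed
    )
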