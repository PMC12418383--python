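"""Model evaluation: cross-validation, error profiles and bias diagnostics.

The headline metric is the Pearson correlation between predicted and
observed labels, averaged over the folds of a 10-fold cross-validation.
Two CV schemes are supported: "standard" (one seeded shuffle, fixed
contiguous folds — deterministic) and "randomized" (independent re-shuffle
per repetition).  Error structure is summarized two ways: mean absolute
error within unit-width label intervals, and the ordinary-least-squares
slopes of predicted~observed and (predicted - observed)~observed, which
expose the regression-to-the-mean bias of CV-fitted models (the error
slope always equals the prediction slope minus one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SupervisedModel(Protocol):
    """Anything with sklearn-style fit/predict on array-likes."""

    def fit(self, X, y): ...

    def predict(self, X) -> np.ndarray: ...


ModelFactory = Callable[[], SupervisedModel]


@dataclass(frozen=True)
class CVScheme:
    mode: str = "standard"  # "standard" | "randomized"
    folds: int = 10
    seed: int = 0
    repetitions: int = 1  # only used in randomized mode

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.mode not in ("standard", "randomized"):
            raise ValueError(f"unknown CV mode {self.mode!r}")


@dataclass
class EvalReport:
    per_fold_r: list[float]
    mean_r: float
    pooled_r: float
    mse: float
    binned_abs_error: dict[tuple[float, float], float]
    bias: dict[str, float]
    n_flagged_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "per_fold_r": self.per_fold_r,
            "mean_r": self.mean_r,
            "pooled_r": self.pooled_r,
            "mse": self.mse,
            "binned_abs_error": {f"[{a:g},{b:g})": v for (a, b), v in self.binned_abs_error.items()},
            "bias": self.bias,
            "n_flagged_folds": self.n_flagged_folds,
        }


def pearson_r(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Pearson correlation coefficient between predictions and observations.

    r = sum((X - mean X)(Y - mean Y)) / sqrt(sum (X - mean X)^2) / sqrt(sum (Y - mean Y)^2).
    Raises on vectors of unequal length, length < 2, or zero variance.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length 1-D vectors, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    dx, dy = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(dx**2)), np.sqrt(np.sum(dy**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in predicted or observed values")
    return float(np.clip(np.sum(dx * dy) / (sx * sy), -1.0, 1.0))


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Contiguous folds (sizes differing by <= 1) of a shuffled index vector."""
    perm = rng.permutation(n)
    return [np.array(chunk) for chunk in np.array_split(perm, folds)]


def run_cv(
    model_factory: ModelFactory,
    X,
    y,
    scheme: CVScheme | None = None,
    edges: Sequence[float] | None = None,
) -> EvalReport:
    """Cross-validate a model and report correlation, error and bias profiles.

    ``model_factory`` must return a fresh sklearn-style estimator per call.
    mean_r is the unweighted mean of the per-fold Pearson r; pooled_r is
    computed once on all out-of-fold predictions.  Folds with constant
    observed labels are flagged and excluded from mean_r with a warning.
    """
    scheme = scheme or CVScheme()
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = Xm.shape[0]
    if n < scheme.folds:
        raise ValueError(f"n={n} smaller than folds={scheme.folds}")

    reps = scheme.repetitions if scheme.mode == "randomized" else 1
    rng = np.random.default_rng(scheme.seed)
    per_fold_r: list[float] = []
    pooled_pred = np.empty(n)
    flagged = 0
    all_pred, all_obs = [], []
    for rep in range(reps):
        for test_idx in _fold_indices(n, scheme.folds, rng):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            model = model_factory()
            model.fit(Xm[train_mask], yv[train_mask])
            pred = np.asarray(model.predict(Xm[test_idx]), dtype=float)
            if rep == 0:
                pooled_pred[test_idx] = pred
            all_pred.append(pred)
            all_obs.append(yv[test_idx])
            if np.ptp(yv[test_idx]) == 0 or np.ptp(pred) == 0:
                flagged += 1
                logger.warning("fold with constant values excluded from mean_r")
                continue
            per_fold_r.append(pearson_r(pred, yv[test_idx]))

    pred_cat = np.concatenate(all_pred)
    obs_cat = np.concatenate(all_obs)
    if edges is None:
        lo, hi = np.floor(yv.min()), np.ceil(yv.max())
        edges = np.arange(lo, hi + 1.0)
    return EvalReport(
        per_fold_r=per_fold_r,
        mean_r=float(np.mean(per_fold_r)) if per_fold_r else float("nan"),
        pooled_r=pearson_r(pooled_pred, yv),
        mse=float(np.mean((pred_cat - obs_cat) ** 2)),
        binned_abs_error=binned_abs_error(pooled_pred, yv, edges),
        bias=bias_slopes(pooled_pred, yv),
        n_flagged_folds=flagged,
    )


def binned_abs_error(
    predicted: Sequence[float], observed: Sequence[float], edges: Sequence[float]
) -> dict[tuple[float, float], float]:
    """Mean |predicted - observed| within [edge_j, edge_{j+1}) intervals of the observed value.

    Empty intervals are omitted from the result (absent, not zero).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    out: dict[tuple[float, float], float] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (obs >= lo) & (obs < hi)
        if mask.any():
            out[(float(lo), float(hi))] = float(np.mean(np.abs(pred[mask] - obs[mask])))
    return out


def bias_slopes(predicted: Sequence[float], observed: Sequence[float]) -> dict[str, float]:
    """OLS slopes of predicted~observed and (predicted - observed)~observed.

    A perfectly calibrated predictor has slopes (1, 0); shrinkage toward the
    mean shows as a prediction slope below 1 and an equally negative error
    slope (the two differ by exactly 1 by linearity of least squares).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    var = np.var(obs)
    if var == 0:
        raise ValueError("zero variance in observed values")
    slope_pred = float(np.cov(pred, obs, bias=True)[0, 1] / var)
    return {
        "slope_pred_vs_actual": slope_pred,
        "slope_error_vs_actual": slope_pred - 1.0,
    }


def ablation_study(
    X: pd.DataFrame,
    y,
    feature_groups: dict[str, Sequence[str]],
    model_factory: ModelFactory,
    scheme: CVScheme | None = None,
) -> pd.DataFrame:
    """Cross-validate the model on several feature subsets with shared folds.

    ``feature_groups`` maps a subset label to the column names it keeps.
    All subsets share the same fold assignments (same scheme and seed), so
    the comparison is paired.  Returns a table sorted by mean_r, best first.
    """
    scheme = scheme or CVScheme()
    rows = []
    for label, columns in feature_groups.items():
        columns = list(columns)
        if not columns:
            raise ValueError(f"feature subset {label!r} is empty")
        missing = set(columns) - set(X.columns)
        if missing:
            raise KeyError(f"subset {label!r}: unknown features {sorted(missing)[:5]}")
        report = run_cv(model_factory, X[columns], y, scheme)
        rows.append(
            {"subset": label, "n_features": len(columns), "mean_r": report.mean_r, "mse": report.mse}
        )
    return (
        pd.DataFrame(rows).sort_values("mean_r", ascending=False).reset_index(drop=True)
    )
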