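"""Randomized-tree regression of expression labels on the feature matrix.

The regressor is an ensemble of extremely randomized trees (random split
thresholds, no bootstrap by default): 100 trees, max_features = 0.8 and
min_samples_leaf = 1 as defaults, with predictions formed by the unweighted
mean of the tree outputs.  A grid search over

    n_estimators in {50, 100, 150},
    min_samples_leaf in {1, 2, 4},
    max_features in {0.5, 0.8}

selects the combination with the lowest 10-fold cross-validated MSE.
"""

from __future__ import annotations

import hashlib
import itertools
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.model_selection import KFold

DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [50, 100, 150],
    "min_samples_leaf": [1, 2, 4],
    "max_features": [0.5, 0.8],
}


@dataclass(frozen=True)
class RFHyperParams:
    n_estimators: int = 100
    max_features: float = 0.8
    min_samples_leaf: int = 1
    max_depth: int | None = None
    min_samples_split: int = 2
    bootstrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0 < self.max_features <= 1:
            raise ValueError("max_features must be in (0, 1]")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class RFBundle:
    """A trained ensemble plus everything needed to apply and audit it."""

    model: ExtraTreesRegressor
    feature_names: list[str]
    params: RFHyperParams
    fingerprint: str
    importances: np.ndarray

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "RFBundle":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain an RFBundle")
        return bundle


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_rf(X, y, params: RFHyperParams | None = None) -> RFBundle:
    """Fit an extremely-randomized-trees regressor; reproducible for a fixed seed."""
    params = params or RFHyperParams()
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if Xm.shape[0] != yv.shape[0]:
        raise ValueError(f"X has {Xm.shape[0]} rows but y has {yv.shape[0]}")
    if Xm.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(Xm)) or not np.all(np.isfinite(yv)):
        raise ValueError("non-finite values in X or y")
    model = ExtraTreesRegressor(
        n_estimators=params.n_estimators,
        max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf,
        max_depth=params.max_depth,
        min_samples_split=params.min_samples_split,
        bootstrap=params.bootstrap,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(Xm, yv)
    return RFBundle(
        model=model,
        feature_names=names,
        params=params,
        fingerprint=_fingerprint(Xm, yv),
        importances=model.feature_importances_,
    )


def predict_rf(bundle: RFBundle, X) -> np.ndarray:
    """Mean of the tree outputs for each row; columns must match training."""
    if isinstance(X, pd.DataFrame):
        cols = [str(c) for c in X.columns]
        if cols != bundle.feature_names:
            missing = set(bundle.feature_names) - set(cols)
            extra = set(cols) - set(bundle.feature_names)
            if missing or extra:
                raise ValueError(
                    f"feature mismatch: missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]}"
                )
            X = X[bundle.feature_names]  # same set, different order
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.shape[1] != len(bundle.feature_names):
            raise ValueError(
                f"expected {len(bundle.feature_names)} features, got {Xm.shape[1]}"
            )
    return bundle.model.predict(Xm)


def grid_search(
    X,
    y,
    grid: dict[str, list] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[RFHyperParams, pd.DataFrame]:
    """Exhaustive grid search by k-fold CV mean MSE.

    Folds are contiguous deterministic splits after one seeded shuffle, so
    the argmin is reproducible.  Ties are broken toward smaller
    n_estimators, then larger min_samples_leaf (the simpler model).
    Returns the winning hyperparameters and the full per-combination table.
    """
    grid = grid or DEFAULT_GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if folds > Xm.shape[0]:
        raise ValueError(f"folds={folds} exceeds n={Xm.shape[0]}")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(Xm))
    rows = []
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        params = replace(RFHyperParams(seed=seed), **overrides)
        fold_mse = []
        for train_idx, test_idx in splits:
            bundle = train_rf(Xm[train_idx], yv[train_idx], params)
            pred = predict_rf(bundle, Xm[test_idx])
            fold_mse.append(float(np.mean((pred - yv[test_idx]) ** 2)))
        rows.append({**overrides, "cv_mse": float(np.mean(fold_mse))})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["cv_mse", "n_estimators", "min_samples_leaf"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    best = order.iloc[0]
    best_params = replace(
        RFHyperParams(seed=seed),
        **{k: best[k] for k in keys if k in RFHyperParams.__dataclass_fields__},
    )
    # numpy scalars -> python types for a clean dataclass
    best_params = replace(
        best_params,
        n_estimators=int(best_params.n_estimators),
        min_samples_leaf=int(best_params.min_samples_leaf),
        max_features=float(best_params.max_features),
    )
    return best_params, table
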