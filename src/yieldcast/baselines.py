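"""The eight classical comparison learners and the CV hyperparameter search.

Estimators are scikit-learn models wrapped behind the package's
``fit(FeatureTable)`` / ``predict(FeatureTable)`` contract. The gradient
boosted tree family (named ``xgboost`` after the benchmarked method) is
backed by :class:`~sklearn.ensemble.HistGradientBoostingRegressor`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold, ParameterGrid, ParameterSampler
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigError
from .features import FeatureTable

BASELINE_NAMES: tuple[str, ...] = (
    "knn",
    "random_forest",
    "xgboost",
    "lasso",
    "ridge",
    "regression_tree",
    "svr",
    "dnn",
)


def euclidean_distance(p, q) -> float:
    """d(p, q) = sqrt(sum_i (q_i - p_i)^2); the KNN distance."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ConfigError(f"length mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((q - p) ** 2)))


@dataclass(frozen=True)
class BaselineSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ConfigError(f"unknown baseline {self.name!r}; valid names: {BASELINE_NAMES}")


class SklearnModel:
    """fit/predict adapter from FeatureTable to a scikit-learn estimator."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._columns: list[str] | None = None

    def fit(self, train: FeatureTable) -> "SklearnModel":
        self._columns = train.columns
        self.estimator.fit(train.X.to_numpy(dtype=float), train.y.to_numpy(dtype=float))
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        if self._columns is not None and table.columns != self._columns:
            raise ConfigError("feature columns differ from those seen at fit time")
        return np.asarray(self.estimator.predict(table.X.to_numpy(dtype=float)), dtype=float)


def _estimator(name: str, params: dict, seed: int):
    if name == "knn":
        return KNeighborsRegressor(metric="euclidean", **{"n_neighbors": 10, **params})
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed, **{"n_estimators": 100, "n_jobs": 1, **params})
    if name == "xgboost":
        return HistGradientBoostingRegressor(random_state=seed, **params)
    if name == "lasso":
        return Lasso(**{"alpha": 0.01, "max_iter": 20000, **params})
    if name == "ridge":
        return Ridge(**{"alpha": 1.0, **params})
    if name == "regression_tree":
        # split criterion: minimum within-partition sum of squared deviations
        return DecisionTreeRegressor(criterion="squared_error", random_state=seed, **params)
    if name == "svr":
        return SVR(**{"C": 1.0, "epsilon": 0.1, **params})
    if name == "dnn":
        return MLPRegressor(
            random_state=seed,
            **{
                "hidden_layer_sizes": (64, 32, 16),
                "activation": "relu",
                "max_iter": 500,
                "early_stopping": False,
                **params,
            },
        )
    raise ConfigError(f"unknown baseline {name!r}; valid names: {BASELINE_NAMES}")


def make_baseline(spec: BaselineSpec) -> SklearnModel:
    """Instantiate a fit/predict-capable baseline from its spec."""
    return SklearnModel(_estimator(spec.name, dict(spec.hyperparameters), spec.seed))


def default_search_space(name: str) -> dict:
    """Small, config-overridable hyperparameter spaces per learner."""
    spaces = {
        "knn": {"n_neighbors": [3, 5, 10, 20, 40], "weights": ["uniform", "distance"]},
        "random_forest": {
            "n_estimators": [50, 100, 200],
            "max_depth": [None, 8, 16],
            "min_samples_leaf": [1, 3, 10],
        },
        "xgboost": {
            "learning_rate": [0.03, 0.1, 0.3],
            "max_depth": [3, 6, None],
            "max_iter": [100, 300],
        },
        "lasso": {"alpha": [1e-4, 1e-3, 1e-2, 1e-1, 1.0]},
        "ridge": {"alpha": [1e-2, 1e-1, 1.0, 10.0, 100.0]},
        "regression_tree": {"max_depth": [4, 8, 16, None], "min_samples_leaf": [1, 5, 20]},
        "svr": {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1, 0.3], "gamma": ["scale"]},
        "dnn": {
            "hidden_layer_sizes": [(64, 32, 16), (128, 64), (32, 32)],
            "learning_rate_init": [1e-3, 3e-3],
        },
    }
    if name not in spaces:
        raise ConfigError(f"unknown baseline {name!r}; valid names: {BASELINE_NAMES}")
    return spaces[name]


@dataclass(frozen=True)
class SearchSpec:
    strategy: str = "randomized"  # or "grid"
    space: dict | None = None  # None -> default space for the model
    n_iter: int = 50
    k_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("grid", "randomized"):
            raise ConfigError(f"strategy must be 'grid' or 'randomized', got {self.strategy!r}")
        if self.n_iter < 1:
            raise ConfigError("n_iter: must be >= 1")
        if self.k_folds < 2:
            raise ConfigError("k_folds: must be >= 2")


def tune_hyperparameters(
    name: str, search: SearchSpec, train: FeatureTable
) -> tuple[dict, pd.DataFrame]:
    """Cross-validated search for the candidate with minimum mean CV RMSE.

    Folds are a seeded random partition of the training rows. Returns the
    winning hyperparameter map and the full trial log (one row per candidate
    with per-fold and mean RMSE).
    """
    space = search.space if search.space is not None else default_search_space(name)
    if not space:
        raise ConfigError("empty search space")
    if len(train) < search.k_folds:
        raise ConfigError(f"need at least k_folds={search.k_folds} rows, got {len(train)}")
    if search.strategy == "grid":
        candidates = list(ParameterGrid(space))
    else:
        n_grid = math.prod(len(v) for v in space.values()) if all(
            isinstance(v, (list, tuple)) for v in space.values()
        ) else None
        n_iter = min(search.n_iter, n_grid) if n_grid is not None else search.n_iter
        candidates = list(ParameterSampler(space, n_iter=n_iter, random_state=search.seed))

    X = train.X.to_numpy(dtype=float)
    y = train.y.to_numpy(dtype=float)
    kf = KFold(n_splits=search.k_folds, shuffle=True, random_state=search.seed)
    folds = list(kf.split(X))

    records = []
    for params in candidates:
        fold_rmse = []
        for tr_idx, va_idx in folds:
            est = _estimator(name, dict(params), search.seed)
            est.fit(X[tr_idx], y[tr_idx])
            pred = est.predict(X[va_idx])
            fold_rmse.append(float(np.sqrt(np.mean((y[va_idx] - pred) ** 2))))
        rec = {"params": dict(params), "mean_rmse": float(np.mean(fold_rmse))}
        rec.update({f"fold{i}_rmse": r for i, r in enumerate(fold_rmse)})
        records.append(rec)
    log = pd.DataFrame(records)
    best = records[int(np.argmin([r["mean_rmse"] for r in records]))]["params"]
    return dict(best), log
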