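"""Model-agnostic Shapley-value interpretation and importance-driven ablation.

Implements Kernel SHAP: coalitions of features are enumerated size-by-size
while the sampling budget allows full enumeration (smallest and largest
coalitions first, where the Shapley kernel puts most weight) and sampled
thereafter; missing features are integrated out over a background sample and
attributions come from a weighted least-squares solve with the efficiency
constraint enforced exactly, so local accuracy (base value + contributions =
prediction) holds to solver precision.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .evaluate import compute_metrics
from .features import FeatureTable, apply_normalizer, fit_normalizer, temporal_split
from .synthdata import WEATHER_VARIABLES

_WEATHER_RE = re.compile(rf"^({'|'.join(WEATHER_VARIABLES)})_(\d+)$")


@dataclass
class ShapMatrix:
    """Per-instance, per-feature contributions (t/ha) plus the base value."""

    values: np.ndarray  # (n_instances, n_features)
    base_value: float
    feature_names: list[str]
    predictions: np.ndarray  # (n_instances,)
    n_background: int
    budget: int

    def local_accuracy_gap(self) -> np.ndarray:
        return self.predictions - (self.base_value + self.values.sum(axis=1))


def _kernel_masks(m: int, budget: int, rng: np.random.Generator):
    """Coalition masks and Shapley-kernel weights.

    Returns (Z, w) with Z a (n_masks, m) boolean matrix (never all-true or
    all-false) and w the regression weights. Sizes are enumerated completely
    while the budget allows (each enumerated size claims its exact share of
    the kernel weight); the remaining budget is filled with subsets sampled
    by size proportionally to the leftover kernel mass.
    """
    if m < 2:
        raise ConfigError("need at least 2 features for Kernel SHAP")
    sizes = np.arange(1, m)
    raw = (m - 1) / (sizes * (m - sizes))
    kernel = raw / raw.sum()  # weight mass per coalition size

    masks: list[np.ndarray] = []
    weights: list[float] = []
    remaining_mass = 1.0
    budget_left = budget
    done = np.zeros(m - 1, dtype=bool)

    # pair sizes (s, m-s), smallest first
    order: list[tuple[int, ...]] = []
    for s in range(1, m // 2 + 1):
        pair = (s,) if 2 * s == m else (s, m - s)
        order.append(pair)

    for pair in order:
        count = sum(math.comb(m, s) for s in pair)
        if count > budget_left:
            break
        mass = sum(kernel[s - 1] for s in pair)
        for s in pair:
            for comb in itertools.combinations(range(m), s):
                z = np.zeros(m, dtype=bool)
                z[list(comb)] = True
                masks.append(z)
                weights.append(mass / count)
        remaining_mass -= mass
        budget_left -= count
        for s in pair:
            done[s - 1] = True

    open_sizes = sizes[~done]
    if budget_left > 0 and open_sizes.size > 0 and remaining_mass > 1e-12:
        p = kernel[~done]
        p = p / p.sum()
        draw_sizes = rng.choice(open_sizes, size=budget_left, p=p)
        for s in draw_sizes:
            comb = rng.choice(m, size=int(s), replace=False)
            z = np.zeros(m, dtype=bool)
            z[comb] = True
            masks.append(z)
            weights.append(remaining_mass / budget_left)

    return np.array(masks), np.asarray(weights, dtype=float)


def shap_values(
    predict_fn,
    background: pd.DataFrame,
    instances: pd.DataFrame,
    budget: int | None = None,
    seed: int = 0,
    chunk: int = 200_000,
) -> ShapMatrix:
    """Kernel SHAP attributions for each row of ``instances``.

    ``predict_fn`` maps a DataFrame with the same columns to a prediction
    vector; ``background`` supplies the reference distribution over which
    masked-out features are averaged. ``budget`` is the number of coalitions
    evaluated per instance (default ``2 * n_features``).
    """
    if list(background.columns) != list(instances.columns):
        raise SchemaError("background and instances must share the model schema")
    cols = list(instances.columns)
    m = len(cols)
    if budget is None:
        budget = 2 * m
    budget = min(budget, 2**m - 2) if m < 24 else budget
    rng = np.random.default_rng(seed)

    B = background.to_numpy(dtype=float)
    X = instances.to_numpy(dtype=float)
    k = B.shape[0]

    base = float(np.mean(predict_fn(background)))
    fx = np.asarray(predict_fn(instances), dtype=float)

    Z, w = _kernel_masks(m, budget, rng)
    nm = Z.shape[0]
    sqrt_w = np.sqrt(w)

    # design for constrained WLS (efficiency enforced by eliminating the last
    # feature): rows scaled by sqrt(weight)
    Zf = Z.astype(float)
    A = (Zf[:, :-1] - Zf[:, [-1]]) * sqrt_w[:, None]

    values = np.empty((X.shape[0], m))
    for i in range(X.shape[0]):
        x = X[i]
        hyb = np.where(Z[:, None, :], x[None, None, :], B[None, :, :]).reshape(nm * k, m)
        preds = np.empty(nm * k)
        for lo in range(0, nm * k, chunk):
            part = pd.DataFrame(hyb[lo : lo + chunk], columns=cols)
            preds[lo : lo + chunk] = predict_fn(part)
        ey = preds.reshape(nm, k).mean(axis=1) - base
        t = (ey - Zf[:, -1] * (fx[i] - base)) * sqrt_w
        phi_rest, *_ = np.linalg.lstsq(A, t, rcond=None)
        phi_last = (fx[i] - base) - phi_rest.sum()
        values[i] = np.concatenate([phi_rest, [phi_last]])

    return ShapMatrix(
        values=values,
        base_value=base,
        feature_names=cols,
        predictions=fx,
        n_background=k,
        budget=int(nm),
    )


def global_importance(shap: ShapMatrix, features: pd.DataFrame) -> pd.DataFrame:
    """Mean |contribution| per feature with a correlation-based sign and rank.

    Rank 1 is the most important feature; ranks are a permutation of
    1..n_features (ties broken by column order).
    """
    if shap.values.size == 0:
        raise ConfigError("empty contribution matrix")
    if list(features.columns) != shap.feature_names:
        raise SchemaError("feature frame does not match the contribution matrix")
    imp = np.abs(shap.values).mean(axis=0)
    signs = np.empty(len(imp))
    fvals = features.to_numpy(dtype=float)
    for j in range(len(imp)):
        fj, cj = fvals[:, j], shap.values[:, j]
        if np.std(fj) == 0 or np.std(cj) == 0:
            signs[j] = 0.0
        else:
            signs[j] = np.sign(np.corrcoef(fj, cj)[0, 1])
    order = np.argsort(-imp, kind="stable")
    rank = np.empty(len(imp), dtype=int)
    rank[order] = np.arange(1, len(imp) + 1)
    return pd.DataFrame(
        {"feature": shap.feature_names, "importance": imp, "sign": signs, "rank": rank}
    )


def top_features(importance: pd.DataFrame, fraction: float) -> list[str]:
    """Top ``ceil(fraction * n)`` features by rank (fraction in (0, 1])."""
    if not (0.0 < fraction <= 1.0):
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = math.ceil(fraction * len(importance))
    kept = importance.sort_values("rank").head(n_keep)
    return kept["feature"].tolist()


def force_data(shap: ShapMatrix, actual: np.ndarray, selector: str) -> dict:
    """Signed contribution breakdown for the min/median/max-yield instance.

    With an even number of instances the median is the lower of the two
    middle yields. Contributions are sorted by magnitude, descending.
    """
    actual = np.asarray(actual, dtype=float)
    if actual.size == 0:
        raise ConfigError("empty instance set")
    if actual.size != shap.values.shape[0]:
        raise SchemaError("actual yields do not align with explained instances")
    order = np.argsort(actual, kind="stable")
    if selector == "min":
        idx = order[0]
    elif selector == "max":
        idx = order[-1]
    elif selector == "median":
        idx = order[(actual.size - 1) // 2]  # lower-middle on even counts
    else:
        raise ConfigError(f"selector must be min/median/max, got {selector!r}")
    contrib = shap.values[idx]
    sort = np.argsort(-np.abs(contrib), kind="stable")
    rows = pd.DataFrame(
        {
            "feature": [shap.feature_names[j] for j in sort],
            "contribution": contrib[sort],
            "direction": np.where(contrib[sort] >= 0, "positive", "negative"),
        }
    )
    return {
        "selector": selector,
        "instance_index": int(idx),
        "actual_yield": float(actual[idx]),
        "base_value": shap.base_value,
        "output_value": float(shap.predictions[idx]),
        "contributions": rows,
    }


def weather_feature_names(columns: list[str]) -> list[str]:
    return [c for c in columns if _WEATHER_RE.match(c)]


def weekly_weather_profile(shap: ShapMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Mean |contribution| per (variable, week), normalized to percent.

    Cells sum to 100 over all weather features; the per-variable totals are
    the row sums of the grid (so they also sum to 100).
    """
    entries = []
    for j, name in enumerate(shap.feature_names):
        mobj = _WEATHER_RE.match(name)
        if mobj:
            entries.append((mobj.group(1), int(mobj.group(2)), np.abs(shap.values[:, j]).mean()))
    if not entries:
        raise ConfigError("no weather columns (<Variable>_<week>) found")
    df = pd.DataFrame(entries, columns=["variable", "week", "importance"])
    grid = df.pivot(index="variable", columns="week", values="importance")
    grid = grid.reindex([v for v in WEATHER_VARIABLES if v in grid.index])
    total = grid.to_numpy().sum()
    if total > 0:
        grid = grid * (100.0 / total)
    else:
        grid[:] = 100.0 / grid.size
    totals = grid.sum(axis=1)
    return grid, totals


def mask_columns(table: FeatureTable, keep: list[str]) -> FeatureTable:
    """Zero out all columns not in ``keep`` (schema and shape preserved).

    On standardized features zeroing equals mean-imputation, which lets
    structured models (the CNN's weather grid) consume reduced feature sets
    without reshaping.
    """
    missing = [c for c in keep if c not in table.X.columns]
    if missing:
        raise SchemaError(f"unknown columns in keep list: {missing[:5]}")
    X = table.X.copy()
    drop = [c for c in X.columns if c not in set(keep)]
    X[drop] = 0.0
    return FeatureTable(X=X, y=table.y.copy(), keys=table.keys.copy())


def ablation_retrain(
    model_builder,
    table: FeatureTable,
    importance: pd.DataFrame,
    test_years: list[int],
    fractions: tuple[float, ...] = (1.0, 0.75, 0.5),
    include_weather_only: bool = True,
) -> pd.DataFrame:
    """Importance-ranked feature-selection ablation grid.

    For each feature subset (full, top fractions by Shapley rank, and
    weather-only) and each test year, the model is retrained on the masked
    training partition and evaluated on train and test. ``model_builder``
    maps a (normalized) training FeatureTable to a fitted predictor.
    """
    cols = set(table.columns)
    known = set(importance["feature"])
    if cols - known:
        raise ConfigError(f"importance table does not cover columns: {sorted(cols - known)[:5]}")

    subsets: list[tuple[str, list[str]]] = []
    for frac in fractions:
        keep = top_features(importance, frac)
        label = "full" if frac == 1.0 else f"top_{int(round(frac * 100))}"
        subsets.append((label, keep))
    if include_weather_only:
        subsets.append(("weather_only", weather_feature_names(table.columns)))

    rows = []
    for year in test_years:
        train_raw, test_raw = temporal_split(table, year)
        params = fit_normalizer(train_raw)
        train = apply_normalizer(train_raw, params)
        test = apply_normalizer(test_raw, params)
        for label, keep in subsets:
            tr = mask_columns(train, keep)
            te = mask_columns(test, keep)
            fitted = model_builder(tr)
            for split, ft in (("train", tr), ("test", te)):
                res = compute_metrics(ft.y.to_numpy(), fitted.predict(ft))
                rows.append(
                    {
                        "subset": label,
                        "n_features": len(keep),
                        "test_year": year,
                        "split": split,
                        "rmse": res.rmse,
                        "mae": res.mae,
                        "r": res.r,
                    }
                )
    return pd.DataFrame(rows)


def table_predict_fn(model, template: FeatureTable):
    """Adapt a ``predict(FeatureTable)`` model to a DataFrame prediction fn."""
    def fn(frame: pd.DataFrame) -> np.ndarray:
        ft = FeatureTable(
            X=frame.reset_index(drop=True),
            y=pd.Series(np.nan, index=range(len(frame))),
            keys=pd.DataFrame(
                {"county_id": ["?"] * len(frame), "year": [0] * len(frame)}
            ),
        )
        return model.predict(ft)

    return fn
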