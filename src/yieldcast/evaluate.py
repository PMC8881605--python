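"""Evaluation metrics, residual normality tests and the benchmark harness.

The correlation metric ``r`` follows the printed definition
``sqrt(1 - SSE/SST)`` (the square root of the coefficient of determination),
which differs from Pearson correlation; both are reported under distinct
names. When SST = 0 or SSE > SST the printed definition is undefined and is
flagged rather than returned as a complex/NaN surprise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .features import FeatureTable, apply_normalizer, fit_normalizer, temporal_split

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    mae: float
    rmse: float
    r: float  # sqrt(1 - SSE/SST); NaN when undefined
    r_defined: bool
    pearson_r: float
    n: int
    residuals: np.ndarray = field(repr=False)
    percentage_errors: np.ndarray | None = field(default=None, repr=False)


def compute_metrics(actual, predicted) -> EvaluationResult:
    """MAE, RMSE and the root-of-R2 correlation metric.

    Raises on empty or length-mismatched inputs. ``r`` is flagged undefined
    (NaN, ``r_defined=False``) when the actuals are constant (SST = 0) or the
    model underperforms the mean predictor (negative radicand).
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ConfigError(f"length mismatch: actual {a.shape} vs predicted {p.shape}")
    if a.size == 0:
        raise ConfigError("empty input vectors")
    resid = a - p
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid**2).mean()))
    sse = float((resid**2).sum())
    sst = float(((a - a.mean()) ** 2).sum())
    if sst == 0.0 or sse > sst:
        r, r_defined = float("nan"), False
        logger.warning("r undefined: SST=%g SSE=%g", sst, sse)
    else:
        r, r_defined = math.sqrt(1.0 - sse / sst), True
    if a.size >= 2 and np.std(a) > 0 and np.std(p) > 0:
        pearson = float(np.corrcoef(a, p)[0, 1])
    else:
        pearson = float("nan")
    return EvaluationResult(
        mae=mae, rmse=rmse, r=r, r_defined=r_defined, pearson_r=pearson, n=int(a.size), residuals=resid
    )


def percentage_error(actual, predicted) -> np.ndarray:
    """Element-wise |(A - P)/A| * 100; NaN flags elements with A = 0."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ConfigError(f"length mismatch: actual {a.shape} vs predicted {p.shape}")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        pe = np.abs((a - p) / a) * 100.0
    pe[a == 0.0] = np.nan
    return pe


def _anderson_darling_normal(x: np.ndarray) -> tuple[float, float]:
    """Anderson-Darling statistic for normality (estimated parameters) and its
    p-value via the small-sample-corrected approximation of D'Agostino &
    Stephens (1986, Table 4.9)."""
    n = x.size
    with warnings.catch_warnings():
        # scipy >= 1.17 emits a FutureWarning steering towards its own
        # p-value methods; we only need the statistic here
        warnings.simplefilter("ignore", FutureWarning)
        a2 = float(stats.anderson(x, dist="norm").statistic)
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star >= 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return a2, min(max(p, 0.0), 1.0)


def residual_normality(residuals, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk and Anderson-Darling normality tests on residuals.

    Returns per-test statistic, p-value and the decision at ``alpha``.
    Requires n >= 8 and a non-constant vector.
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < 8:
        raise ConfigError(f"need at least 8 residuals, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ConfigError("constant residual vector")
    sw_stat, sw_p = stats.shapiro(x)
    ad_stat, ad_p = _anderson_darling_normal(x)
    return {
        "shapiro_wilk": {"statistic": float(sw_stat), "p_value": float(sw_p), "normal": sw_p > alpha},
        "anderson_darling": {"statistic": ad_stat, "p_value": ad_p, "normal": ad_p > alpha},
        "alpha": alpha,
        "n": int(x.size),
    }


def evaluate_split(model, train: FeatureTable, test: FeatureTable) -> dict[str, EvaluationResult]:
    """Train/test metrics for a fitted model exposing ``predict(FeatureTable)``."""
    out = {}
    for split, ft in (("train", train), ("test", test)):
        pred = model.predict(ft)
        res = compute_metrics(ft.y.to_numpy(), pred)
        res.percentage_errors = percentage_error(ft.y.to_numpy(), pred)
        out[split] = res
    return out


def benchmark(
    model_builders: dict,
    table: FeatureTable,
    test_years: list[int],
) -> pd.DataFrame:
    """Year-wise hold-out benchmark grid.

    ``model_builders`` maps model name -> callable(train: FeatureTable) that
    returns a fitted object with ``predict(FeatureTable) -> ndarray``. For each
    test year every model is trained on all strictly earlier years (normalized
    with train-only parameters) and evaluated on train and test partitions.
    """
    present = set(int(y) for y in table.years)
    missing = [y for y in test_years if y not in present]
    if missing:
        raise ConfigError(f"test year(s) {missing} absent from table")
    rows = []
    for year in test_years:
        train_raw, test_raw = temporal_split(table, year)
        params = fit_normalizer(train_raw)
        train = apply_normalizer(train_raw, params)
        test = apply_normalizer(test_raw, params)
        for name, builder in model_builders.items():
            fitted = builder(train)
            metrics = evaluate_split(fitted, train, test)
            for split, res in metrics.items():
                rows.append(
                    {
                        "model": name,
                        "test_year": year,
                        "split": split,
                        "rmse": res.rmse,
                        "mae": res.mae,
                        "r": res.r,
                        "pearson_r": res.pearson_r,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)
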