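"""Feature assembly, z-score standardization and year-wise temporal splits.

The model-ready table has ``6 * n_weeks`` weekly weather columns named
``<Variable>_<week>`` (variable-major), followed by the seven static
columns ``SowingDOY, FloweringDOY, HarvestDOY, LL, DUL, SAT, BD`` —
277 columns at the default 45-week season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .synthdata import STATIC_COLUMNS, PanelTable, weather_columns

logger = logging.getLogger(__name__)


def aggregate_daily_to_weekly(daily: np.ndarray) -> np.ndarray:
    """Weekly means of a daily series.

    Week k averages days ``7(k-1)+1 .. 7k``; a trailing partial week of at
    least one day is averaged over its actual length (365 days -> 52 weeks
    with an 8-day final week).
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 1 or daily.size == 0:
        raise ConfigError("daily series must be a non-empty 1-D vector")
    n_weeks = daily.size // 7
    if n_weeks == 0:
        return np.array([daily.mean()])
    weekly = daily[: 7 * n_weeks].reshape(n_weeks, 7).mean(axis=1)
    if daily.size % 7:
        # fold leftover days into the final week (365 days -> 52 weeks, the
        # 52nd averaging 8 days) so no observation is discarded
        weekly[-1] = daily[7 * (n_weeks - 1) :].mean()
    return weekly


@dataclass
class FeatureTable:
    """Flattened model-ready matrix with aligned target and row keys."""

    X: pd.DataFrame
    y: pd.Series
    keys: pd.DataFrame  # columns: county_id, year

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.keys)):
            raise SchemaError("X, y and keys must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def years(self) -> np.ndarray:
        return self.keys["year"].to_numpy()

    def select_rows(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            X=self.X.loc[mask].reset_index(drop=True),
            y=self.y.loc[mask].reset_index(drop=True),
            keys=self.keys.loc[mask].reset_index(drop=True),
        )

    def select_columns(self, names: list[str]) -> "FeatureTable":
        missing = [c for c in names if c not in self.X.columns]
        if missing:
            raise SchemaError(f"unknown columns: {missing[:5]}")
        return FeatureTable(X=self.X[names].copy(), y=self.y.copy(), keys=self.keys.copy())

    def sorted_by_key(self) -> "FeatureTable":
        order = self.keys.sort_values(["county_id", "year"]).index.to_numpy()
        return FeatureTable(
            X=self.X.iloc[order].reset_index(drop=True),
            y=self.y.iloc[order].reset_index(drop=True),
            keys=self.keys.iloc[order].reset_index(drop=True),
        )

    def to_csv(self, path) -> None:
        out = pd.concat([self.keys, self.X, self.y.rename("Yield")], axis=1)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path)
        keys = frame[["county_id", "year"]]
        y = frame["Yield"]
        X = frame.drop(columns=["county_id", "year", "Yield"])
        return cls(X=X, y=y, keys=keys)


def feature_column_order(n_weeks: int) -> list[str]:
    """Fixed, documented column order: weather (variable-major) then statics."""
    return weather_columns(n_weeks) + list(STATIC_COLUMNS)


def assemble_feature_table(panel: PanelTable) -> FeatureTable:
    """Flatten a panel into the fixed-order feature matrix (277 cols at 45 weeks)."""
    if len(panel) == 0:
        raise SchemaError("cannot assemble features from an empty panel")
    cols = feature_column_order(panel.n_weeks)
    missing = [c for c in cols if c not in panel.frame.columns]
    if missing:
        raise SchemaError(f"panel missing feature columns: {missing[:5]}")
    X = panel.frame[cols].astype(float).reset_index(drop=True)
    bad = ~np.isfinite(X.to_numpy()).all(axis=1)
    if bad.any():
        key = panel.frame.iloc[int(np.flatnonzero(bad)[0])]
        raise SchemaError(
            f"non-finite feature values in row (county_id={key['county_id']}, year={key['year']})"
        )
    y = panel.frame["Yield"].astype(float).reset_index(drop=True) if "Yield" in panel.frame else pd.Series(np.nan, index=X.index)
    keys = panel.frame[["county_id", "year"]].reset_index(drop=True)
    return FeatureTable(X=X, y=y, keys=keys)


@dataclass
class NormalizationParams:
    """Per-feature mean/SD fitted on training rows (population SD by default)."""

    mean: pd.Series
    std: pd.Series
    fitted_on: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def columns(self) -> list[str]:
        return list(self.mean.index)


def fit_normalizer(train: FeatureTable, ddof: int = 0) -> NormalizationParams:
    """Column means and SDs over training rows only.

    ``ddof=0`` (population SD) matches the plain z-score definition;
    set ``ddof=1`` for the sample SD.
    """
    if len(train) == 0:
        raise SchemaError("cannot fit normalizer on an empty table")
    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0, ddof=ddof).fillna(0.0)
    return NormalizationParams(mean=mean, std=std, fitted_on=train.keys.copy())


def apply_normalizer(table: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """z-score each column with the fitted (mean, SD); sigma=0 columns map to 0."""
    cols = list(table.X.columns)
    if cols != params.columns:
        missing = sorted(set(params.columns) - set(cols))
        extra = sorted(set(cols) - set(params.columns))
        raise SchemaError(f"column mismatch: missing={missing[:5]} extra={extra[:5]}")
    std = params.std.to_numpy(dtype=float)
    zero = std == 0.0
    if zero.any():
        logger.warning(
            "%d constant column(s) (sigma=0) mapped to 0: %s",
            int(zero.sum()),
            [c for c, z in zip(cols, zero) if z][:5],
        )
    safe_std = np.where(zero, 1.0, std)
    Xs = (table.X.to_numpy(dtype=float) - params.mean.to_numpy(dtype=float)) / safe_std
    Xs[:, zero] = 0.0
    return FeatureTable(
        X=pd.DataFrame(Xs, columns=cols),
        y=table.y.reset_index(drop=True),
        keys=table.keys.reset_index(drop=True),
    )


def invert_normalizer(table: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """Inverse of :func:`apply_normalizer` for sigma > 0 columns."""
    X = table.X.to_numpy(dtype=float) * params.std.to_numpy(dtype=float) + params.mean.to_numpy(
        dtype=float
    )
    return FeatureTable(
        X=pd.DataFrame(X, columns=list(table.X.columns)),
        y=table.y.reset_index(drop=True),
        keys=table.keys.reset_index(drop=True),
    )


def temporal_split(table: FeatureTable, test_year: int) -> tuple[FeatureTable, FeatureTable]:
    """Non-random year-wise hold-out: train on years strictly before ``test_year``.

    Rows with year > test_year are excluded from both partitions.
    """
    years = table.years
    if test_year not in years:
        raise ConfigError(f"test_year {test_year} not present in table (years {sorted(set(years))})")
    train_mask = years < test_year
    if not train_mask.any():
        raise ConfigError(f"test_year {test_year} leaves an empty training partition")
    train = table.select_rows(train_mask)
    test = table.select_rows(years == test_year)
    return train, test
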