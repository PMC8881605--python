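"""Synthetic county-year panel generator.

Produces panels with the statistical structure of a German county-level
winter-wheat dataset: six weekly weather series per growing season,
four static soil properties, three phenology dates, and a yield target
driven by a documented, queryable ground-truth response.

Week indices are season-relative: week 1 is the first week after sowing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Canonical ordering of the six weekly weather variables.
WEATHER_VARIABLES: tuple[str, ...] = (
    "Wind",
    "TempMin",
    "TempMax",
    "Humidity",
    "Precipitation",
    "Radiation",
)

#: Static (non-weekly) columns, in canonical order.
PHENOLOGY_COLUMNS: tuple[str, ...] = ("SowingDOY", "FloweringDOY", "HarvestDOY")
SOIL_COLUMNS: tuple[str, ...] = ("LL", "DUL", "SAT", "BD")
STATIC_COLUMNS: tuple[str, ...] = PHENOLOGY_COLUMNS + SOIL_COLUMNS


@dataclass(frozen=True)
class WeatherParams:
    """Generative parameters for one weekly weather variable.

    The weekly value for county c, year t, week w is

        seasonal(w) + county_effect_c + year_anomaly_{c,t} + e_w

    where ``seasonal(w) = mean + amplitude * sin(2*pi*(w + phase_weeks)/52)``
    and ``e_w`` follows an AR(1) process with coefficient ``ar_coef`` and
    innovation SD ``innovation_sd`` (stationary initialisation).
    """

    mean: float
    amplitude: float
    phase_weeks: float
    county_sd: float
    year_sd: float
    ar_coef: float
    innovation_sd: float
    nonnegative: bool = False

    def seasonal(self, weeks: np.ndarray) -> np.ndarray:
        return self.mean + self.amplitude * np.sin(
            2.0 * np.pi * (weeks + self.phase_weeks) / 52.0
        )

    def stationary_sd(self) -> float:
        return self.innovation_sd / math.sqrt(1.0 - self.ar_coef**2)


DEFAULT_WEATHER_PARAMS: dict[str, WeatherParams] = {
    "Wind": WeatherParams(3.6, 0.9, 1.0, 0.45, 0.30, 0.45, 0.70),
    "TempMin": WeatherParams(4.5, 7.0, 27.0, 0.80, 0.90, 0.60, 1.10),
    "TempMax": WeatherParams(12.0, 9.0, 27.0, 0.90, 1.00, 0.60, 1.30),
    "Humidity": WeatherParams(78.0, 8.0, 1.0, 2.50, 2.00, 0.50, 3.00),
    "Precipitation": WeatherParams(13.0, 4.0, 1.0, 2.50, 2.00, 0.30, 5.00, nonnegative=True),
    "Radiation": WeatherParams(85.0, 65.0, 27.0, 6.00, 7.00, 0.55, 10.00, nonnegative=True),
}


@dataclass(frozen=True)
class Driver:
    """One ground-truth yield driver over a weekly window of a weather variable.

    The driver contributes ``weight * g((m - center)/scale)`` where ``m`` is the
    mean of the variable over ``window`` (inclusive week range) and ``g`` is the
    identity for ``transform='linear'`` or ``u**2 - 1`` for ``transform='square'``
    (centred so the expected contribution is near zero).
    """

    variable: str
    window: tuple[int, int]
    weight: float
    transform: str = "linear"
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.variable not in WEATHER_VARIABLES:
            raise ConfigError(f"driver.variable: unknown weather variable {self.variable!r}")
        if self.transform not in ("linear", "square"):
            raise ConfigError(f"driver.transform: must be 'linear' or 'square', got {self.transform!r}")
        if self.scale <= 0:
            raise ConfigError("driver.scale: must be > 0")

    def evaluate(self, window_mean: np.ndarray | float) -> np.ndarray | float:
        u = (np.asarray(window_mean, dtype=float) - self.center) / self.scale
        if self.transform == "square":
            g = u**2 - 1.0
        else:
            g = u
        return self.weight * g


@dataclass(frozen=True)
class YieldTruth:
    """Ground-truth yield response (t/ha).

    yield = baseline + sum(driver terms) - dul_penalty * max(0, dul_breakpoint - DUL)
            + county_effect + year_trend * (year - first_year) + N(0, noise_sd)
    """

    baseline_yield: float = 7.2
    drivers: tuple[Driver, ...] = ()
    dul_breakpoint: float = 0.27
    dul_penalty: float = 8.0
    county_effect_sd: float = 0.25
    year_trend: float = 0.02
    noise_sd: float = 0.20

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("yield_params.noise_sd: must be >= 0")
        if self.county_effect_sd < 0:
            raise ConfigError("yield_params.county_effect_sd: must be >= 0")

    def driver_features(self) -> tuple[str, ...]:
        """Feature names with a nonzero partial effect on the noiseless response."""
        names: list[str] = []
        for d in self.drivers:
            if d.weight != 0.0:
                names.extend(f"{d.variable}_{w}" for w in range(d.window[0], d.window[1] + 1))
        if self.dul_penalty != 0.0:
            names.append("DUL")
        return tuple(dict.fromkeys(names))

    def validate_windows(self, n_weeks: int) -> None:
        for d in self.drivers:
            lo, hi = d.window
            if not (1 <= lo <= hi <= n_weeks):
                raise ConfigError(
                    f"driver window {d.window} for {d.variable!r} outside [1, {n_weeks}]"
                )


def default_yield_truth(
    weather_params: Mapping[str, WeatherParams] | None = None,
) -> YieldTruth:
    """Default truth with linear and nonlinear weekly drivers plus the DUL hinge.

    Centers/scales are derived from the generative weather parameters so the
    standardized driver inputs are roughly unit-scale.
    """
    wp = dict(weather_params or DEFAULT_WEATHER_PARAMS)

    def center(var: str, lo: int, hi: int) -> float:
        p = wp[var]
        return float(np.mean(p.seasonal(np.arange(lo, hi + 1, dtype=float))))

    def scale(var: str, lo: int, hi: int) -> float:
        p = wp[var]
        n = hi - lo + 1
        # window mean of county + year + AR noise; AR part shrinks ~1/sqrt(n)
        return math.sqrt(p.county_sd**2 + p.year_sd**2 + p.stationary_sd() ** 2 / n)

    def mk(var: str, lo: int, hi: int, weight: float, transform: str) -> Driver:
        return Driver(var, (lo, hi), weight, transform, center(var, lo, hi), scale(var, lo, hi))

    drivers = (
        mk("Radiation", 6, 8, -0.40, "square"),
        mk("TempMin", 2, 4, 0.35, "square"),
        mk("Wind", 9, 11, -0.45, "linear"),
        mk("TempMax", 7, 9, 0.45, "linear"),
        mk("Precipitation", 30, 32, 0.40, "linear"),
    )
    return YieldTruth(drivers=drivers, dul_penalty=10.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic panel generator."""

    n_counties: int = 271
    first_year: int = 1999
    last_year: int = 2019
    n_weeks: int = 45
    weather_params: Mapping[str, WeatherParams] = field(
        default_factory=lambda: dict(DEFAULT_WEATHER_PARAMS)
    )
    ll_range: tuple[float, float] = (0.05, 0.15)
    dul_range: tuple[float, float] = (0.18, 0.40)
    sat_range: tuple[float, float] = (0.42, 0.55)
    bd_range: tuple[float, float] = (1.10, 1.70)
    sowing_mean: float = 290.0
    sowing_sd: float = 7.0
    flowering_mean: float = 155.0
    flowering_sd: float = 5.0
    harvest_mean: float = 210.0
    harvest_sd: float = 5.0
    truth: YieldTruth | None = None
    seed: int = 0

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    def resolved_truth(self) -> YieldTruth:
        return self.truth if self.truth is not None else default_yield_truth(self.weather_params)

    def validate(self) -> None:
        if self.n_counties < 1:
            raise ConfigError("n_counties: must be >= 1")
        if self.n_weeks < 1:
            raise ConfigError("n_weeks: must be >= 1")
        if self.last_year < self.first_year:
            raise ConfigError("last_year: must be >= first_year")
        for name in WEATHER_VARIABLES:
            if name not in self.weather_params:
                raise ConfigError(f"weather_params: missing variable {name!r}")
            p = self.weather_params[name]
            if not (-1.0 < p.ar_coef < 1.0):
                raise ConfigError(f"weather_params[{name!r}].ar_coef: must be in (-1, 1)")
            if p.innovation_sd < 0 or p.county_sd < 0 or p.year_sd < 0:
                raise ConfigError(f"weather_params[{name!r}]: SDs must be >= 0")
        for rname, rng_ in (
            ("ll_range", self.ll_range),
            ("dul_range", self.dul_range),
            ("sat_range", self.sat_range),
            ("bd_range", self.bd_range),
        ):
            if rng_[0] > rng_[1]:
                raise ConfigError(f"{rname}: lower bound exceeds upper bound")
        if self.ll_range[1] >= self.dul_range[0]:
            raise ConfigError("dul_range: must lie strictly above ll_range so LL < DUL")
        if self.dul_range[1] >= self.sat_range[0]:
            raise ConfigError("sat_range: must lie strictly above dul_range so DUL < SAT")
        if self.bd_range[0] <= 0:
            raise ConfigError("bd_range: BD must be > 0")
        self.resolved_truth().validate_windows(self.n_weeks)


def weather_column(variable: str, week: int) -> str:
    return f"{variable}_{week}"


def weather_columns(n_weeks: int) -> list[str]:
    return [weather_column(v, w) for v in WEATHER_VARIABLES for w in range(1, n_weeks + 1)]


@dataclass
class PanelTable:
    """County-year panel: weather series, soil, phenology and yield per row.

    Backed by a DataFrame with columns ``county_id, year`` followed by the
    weather columns (variable-major, ``<Variable>_<week>``), the static
    columns and ``Yield``.
    """

    frame: pd.DataFrame
    n_weeks: int

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def weather_column_names(self) -> list[str]:
        return weather_columns(self.n_weeks)

    def weather_matrix(self, idx: int) -> np.ndarray:
        """6 x n_weeks weather matrix for row position ``idx``."""
        row = self.frame.iloc[idx]
        return row[self.weather_column_names].to_numpy(dtype=float).reshape(
            len(WEATHER_VARIABLES), self.n_weeks
        )

    def validate(self) -> None:
        f = self.frame
        missing = [c for c in ("county_id", "year", *self.weather_column_names, *STATIC_COLUMNS) if c not in f.columns]
        if missing:
            raise ConfigError(f"panel missing columns: {missing[:5]}")
        if not (f["LL"] < f["DUL"]).all() or not (f["DUL"] < f["SAT"]).all():
            raise ConfigError("soil ordering LL < DUL < SAT violated")
        if not (f["BD"] > 0).all():
            raise ConfigError("BD must be > 0")
        for c in PHENOLOGY_COLUMNS:
            if not f[c].between(1, 366).all():
                raise ConfigError(f"{c} outside [1, 366]")
        if not np.isfinite(f[self.weather_column_names].to_numpy(dtype=float)).all():
            raise ConfigError("non-finite weather values")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelTable":
        frame = pd.read_csv(path)
        weeks = [
            int(c.split("_")[1])
            for c in frame.columns
            if c.startswith(WEATHER_VARIABLES[0] + "_")
        ]
        if not weeks:
            raise ConfigError(f"no weather columns found in {path}")
        return cls(frame=frame, n_weeks=max(weeks))


def yield_response(
    weather: np.ndarray,
    soil: Mapping[str, float],
    phenology: Mapping[str, float],
    truth: YieldTruth,
    noise_draw: float = 0.0,
    county_effect: float = 0.0,
    year_effect: float = 0.0,
) -> float:
    """Ground-truth yield (t/ha) for one county-year.

    ``weather`` is the 6 x n_weeks matrix in canonical variable order;
    ``noise_draw`` is an externally supplied Gaussian draw (pass 0 for the
    deterministic response). Phenology has no effect under the default truth
    but is part of the signature for custom truths.
    """
    weather = np.asarray(weather, dtype=float)
    n_weeks = weather.shape[1]
    truth.validate_windows(n_weeks)
    total = truth.baseline_yield
    for d in truth.drivers:
        vi = WEATHER_VARIABLES.index(d.variable)
        lo, hi = d.window
        m = float(weather[vi, lo - 1 : hi].mean())
        total += float(d.evaluate(m))
    deficit = max(0.0, truth.dul_breakpoint - float(soil["DUL"]))
    total -= truth.dul_penalty * deficit
    return total + county_effect + year_effect + float(noise_draw)


def _generate_weather(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Return array of shape (n_vars, n_counties, n_years, n_weeks)."""
    nv, nc, ny, nw = (
        len(WEATHER_VARIABLES),
        config.n_counties,
        config.n_years,
        config.n_weeks,
    )
    out = np.empty((nv, nc, ny, nw))
    weeks = np.arange(1, nw + 1, dtype=float)
    for vi, name in enumerate(WEATHER_VARIABLES):
        p = config.weather_params[name]
        seasonal = p.seasonal(weeks)
        county = rng.normal(0.0, p.county_sd, size=nc)
        year = rng.normal(0.0, p.year_sd, size=(nc, ny))
        e = np.empty((nc, ny, nw))
        e[..., 0] = rng.normal(0.0, p.stationary_sd(), size=(nc, ny))
        innov = rng.normal(0.0, p.innovation_sd, size=(nc, ny, nw - 1)) if nw > 1 else None
        for w in range(1, nw):
            e[..., w] = p.ar_coef * e[..., w - 1] + innov[..., w - 1]
        series = seasonal[None, None, :] + county[:, None, None] + year[..., None] + e
        if p.nonnegative:
            series = np.clip(series, 0.0, None)
        out[vi] = series
    return out


def generate_panel(config: GeneratorConfig) -> PanelTable:
    """Generate a seeded synthetic county-year panel.

    Regeneration with the same config (including seed) is bit-identical.
    Soil is static per county across years; phenology is jittered per row.
    """
    config.validate()
    truth = config.resolved_truth()
    rng = np.random.default_rng(config.seed)
    nc, ny, nw = config.n_counties, config.n_years, config.n_weeks

    weather = _generate_weather(config, rng)  # (6, nc, ny, nw)

    ll = rng.uniform(*config.ll_range, size=nc)
    dul = rng.uniform(*config.dul_range, size=nc)
    sat = rng.uniform(*config.sat_range, size=nc)
    bd = rng.uniform(*config.bd_range, size=nc)

    sow = np.clip(np.rint(rng.normal(config.sowing_mean, config.sowing_sd, size=(nc, ny))), 1, 366)
    flo = np.clip(np.rint(rng.normal(config.flowering_mean, config.flowering_sd, size=(nc, ny))), 1, 366)
    har = np.clip(np.rint(rng.normal(config.harvest_mean, config.harvest_sd, size=(nc, ny))), 1, 366)

    county_yield_effect = rng.normal(0.0, truth.county_effect_sd, size=nc)
    noise = (
        rng.normal(0.0, truth.noise_sd, size=(nc, ny))
        if truth.noise_sd > 0
        else np.zeros((nc, ny))
    )

    years = np.array(list(config.years))
    records: list[dict] = []
    wcols = weather_columns(nw)
    for ci in range(nc):
        soil = {"LL": ll[ci], "DUL": dul[ci], "SAT": sat[ci], "BD": bd[ci]}
        for yi, year in enumerate(years):
            wmat = weather[:, ci, yi, :]
            phen = {
                "SowingDOY": int(sow[ci, yi]),
                "FloweringDOY": int(flo[ci, yi]),
                "HarvestDOY": int(har[ci, yi]),
            }
            y = yield_response(
                wmat,
                soil,
                phen,
                truth,
                noise_draw=noise[ci, yi],
                county_effect=county_yield_effect[ci],
                year_effect=truth.year_trend * (year - config.first_year),
            )
            rec = {"county_id": f"C{ci + 1:04d}", "year": int(year)}
            rec.update(zip(wcols, wmat.ravel()))
            rec.update(phen)
            rec.update({k: float(v) for k, v in soil.items()})
            rec["Yield"] = y
            records.append(rec)

    frame = pd.DataFrame.from_records(records)
    panel = PanelTable(frame=frame, n_weeks=nw)
    panel.validate()
    return panel


def write_truth_manifest(truth: YieldTruth, path) -> None:
    """Write the ground-truth driver manifest as JSON next to a panel CSV."""
    payload = {
        "baseline_yield": truth.baseline_yield,
        "dul_breakpoint": truth.dul_breakpoint,
        "dul_penalty": truth.dul_penalty,
        "county_effect_sd": truth.county_effect_sd,
        "year_trend": truth.year_trend,
        "noise_sd": truth.noise_sd,
        "drivers": [dataclasses.asdict(d) for d in truth.drivers],
        "driver_features": list(truth.driver_features()),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
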