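"""Config-driven orchestration and command-line interface.

``run_experiment`` executes the full pipeline — generate, assemble,
benchmark, explain, ablate — and writes the tabular artifacts (CSV, UTF-8,
header row) plus a run log recording every default that filled an
unspecified parameter. A master seed deterministically derives the
per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import baselines as bl
from . import cnn as cnn_mod
from . import evaluate as ev
from . import features as ft
from . import interpret as it
from . import synthdata as sd
from .errors import ConfigError

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "generate": 0,
    "cnn": 1,
    "baselines": 2,
    "search": 3,
    "shap": 4,
}


@dataclass
class ShapBudget:
    background_size: int = 50
    n_instances: int = 30
    budget: int | None = None  # None -> 2 * n_features


@dataclass
class ExperimentConfig:
    generator: sd.GeneratorConfig = field(default_factory=sd.GeneratorConfig)
    arch: cnn_mod.CnnArchConfig = field(default_factory=cnn_mod.CnnArchConfig)
    train: cnn_mod.TrainConfig = field(default_factory=cnn_mod.TrainConfig)
    baseline_names: tuple[str, ...] = bl.BASELINE_NAMES
    baseline_hyperparameters: dict = field(default_factory=dict)
    search: bl.SearchSpec | None = None  # None -> no tuning, defaults used
    test_years: tuple[int, ...] = ()
    shap: ShapBudget = field(default_factory=ShapBudget)
    ablation_fractions: tuple[float, ...] = (1.0, 0.75, 0.5)
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, STAGE_SEED_OFFSETS[stage]]).generate_state(1)[0]
            % (2**31)
        )

    def resolved_test_years(self) -> list[int]:
        if self.test_years:
            return list(self.test_years)
        last = self.generator.last_year
        return [last - 2, last - 1, last]

    def validate(self) -> None:
        self.generator.validate()
        if self.test_years:
            self.validate_test_years()
        for name in self.baseline_names:
            if name not in bl.BASELINE_NAMES:
                raise ConfigError(f"baseline_names: unknown model {name!r}")

    def validate_test_years(self) -> None:
        years = set(self.generator.years)
        for y in self.resolved_test_years():
            if y not in years:
                raise ConfigError(f"test_years: {y} outside generated range")
            if y == self.generator.first_year:
                raise ConfigError(f"test_years: {y} leaves no training years")


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Parse a YAML/JSON experiment config; unknown/missing fields error early."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg_kwargs: dict = {}
    if "generator" in raw:
        gen = dict(raw.pop("generator"))
        if "weather_params" in gen:
            gen["weather_params"] = {
                k: sd.WeatherParams(**v) for k, v in gen["weather_params"].items()
            }
        if "truth" in gen:
            tr = dict(gen["truth"])
            if "drivers" in tr:
                tr["drivers"] = tuple(
                    sd.Driver(**{**d, "window": tuple(d["window"])}) for d in tr["drivers"]
                )
            gen["truth"] = YieldTruthFactory(tr)
        cfg_kwargs["generator"] = _build_dataclass(sd.GeneratorConfig, gen, "generator")
    if "arch" in raw:
        cfg_kwargs["arch"] = _build_dataclass(cnn_mod.CnnArchConfig, raw.pop("arch"), "arch")
    if "train" in raw:
        cfg_kwargs["train"] = _build_dataclass(cnn_mod.TrainConfig, raw.pop("train"), "train")
    if "search" in raw:
        search = raw.pop("search")
        cfg_kwargs["search"] = (
            _build_dataclass(bl.SearchSpec, search, "search") if search else None
        )
    if "shap" in raw:
        cfg_kwargs["shap"] = _build_dataclass(ShapBudget, raw.pop("shap"), "shap")
    for key in ("baseline_names", "baseline_hyperparameters", "test_years", "ablation_fractions", "seed"):
        if key in raw:
            value = raw.pop(key)
            if isinstance(value, list):
                value = tuple(value)
            cfg_kwargs[key] = value
    if raw:
        raise ConfigError(f"unknown top-level config field(s): {sorted(raw)}")
    cfg = ExperimentConfig(**cfg_kwargs)
    cfg.validate()
    return cfg


def YieldTruthFactory(data: dict) -> sd.YieldTruth:
    return _build_dataclass(sd.YieldTruth, data, "generator.truth")


def _cnn_builder(config: ExperimentConfig):
    def build(train_table: ft.FeatureTable):
        model = cnn_mod.build_cnn(config.arch, config.generator.n_weeks, n_static=7)
        cfg = dataclasses.replace(config.train, seed=config.stage_seed("cnn"))
        cnn_mod.train_cnn(model, train_table, cfg)
        return model

    return build


def _baseline_builders(config: ExperimentConfig, tuned: dict[str, dict]) -> dict:
    builders = {}
    for name in config.baseline_names:
        params = dict(config.baseline_hyperparameters.get(name, {}))
        params.update(tuned.get(name, {}))
        spec = bl.BaselineSpec(name=name, hyperparameters=params, seed=config.stage_seed("baselines"))

        def build(train_table: ft.FeatureTable, _spec=spec):
            return bl.make_baseline(_spec).fit(train_table)

        builders[name] = build
    return builders


def run_experiment(config: ExperimentConfig, outdir) -> Path:
    """Execute the full pipeline and write all artifacts into ``outdir``."""
    config.validate()
    config.validate_test_years()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config": _config_dict(config)}

    gen_cfg = dataclasses.replace(config.generator, seed=config.stage_seed("generate"))
    truth = gen_cfg.resolved_truth()
    panel = sd.generate_panel(gen_cfg)
    panel.to_csv(out / "panel.csv")
    sd.write_truth_manifest(truth, out / "truth.json")

    table = ft.assemble_feature_table(panel)
    table.to_csv(out / "features.csv")
    run_log["n_rows"] = len(table)
    run_log["n_features"] = len(table.columns)

    test_years = config.resolved_test_years()

    tuned: dict[str, dict] = {}
    if config.search is not None:
        first_train, _ = ft.temporal_split(table, test_years[0])
        norm = ft.fit_normalizer(first_train)
        first_train_n = ft.apply_normalizer(first_train, norm)
        search = dataclasses.replace(config.search, seed=config.stage_seed("search"))
        for name in config.baseline_names:
            best, log = bl.tune_hyperparameters(name, search, first_train_n)
            tuned[name] = best
            log.to_csv(out / f"search_{name}.csv", index=False)
        run_log["tuned_hyperparameters"] = tuned

    builders = _baseline_builders(config, tuned)
    builders["cnn"] = _cnn_builder(config)
    grid = ev.benchmark(builders, table, test_years)
    grid.to_csv(out / "benchmark.csv", index=False)

    # interpretation artifacts use the final test year's hold-out model
    year = test_years[-1]
    train_raw, test_raw = ft.temporal_split(table, year)
    norm = ft.fit_normalizer(train_raw)
    train_n = ft.apply_normalizer(train_raw, norm)
    test_n = ft.apply_normalizer(test_raw, norm)
    model = builders["cnn"](train_n)

    rng = np.random.default_rng(config.stage_seed("shap"))
    bg_idx = rng.choice(len(train_n), size=min(config.shap.background_size, len(train_n)), replace=False)
    inst_idx = rng.choice(len(test_n), size=min(config.shap.n_instances, len(test_n)), replace=False)
    predict_fn = it.table_predict_fn(model, train_n)
    shap = it.shap_values(
        predict_fn,
        train_n.X.iloc[bg_idx].reset_index(drop=True),
        test_n.X.iloc[inst_idx].reset_index(drop=True),
        budget=config.shap.budget,
        seed=config.stage_seed("shap"),
    )
    run_log["shap"] = {
        "background_size": int(len(bg_idx)),
        "n_instances": int(len(inst_idx)),
        "budget": shap.budget,
        "base_value": shap.base_value,
    }

    importance = it.global_importance(shap, test_n.X.iloc[inst_idx].reset_index(drop=True))
    importance.sort_values("rank").to_csv(out / "importance.csv", index=False)

    actual = test_n.y.to_numpy()[inst_idx]
    force_rows = []
    for selector in ("min", "median", "max"):
        fd = it.force_data(shap, actual, selector)
        top = fd["contributions"].head(15).assign(
            selector=selector,
            base_value=fd["base_value"],
            output_value=fd["output_value"],
            actual_yield=fd["actual_yield"],
        )
        force_rows.append(top)
    pd.concat(force_rows, ignore_index=True).to_csv(out / "force.csv", index=False)

    grid_profile, totals = it.weekly_weather_profile(shap)
    profile = grid_profile.reset_index().melt(id_vars="variable", var_name="week", value_name="importance_pct")
    profile.to_csv(out / "weekly_profile.csv", index=False)
    totals.rename("total_pct").to_csv(out / "weekly_totals.csv")

    ablation = it.ablation_retrain(
        builders["cnn"], table, importance, test_years, fractions=config.ablation_fractions
    )
    ablation.to_csv(out / "ablation.csv", index=False)

    with open(out / "run_log.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=False)
    return out


def _config_dict(config: ExperimentConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load_or_default(config_path, seed) -> ExperimentConfig:
    cfg = load_config(config_path) if config_path else ExperimentConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    return cfg


@click.group()
def cli():
    """County-year yield modelling pipeline."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def generate(config_path, seed, outdir):
    """Generate the synthetic panel CSV and ground-truth manifest."""
    cfg = _load_or_default(config_path, seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen_cfg = dataclasses.replace(cfg.generator, seed=cfg.stage_seed("generate"))
    panel = sd.generate_panel(gen_cfg)
    panel.to_csv(out / "panel.csv")
    sd.write_truth_manifest(gen_cfg.resolved_truth(), out / "truth.json")
    click.echo(f"wrote {len(panel)} rows to {out / 'panel.csv'}")


@cli.command("features")
@click.option("--panel", "panel_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def features_cmd(panel_path, out_path):
    """Assemble the model-ready feature table from a panel CSV."""
    panel = sd.PanelTable.from_csv(panel_path)
    table = ft.assemble_feature_table(panel)
    table.to_csv(out_path)
    click.echo(f"wrote {len(table)} rows x {len(table.columns)} features to {out_path}")


@cli.command("train-cnn")
@click.option("--features", "features_path", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--test-year", type=int, required=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def train_cnn_cmd(features_path, config_path, seed, test_year, outdir):
    """Train the CNN under the year-wise hold-out and write the loss history."""
    cfg = _load_or_default(config_path, seed)
    table = ft.FeatureTable.from_csv(features_path)
    train_raw, test_raw = ft.temporal_split(table, test_year)
    norm = ft.fit_normalizer(train_raw)
    train_n = ft.apply_normalizer(train_raw, norm)
    test_n = ft.apply_normalizer(test_raw, norm)
    model = cnn_mod.build_cnn(cfg.arch, n_weeks=_infer_weeks(table), n_static=7)
    tcfg = dataclasses.replace(cfg.train, seed=cfg.stage_seed("cnn"))
    _, history = cnn_mod.train_cnn(model, train_n, tcfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(history).to_csv(out / "cnn_history.csv", index=False)
    metrics = ev.evaluate_split(model, train_n, test_n)
    pd.DataFrame(
        [
            {"split": s, "rmse": m.rmse, "mae": m.mae, "r": m.r, "n": m.n}
            for s, m in metrics.items()
        ]
    ).to_csv(out / "cnn_metrics.csv", index=False)
    click.echo(f"test RMSE {metrics['test'].rmse:.3f} (n={metrics['test'].n})")


def _infer_weeks(table: ft.FeatureTable) -> int:
    weeks = [int(c.split("_")[1]) for c in table.columns if c.startswith("Wind_")]
    if not weeks:
        raise ConfigError("cannot infer n_weeks: no Wind_<week> columns")
    return max(weeks)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.option("--test-years", type=str, default=None, help="comma-separated years")
def benchmark(config_path, seed, outdir, test_years):
    """Run the full model x test-year benchmark grid."""
    cfg = _load_or_default(config_path, seed)
    if test_years:
        cfg = dataclasses.replace(cfg, test_years=tuple(int(y) for y in test_years.split(",")))
    run_experiment(cfg, outdir)
    click.echo(f"artifacts in {outdir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def explain(config_path, seed, outdir):
    """Generate, train the CNN and emit SHAP artifacts (importance, force, profile)."""
    cfg = _load_or_default(config_path, seed)
    cfg = dataclasses.replace(cfg, baseline_names=())
    run_experiment(cfg, outdir)
    click.echo(f"artifacts in {outdir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def ablate(config_path, seed, outdir):
    """Run the importance-driven feature-selection ablation."""
    cfg = _load_or_default(config_path, seed)
    cfg = dataclasses.replace(cfg, baseline_names=())
    run_experiment(cfg, outdir)
    click.echo(f"artifacts in {outdir}")


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def run_all(config_path, seed, outdir):
    """End-to-end pipeline: generate, features, benchmark, explain, ablate."""
    cfg = _load_or_default(config_path, seed)
    run_experiment(cfg, outdir)
    click.echo(f"artifacts in {outdir}")


if __name__ == "__main__":
    cli()
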