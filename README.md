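# yieldcast

County-year winter wheat yield modelling: a multi-branch 1-D convolutional
network over weekly weather series fused with soil/phenology features,
benchmarked against eight classical learners under a year-wise (non-random)
hold-out protocol, with Kernel-SHAP interpretation and importance-driven
feature-selection ablations. All stages run on a seeded synthetic county-year
panel generator with a documented ground-truth yield response, so no external
data is required.

## Layout

| module | what it does |
|---|---|
| `yieldcast.synthdata` | synthetic panel generator: seasonal + AR(1) weekly weather, static soil (LL < DUL < SAT, BD), phenology dates, ground-truth yield response with queryable drivers |
| `yieldcast.features` | daily→weekly aggregation, 277-column feature assembly (`<Variable>_<week>` naming), train-only z-score normalization, temporal train/test split |
| `yieldcast.cnn` | the proposed model: shared 1-D conv branches per weather variable + 2-layer static FC branch + 3-layer FC head; pure-numpy forward/backward with Adam |
| `yieldcast.baselines` | knn, random_forest, xgboost (gradient-boosted trees), lasso, ridge, regression_tree, svr, dnn; cross-validated grid/randomized hyperparameter search |
| `yieldcast.evaluate` | MAE / RMSE / √(1−SSE/SST) correlation metric, per-county percentage error, Shapiro–Wilk + Anderson–Darling residual normality, benchmark harness |
| `yieldcast.interpret` | Kernel SHAP (from scratch), global importance with signs, force-plot data, weekly weather profiles, Shapley-ranked feature-selection ablation |
| `yieldcast.pipeline` | YAML config, end-to-end orchestration, CSV artifacts, CLI |

Note on dependencies: the deep-learning framework, gradient-boosting library
and SHAP package this kind of pipeline usually leans on are deliberately not
required — the CNN and Kernel SHAP are implemented in numpy (deterministic,
CPU-friendly), and the gradient-boosted tree baseline is scikit-learn's
`HistGradientBoostingRegressor`.

## CLI

```sh
yieldcast generate  --seed 1 --out artifacts/            # panel.csv + truth.json
yieldcast features  --panel artifacts/panel.csv --out artifacts/features.csv
yieldcast train-cnn --features artifacts/features.csv --test-year 2019 --out artifacts/
yieldcast run-all   --config experiment.yaml --seed 1 --out artifacts/
```

`run-all` writes: `panel.csv`, `truth.json`, `features.csv`, `benchmark.csv`
(model × test-year grid), `importance.csv`, `force.csv` (min/median/max-yield
instances), `weekly_profile.csv` + `weekly_totals.csv`, `ablation.csv`, and
`run_log.yaml` recording every default used. An example config:

```yaml
generator: {n_counties: 80, first_year: 2000, last_year: 2011}
train: {epochs: 50, batch_size: 128, learning_rate: 0.002}
test_years: [2009, 2010, 2011]
search: {strategy: randomized, n_iter: 50, k_folds: 3}
seed: 7
```

Users holding a real county-year dataset can bypass the generator entirely:
provide a CSV with `county_id, year`, weather columns `<Variable>_<week>`
(variables `Wind, TempMin, TempMax, Humidity, Precipitation, Radiation`),
static columns `SowingDOY, FloweringDOY, HarvestDOY, LL, DUL, SAT, BD` and
`Yield`, then start from `yieldcast features`.

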