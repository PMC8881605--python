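import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yieldcast import baselines as bl
from yieldcast import features as ft
from yieldcast import synthdata as sd
from yieldcast.errors import ConfigError
from yieldcast.features import FeatureTable


def make_table(X: np.ndarray, y: np.ndarray) -> FeatureTable:
    return FeatureTable(
        X=pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])]),
        y=pd.Series(y),
        keys=pd.DataFrame({"county_id": ["c"] * len(y), "year": np.arange(len(y))}),
    )


class TestEuclideanDistance:
    def test_3_4_5_triangle(self):
        assert bl.euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_identity(self):
        assert bl.euclidean_distance([1.5, -2, 7], [1.5, -2, 7]) == 0.0

    def test_1d_absolute_difference(self):
        assert bl.euclidean_distance([2.0], [-3.0]) == pytest.approx(5.0)

    def test_length_mismatch(self):
        with pytest.raises(ConfigError):
            bl.euclidean_distance([1, 2], [1, 2, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=10),
        st.lists(st.floats(-100, 100), min_size=1, max_size=10),
        st.lists(st.floats(-100, 100), min_size=1, max_size=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_metric_axioms(self, p, q, r):
        n = min(len(p), len(q), len(r))
        p, q, r = p[:n], q[:n], r[:n]
        dpq = bl.euclidean_distance(p, q)
        assert dpq >= 0
        assert dpq == pytest.approx(bl.euclidean_distance(q, p))
        assert bl.euclidean_distance(p, r) <= dpq + bl.euclidean_distance(q, r) + 1e-9


class TestMakeBaseline:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ConfigError, match="knn"):
            bl.BaselineSpec(name="catboost")

    def test_all_names_constructible(self):
        for name in bl.BASELINE_NAMES:
            model = bl.make_baseline(bl.BaselineSpec(name=name))
            assert hasattr(model, "fit") and hasattr(model, "predict")

    def test_knn_full_neighborhood_predicts_mean(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
        table = make_table(X, y)
        model = bl.make_baseline(bl.BaselineSpec("knn", {"n_neighbors": 20})).fit(table)
        np.testing.assert_allclose(model.predict(table), y.mean(), atol=1e-10)

    def test_knn_convex_combination_of_targets(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.normal(size=(50, 4)), rng.normal(size=50))
        test = make_table(rng.normal(size=(30, 4)), np.zeros(30))
        model = bl.make_baseline(bl.BaselineSpec("knn", {"n_neighbors": 7})).fit(table)
        pred = model.predict(test)
        assert (pred >= table.y.min() - 1e-12).all()
        assert (pred <= table.y.max() + 1e-12).all()

    def test_lasso_zero_penalty_limit_approaches_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        beta = np.array([1.5, -2.0, 0.7])
        y = X @ beta + 0.01 * rng.normal(size=200)
        table = make_table(X, y)
        model = bl.make_baseline(bl.BaselineSpec("lasso", {"alpha": 1e-8})).fit(table)
        ols = np.linalg.lstsq(np.c_[X, np.ones(200)], y, rcond=None)[0]
        np.testing.assert_allclose(model.estimator.coef_, ols[:3], atol=1e-3)

    def test_regression_tree_first_split_matches_sse_oracle(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(-1, 1, size=60))
        y = (x > 0).astype(float)
        table = make_table(x[:, None], y)
        model = bl.make_baseline(bl.BaselineSpec("regression_tree", {"max_depth": 1})).fit(table)
        threshold = model.estimator.tree_.threshold[0]

        # brute-force SSE minimization over all candidate midpoints
        best_sse, best_thr = np.inf, None
        for i in range(1, len(x)):
            thr = (x[i - 1] + x[i]) / 2
            left, right = y[x <= thr], y[x > thr]
            sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            if sse < best_sse:
                best_sse, best_thr = sse, thr
        # sklearn stores features as float32 internally, hence the tolerance
        assert threshold == pytest.approx(best_thr, abs=1e-6)
        assert x[x <= best_thr].max() <= 0 < x[x > best_thr].min()  # sign boundary


@pytest.fixture(scope="module")
def tune_table():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 4))
    y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + 0.1 * rng.normal(size=60)
    return make_table(X, y)


class TestTuning:
    def test_singleton_space(self, tune_table):
        search = bl.SearchSpec(strategy="grid", space={"alpha": [0.5]}, k_folds=3, seed=0)
        best, log = bl.tune_hyperparameters("ridge", search, tune_table)
        assert best == {"alpha": 0.5}
        assert len(log) == 1

    def test_grid_matches_brute_force_enumeration(self, tune_table):
        space = {"alpha": [1e-3, 1e-1, 1.0, 10.0]}
        search = bl.SearchSpec(strategy="grid", space=space, k_folds=3, seed=7)
        best, log = bl.tune_hyperparameters("ridge", search, tune_table)

        # independent oracle: same folds, explicit loop over all 4 candidates
        from sklearn.linear_model import Ridge
        from sklearn.model_selection import KFold

        X = tune_table.X.to_numpy()
        y = tune_table.y.to_numpy()
        folds = list(KFold(3, shuffle=True, random_state=7).split(X))
        means = []
        for alpha in space["alpha"]:
            rmses = []
            for tr, va in folds:
                est = Ridge(alpha=alpha).fit(X[tr], y[tr])
                rmses.append(np.sqrt(np.mean((y[va] - est.predict(X[va])) ** 2)))
            means.append(np.mean(rmses))
        assert best == {"alpha": space["alpha"][int(np.argmin(means))]}
        np.testing.assert_allclose(sorted(log["mean_rmse"]), sorted(means), rtol=1e-12)

    def test_same_seed_identical_trial_log(self, tune_table):
        search = bl.SearchSpec(strategy="randomized", n_iter=5, seed=3)
        _, log1 = bl.tune_hyperparameters("regression_tree", search, tune_table)
        _, log2 = bl.tune_hyperparameters("regression_tree", search, tune_table)
        pd.testing.assert_frame_equal(log1, log2)

    def test_empty_space_errors(self, tune_table):
        with pytest.raises(ConfigError):
            bl.tune_hyperparameters("ridge", bl.SearchSpec(space={}), tune_table)

    def test_too_few_rows_errors(self):
        table = make_table(np.zeros((2, 1)), np.zeros(2))
        with pytest.raises(ConfigError):
            bl.tune_hyperparameters("ridge", bl.SearchSpec(k_folds=3), table)


class TestLinearDataSanity:
    def test_linear_models_beat_tree_on_linear_truth(self):
        """All-linear drivers: Lasso/Ridge should match or beat the tree."""
        truth = sd.YieldTruth(
            drivers=(
                sd.Driver("Wind", (3, 5), -0.5, "linear", center=3.6, scale=0.9),
                sd.Driver("TempMax", (6, 8), 0.5, "linear", center=14.0, scale=1.9),
            ),
            dul_penalty=0.0,
            noise_sd=0.1,
            county_effect_sd=0.0,
        )
        cfg = sd.GeneratorConfig(
            n_counties=110, first_year=2000, last_year=2011, n_weeks=10, truth=truth, seed=17
        )
        table = ft.assemble_feature_table(sd.generate_panel(cfg))
        train_raw, test_raw = ft.temporal_split(table, 2011)
        params = ft.fit_normalizer(train_raw)
        train = ft.apply_normalizer(train_raw, params)
        test = ft.apply_normalizer(test_raw, params)
        assert len(train) >= 1000

        def rmse(name, hp=None):
            model = bl.make_baseline(bl.BaselineSpec(name, hp or {})).fit(train)
            return float(np.sqrt(np.mean((test.y.to_numpy() - model.predict(test)) ** 2)))

        tree = rmse("regression_tree", {"max_depth": 8})
        assert rmse("lasso", {"alpha": 1e-3}) <= tree
        assert rmse("ridge", {"alpha": 1.0}) <= tree
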