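import numpy as np
import pandas as pd
import pytest

from yieldcast import baselines as bl
from yieldcast import features as ft
from yieldcast import interpret as it
from yieldcast import synthdata as sd
from yieldcast.errors import ConfigError, SchemaError


def frame(values, prefix="x"):
    values = np.atleast_2d(values)
    return pd.DataFrame(values, columns=[f"{prefix}{i}" for i in range(values.shape[1])])


@pytest.fixture(scope="module")
def additive_case():
    rng = np.random.default_rng(0)
    bg = frame(rng.normal(size=(60, 6)))
    inst = frame(rng.normal(size=(8, 6)))
    fn = lambda df: 2.0 * df["x0"].to_numpy() - 1.5 * df["x4"].to_numpy() + 0.7
    return fn, bg, inst


class TestShapValues:
    def test_additive_closed_form(self, additive_case):
        fn, bg, inst = additive_case
        sm = it.shap_values(fn, bg, inst, budget=500, seed=0)
        np.testing.assert_allclose(
            sm.values[:, 0], 2.0 * (inst["x0"].to_numpy() - bg["x0"].mean()), atol=1e-9
        )
        np.testing.assert_allclose(
            sm.values[:, 4], -1.5 * (inst["x4"].to_numpy() - bg["x4"].mean()), atol=1e-9
        )

    def test_null_player(self, additive_case):
        fn, bg, inst = additive_case
        sm = it.shap_values(fn, bg, inst, budget=500, seed=0)
        np.testing.assert_allclose(sm.values[:, [1, 2, 3, 5]], 0.0, atol=1e-9)

    def test_local_accuracy_nonlinear_model(self):
        rng = np.random.default_rng(1)
        bg = frame(rng.normal(size=(40, 5)))
        inst = frame(rng.normal(size=(6, 5)))
        fn = lambda df: np.tanh(df["x0"].to_numpy() * df["x1"].to_numpy()) + df["x2"].to_numpy() ** 2
        sm = it.shap_values(fn, bg, inst, budget=200, seed=2)
        assert np.abs(sm.local_accuracy_gap()).max() < 1e-9

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        bg = frame(rng.normal(size=(20, 30)))
        inst = frame(rng.normal(size=(3, 30)))
        fn = lambda df: np.sin(df.to_numpy()).sum(axis=1)
        a = it.shap_values(fn, bg, inst, budget=90, seed=5)
        b = it.shap_values(fn, bg, inst, budget=90, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_schema_mismatch_errors(self, additive_case):
        fn, bg, inst = additive_case
        with pytest.raises(SchemaError):
            it.shap_values(fn, bg, inst.rename(columns={"x0": "z0"}), budget=50)

    def test_exact_on_full_enumeration_vs_permutation_oracle(self):
        """Small m: kernel solution with all 2^m-2 coalitions equals the
        Shapley value computed by direct permutation enumeration."""
        import itertools

        rng = np.random.default_rng(4)
        m = 4
        bg = frame(rng.normal(size=(12, m)))
        inst = frame(rng.normal(size=(2, m)))

        def fn(df):
            X = df.to_numpy()
            return X[:, 0] * X[:, 1] + 0.5 * X[:, 2] ** 2 + X[:, 3]

        sm = it.shap_values(fn, bg, inst, budget=2**m, seed=0)

        B = bg.to_numpy()

        def value(S, x):  # E_b f(x_S, b_~S)
            mask = np.zeros(m, dtype=bool)
            mask[list(S)] = True
            hyb = np.where(mask, x, B)
            return fn(pd.DataFrame(hyb, columns=bg.columns)).mean()

        for i in range(2):
            x = inst.to_numpy()[i]
            phi = np.zeros(m)
            for perm in itertools.permutations(range(m)):
                S = []
                for j in perm:
                    before = value(S, x)
                    S.append(j)
                    phi[j] += value(S, x) - before
            import math

            phi /= math.factorial(m)
            np.testing.assert_allclose(sm.values[i], phi, atol=1e-8)


def make_shap(values, names, base=1.0, preds=None):
    values = np.asarray(values, dtype=float)
    if preds is None:
        preds = base + values.sum(axis=1)
    return it.ShapMatrix(
        values=values,
        base_value=base,
        feature_names=list(names),
        predictions=np.asarray(preds, dtype=float),
        n_background=1,
        budget=0,
    )


class TestGlobalImportance:
    def test_all_zero_contributions(self):
        sm = make_shap(np.zeros((4, 3)), ["a", "b", "c"])
        imp = it.global_importance(sm, frame(np.random.default_rng(0).normal(size=(4, 3)), "f").set_axis(["a", "b", "c"], axis=1))
        assert (imp["importance"] == 0).all()
        assert sorted(imp["rank"]) == [1, 2, 3]

    def test_single_nonzero_column_ranked_first(self):
        vals = np.zeros((5, 3))
        vals[:, 1] = [1.0, -2.0, 0.5, 1.5, -1.0]
        sm = make_shap(vals, ["a", "b", "c"])
        feats = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 3)), columns=["a", "b", "c"])
        imp = it.global_importance(sm, feats)
        assert imp.loc[imp["feature"] == "b", "rank"].iloc[0] == 1

    def test_mean_abs_matches_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(7, 4))
        names = ["a", "b", "c", "d"]
        sm = make_shap(vals, names)
        feats = pd.DataFrame(rng.normal(size=(7, 4)), columns=names)
        imp = it.global_importance(sm, feats)
        for j, name in enumerate(names):
            brute = sum(abs(vals[i, j]) for i in range(7)) / 7
            assert imp.loc[imp["feature"] == name, "importance"].iloc[0] == pytest.approx(brute)

    def test_sign_from_correlation(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=20)
        vals = np.c_[2 * f, -3 * f]
        sm = make_shap(vals, ["up", "down"])
        feats = pd.DataFrame({"up": f, "down": f})
        imp = it.global_importance(sm, feats)
        assert imp.set_index("feature").loc["up", "sign"] == 1.0
        assert imp.set_index("feature").loc["down", "sign"] == -1.0


@pytest.fixture(scope="module")
def imp277():
    rng = np.random.default_rng(0)
    names = ft.feature_column_order(45)
    vals = rng.exponential(size=(3, 277))
    sm = make_shap(vals, names)
    return it.global_importance(sm, pd.DataFrame(rng.normal(size=(3, 277)), columns=names))


class TestTopFeatures:
    def test_fraction_counts(self, imp277):
        assert len(it.top_features(imp277, 1.0)) == 277
        assert len(it.top_features(imp277, 0.75)) == 208  # ceil(207.75)
        assert len(it.top_features(imp277, 0.5)) == 139  # ceil(138.5)

    def test_weather_only_is_270(self, imp277):
        assert len(it.weather_feature_names(list(imp277["feature"]))) == 270

    def test_invalid_fraction(self, imp277):
        with pytest.raises(ConfigError):
            it.top_features(imp277, 0.0)
        with pytest.raises(ConfigError):
            it.top_features(imp277, 1.2)


class TestForceData:
    def test_single_instance_all_selectors_agree(self):
        sm = make_shap([[1.0, -0.5]], ["a", "b"], base=2.0)
        for sel in ("min", "median", "max"):
            fd = it.force_data(sm, np.array([4.0]), sel)
            assert fd["instance_index"] == 0

    def test_signed_sum_reproduces_prediction(self):
        rng = np.random.default_rng(5)
        sm = make_shap(rng.normal(size=(6, 4)), list("abcd"), base=3.0)
        fd = it.force_data(sm, rng.normal(size=6), "max")
        total = fd["base_value"] + fd["contributions"]["contribution"].sum()
        assert total == pytest.approx(fd["output_value"])

    def test_even_count_median_is_lower_middle(self):
        sm = make_shap(np.zeros((4, 2)), ["a", "b"])
        actual = np.array([4.0, 1.0, 3.0, 2.0])
        fd = it.force_data(sm, actual, "median")
        assert fd["actual_yield"] == 2.0  # lower of the two middle yields {2, 3}

    def test_contributions_sorted_by_magnitude(self):
        sm = make_shap([[0.1, -2.0, 1.0]], ["a", "b", "c"])
        fd = it.force_data(sm, np.array([1.0]), "min")
        mags = fd["contributions"]["contribution"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()

    def test_empty_set_errors(self):
        sm = make_shap(np.zeros((1, 2)), ["a", "b"])
        with pytest.raises(ConfigError):
            it.force_data(sm, np.array([]), "min")


class TestWeeklyProfile:
    def test_uniform_contributions_flat_profile(self):
        names = ft.feature_column_order(45)
        vals = np.ones((3, 277))
        sm = make_shap(vals, names)
        grid, totals = it.weekly_weather_profile(sm)
        assert grid.shape == (6, 45)
        np.testing.assert_allclose(totals.to_numpy(), 100.0 / 6.0)
        np.testing.assert_allclose(grid.to_numpy().sum(), 100.0)

    def test_single_nonzero_wind_week(self):
        names = ft.feature_column_order(45)
        vals = np.zeros((2, 277))
        vals[:, names.index("Wind_10")] = 3.0
        sm = make_shap(vals, names)
        _, totals = it.weekly_weather_profile(sm)
        assert totals["Wind"] == pytest.approx(100.0)

    def test_brute_force_grouping_agreement(self):
        rng = np.random.default_rng(6)
        names = ft.feature_column_order(12)
        vals = rng.normal(size=(5, len(names)))
        sm = make_shap(vals, names)
        grid, totals = it.weekly_weather_profile(sm)
        raw = {
            v: sum(
                np.abs(vals[:, names.index(f"{v}_{w}")]).mean() for w in range(1, 13)
            )
            for v in sd.WEATHER_VARIABLES
        }
        total = sum(raw.values())
        for v in sd.WEATHER_VARIABLES:
            assert totals[v] == pytest.approx(100.0 * raw[v] / total)

    def test_no_weather_columns_errors(self):
        sm = make_shap(np.ones((2, 2)), ["DUL", "BD"])
        with pytest.raises(ConfigError):
            it.weekly_weather_profile(sm)


@pytest.fixture(scope="module")
def ablation_setup():
    cfg = sd.GeneratorConfig(
        n_counties=12,
        first_year=2000,
        last_year=2005,
        n_weeks=10,
        truth=sd.YieldTruth(
            drivers=(sd.Driver("Wind", (2, 4), -0.5, "linear", center=3.6, scale=0.9),),
            noise_sd=0.15,
        ),
        seed=9,
    )
    table = ft.assemble_feature_table(sd.generate_panel(cfg))
    rng = np.random.default_rng(0)
    names = table.columns
    sm = make_shap(rng.exponential(size=(4, len(names))), names)
    imp = it.global_importance(sm, table.X.iloc[:4])
    return table, imp


class TestAblation:
    def test_grid_shape_and_subset_sizes(self, ablation_setup):
        table, imp = ablation_setup
        builder = lambda tr: bl.make_baseline(bl.BaselineSpec("ridge")).fit(tr)
        grid = it.ablation_retrain(builder, table, imp, [2004, 2005], fractions=(1.0, 0.5))
        # 3 subsets (full, top_50, weather_only) x 2 years x 2 splits
        assert len(grid) == 12
        sizes = grid.groupby("subset")["n_features"].first()
        n = len(table.columns)
        assert sizes["full"] == n
        assert sizes["top_50"] == int(np.ceil(0.5 * n))
        assert sizes["weather_only"] == 60  # 6 x 10 weeks

    def test_invalid_fraction_errors(self, ablation_setup):
        table, imp = ablation_setup
        builder = lambda tr: bl.make_baseline(bl.BaselineSpec("ridge")).fit(tr)
        with pytest.raises(ConfigError):
            it.ablation_retrain(builder, table, imp, [2005], fractions=(1.5,))

    def test_mask_columns_zeroes_dropped(self, ablation_setup):
        table, _ = ablation_setup
        masked = it.mask_columns(table, ["DUL", "Wind_1"])
        assert (masked.X["DUL"] == table.X["DUL"]).all()
        assert (masked.X["BD"] == 0.0).all()
        assert (masked.X["Wind_2"] == 0.0).all()
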