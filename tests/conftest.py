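import numpy as np
import pytest

from yieldcast import cnn
from yieldcast import features as ft
from yieldcast import synthdata as sd


def tiny_truth(n_weeks: int = 12) -> sd.YieldTruth:
    """Truth with driver windows that fit a short season (for cheap CNN tests)."""
    return sd.YieldTruth(
        drivers=(
            sd.Driver("Radiation", (3, 5), -0.4, "square", center=100.0, scale=12.0),
            sd.Driver("Wind", (6, 8), -0.3, "linear", center=3.6, scale=0.9),
            sd.Driver("TempMax", (2, 4), 0.3, "linear", center=14.0, scale=1.8),
        ),
        noise_sd=0.15,
        county_effect_sd=0.15,
    )


@pytest.fixture(scope="session")
def small_panel() -> sd.PanelTable:
    """45-week panel, 12 counties x 6 years: full schema, desk-fast."""
    cfg = sd.GeneratorConfig(n_counties=12, first_year=2000, last_year=2005, seed=11)
    return sd.generate_panel(cfg)


@pytest.fixture(scope="session")
def small_table(small_panel) -> ft.FeatureTable:
    return ft.assemble_feature_table(small_panel)


@pytest.fixture(scope="session")
def tiny_config() -> sd.GeneratorConfig:
    return sd.GeneratorConfig(
        n_counties=10,
        first_year=2001,
        last_year=2006,
        n_weeks=12,
        truth=tiny_truth(),
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_table(tiny_config) -> ft.FeatureTable:
    return ft.assemble_feature_table(sd.generate_panel(tiny_config))


@pytest.fixture(scope="session")
def tiny_normalized(tiny_table):
    train_raw, test_raw = ft.temporal_split(tiny_table, 2006)
    params = ft.fit_normalizer(train_raw)
    return ft.apply_normalizer(train_raw, params), ft.apply_normalizer(test_raw, params)


@pytest.fixture(scope="session")
def tiny_arch() -> cnn.CnnArchConfig:
    return cnn.CnnArchConfig(
        conv_layers=((4, 3, 1), (4, 3, 1)),
        pool_width=2,
        static_fc_sizes=(8, 8),
        head_fc_sizes=(16, 8, 8),
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_arch, tiny_normalized):
    """A CNN trained briefly on the tiny panel; shared by several tests."""
    train, test = tiny_normalized
    model = cnn.build_cnn(tiny_arch, n_weeks=12)
    _, history = cnn.train_cnn(
        model, train, cnn.TrainConfig(epochs=15, batch_size=32, learning_rate=2e-3, seed=3)
    )
    return model, history, train, test


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
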