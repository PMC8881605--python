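"""Multi-branch 1-D CNN for county-year yield regression.

Each of the six weekly weather series passes through a stack of valid-padding
1-D convolutions (weights shared across variables by default) followed by
average pooling; the flattened branch outputs are concatenated with a
two-layer fully-connected encoding of the seven static soil/phenology
features, and a three-layer fully-connected head produces the scalar yield.
All layers except the output use ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError, SchemaError, TrainingError
from ..synthdata import STATIC_COLUMNS, WEATHER_VARIABLES
from . import layers as L


@dataclass(frozen=True)
class CnnArchConfig:
    conv_layers: tuple[tuple[int, int, int], ...] = ((16, 3, 1), (16, 3, 1))  # (filters, kernel, stride)
    pool_width: int = 2
    share_branch_weights: bool = True
    static_fc_sizes: tuple[int, int] = (16, 16)
    head_fc_sizes: tuple[int, int, int] = (64, 32, 16)

    def __post_init__(self) -> None:
        if len(self.head_fc_sizes) != 3:
            raise ConfigError("head_fc_sizes: head must have exactly three layers")
        if len(self.static_fc_sizes) != 2:
            raise ConfigError("static_fc_sizes: static branch must have exactly two layers")
        if self.pool_width < 1:
            raise ConfigError("pool_width: must be >= 1")
        for f, k, s in self.conv_layers:
            if f < 1 or k < 1 or s < 1:
                raise ConfigError("conv_layers: filters, kernel and stride must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs: must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate: must be > 0")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ConfigError("validation_fraction: must be in [0, 1)")


class YieldCnn:
    """The model handle: architecture, parameters, and forward/backward."""

    def __init__(self, arch: CnnArchConfig, n_weeks: int, n_static: int):
        self.arch = arch
        self.n_weeks = n_weeks
        self.n_static = n_static
        self.columns: list[str] | None = None
        self.history: dict | None = None
        self.train_config: TrainConfig | None = None

        # trace conv chain lengths to validate kernels and size the head
        length = n_weeks
        for i, (f, k, s) in enumerate(arch.conv_layers):
            if k > length:
                raise ConfigError(
                    f"conv_layers[{i}]: kernel {k} larger than input length {length}"
                )
            length = (length - k) // s + 1
        self._conv_out_len = length
        self._pool_out_len = max(length // arch.pool_width, 0) if arch.pool_width > 1 else length
        if self._pool_out_len == 0:
            raise ConfigError("pool_width: pooling collapses the sequence to length 0")
        last_filters = arch.conv_layers[-1][0] if arch.conv_layers else 1
        self._branch_dim = self._pool_out_len * last_filters
        self._concat_dim = len(WEATHER_VARIABLES) * self._branch_dim + arch.static_fc_sizes[-1]
        self.params: dict[str, np.ndarray] = {}
        self.init_params(np.random.default_rng(0))

    # -- parameters -----------------------------------------------------
    def _branch_prefixes(self) -> list[str]:
        if self.arch.share_branch_weights:
            return [""]
        return [f"v{i}_" for i in range(len(WEATHER_VARIABLES))]

    def init_params(self, rng: np.random.Generator) -> None:
        """He-initialised weights, zero biases."""
        p: dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        for prefix in self._branch_prefixes():
            c_in = 1
            for li, (f, k, s) in enumerate(self.arch.conv_layers):
                p[f"{prefix}cv{li}_w"] = he((k * c_in, f), k * c_in)
                p[f"{prefix}cv{li}_b"] = np.zeros(f)
                c_in = f
        dims = (self.n_static, *self.arch.static_fc_sizes)
        for i in range(2):
            p[f"st{i}_w"] = he((dims[i], dims[i + 1]), dims[i])
            p[f"st{i}_b"] = np.zeros(dims[i + 1])
        hdims = (self._concat_dim, *self.arch.head_fc_sizes)
        for i in range(3):
            p[f"hd{i}_w"] = he((hdims[i], hdims[i + 1]), hdims[i])
            p[f"hd{i}_b"] = np.zeros(hdims[i + 1])
        p["out_w"] = he((hdims[-1], 1), hdims[-1])
        p["out_b"] = np.zeros(1)
        self.params = p

    # -- forward / backward --------------------------------------------
    def _branch_forward(self, x: np.ndarray, prefix: str):
        """x: (M, n_weeks, 1) -> (flat (M, branch_dim), cache)."""
        cache = []
        h = x
        for li, (f, k, s) in enumerate(self.arch.conv_layers):
            z, cols = L.conv1d_forward(h, self.params[f"{prefix}cv{li}_w"], self.params[f"{prefix}cv{li}_b"], k, s)
            cache.append((h.shape, cols, z))
            h = L.relu(z)
        pre_pool_len = h.shape[1]
        if self.arch.pool_width > 1:
            h, _ = L.avgpool1d_forward(h, self.arch.pool_width)
        flat = h.reshape(h.shape[0], -1)
        return flat, (cache, pre_pool_len, h.shape)

    def _branch_backward(self, grad_flat: np.ndarray, bcache, prefix: str, grads: dict) -> None:
        cache, pre_pool_len, pooled_shape = bcache
        g = grad_flat.reshape(pooled_shape)
        if self.arch.pool_width > 1:
            g = L.avgpool1d_backward(g, self.arch.pool_width, pre_pool_len)
        for li in reversed(range(len(self.arch.conv_layers))):
            f, k, s = self.arch.conv_layers[li]
            x_shape, cols, z = cache[li]
            g = L.relu_backward(g, z)
            g, dw, db = L.conv1d_backward(g, cols, x_shape, self.params[f"{prefix}cv{li}_w"], k, s)
            grads[f"{prefix}cv{li}_w"] = grads.get(f"{prefix}cv{li}_w", 0.0) + dw
            grads[f"{prefix}cv{li}_b"] = grads.get(f"{prefix}cv{li}_b", 0.0) + db

    def forward(self, weather: np.ndarray, static: np.ndarray, want_cache: bool = False):
        """weather: (N, 6, n_weeks); static: (N, n_static) -> predictions (N,)."""
        n = weather.shape[0]
        nv = len(WEATHER_VARIABLES)
        if self.arch.share_branch_weights:
            xb = weather.reshape(n * nv, self.n_weeks, 1)
            flat, bcache = self._branch_forward(xb, "")
            weather_feats = flat.reshape(n, nv * self._branch_dim)
            bcaches = [bcache]
        else:
            flats, bcaches = [], []
            for vi in range(nv):
                flat, bc = self._branch_forward(weather[:, vi, :, None], f"v{vi}_")
                flats.append(flat)
                bcaches.append(bc)
            weather_feats = np.concatenate(flats, axis=1)

        z_st = []
        h = static
        st_inputs = []
        for i in range(2):
            st_inputs.append(h)
            z = L.dense_forward(h, self.params[f"st{i}_w"], self.params[f"st{i}_b"])
            z_st.append(z)
            h = L.relu(z)
        static_feats = h

        concat = np.concatenate([weather_feats, static_feats], axis=1)
        z_hd, hd_inputs = [], []
        h = concat
        for i in range(3):
            hd_inputs.append(h)
            z = L.dense_forward(h, self.params[f"hd{i}_w"], self.params[f"hd{i}_b"])
            z_hd.append(z)
            h = L.relu(z)
        pred = L.dense_forward(h, self.params["out_w"], self.params["out_b"]).ravel()
        if not want_cache:
            return pred
        cache = {
            "bcaches": bcaches,
            "z_st": z_st,
            "st_inputs": st_inputs,
            "z_hd": z_hd,
            "hd_inputs": hd_inputs,
            "head_out": h,
            "n": n,
        }
        return pred, cache

    def backward(self, dpred: np.ndarray, cache) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        n = cache["n"]
        nv = len(WEATHER_VARIABLES)
        g = dpred[:, None]
        gx, grads["out_w"], grads["out_b"] = L.dense_backward(g, cache["head_out"], self.params["out_w"])
        for i in reversed(range(3)):
            gx = L.relu_backward(gx, cache["z_hd"][i])
            gx, grads[f"hd{i}_w"], grads[f"hd{i}_b"] = L.dense_backward(
                gx, cache["hd_inputs"][i], self.params[f"hd{i}_w"]
            )
        g_weather = gx[:, : nv * self._branch_dim]
        g_static = gx[:, nv * self._branch_dim :]
        for i in reversed(range(2)):
            g_static = L.relu_backward(g_static, cache["z_st"][i])
            g_static, grads[f"st{i}_w"], grads[f"st{i}_b"] = L.dense_backward(
                g_static, cache["st_inputs"][i], self.params[f"st{i}_w"]
            )
        if self.arch.share_branch_weights:
            gb = g_weather.reshape(n * nv, self._branch_dim)
            self._branch_backward(gb, cache["bcaches"][0], "", grads)
        else:
            for vi in range(nv):
                gb = g_weather[:, vi * self._branch_dim : (vi + 1) * self._branch_dim]
                self._branch_backward(gb, cache["bcaches"][vi], f"v{vi}_", grads)
        return grads

    # -- FeatureTable plumbing ------------------------------------------
    def split_columns(self, columns: list[str]) -> tuple[list[str], list[str]]:
        weather_cols = [
            f"{v}_{w}" for v in WEATHER_VARIABLES for w in range(1, self.n_weeks + 1)
        ]
        missing = [c for c in weather_cols if c not in columns]
        if missing:
            raise SchemaError(f"missing weather columns: {missing[:5]}")
        static_cols = [c for c in STATIC_COLUMNS if c in columns]
        if len(static_cols) != self.n_static:
            raise SchemaError(
                f"expected {self.n_static} static columns, found {static_cols}"
            )
        return weather_cols, static_cols

    def table_inputs(self, table) -> tuple[np.ndarray, np.ndarray]:
        weather_cols, static_cols = self.split_columns(table.columns)
        n = len(table)
        xw = table.X[weather_cols].to_numpy(dtype=float).reshape(
            n, len(WEATHER_VARIABLES), self.n_weeks
        )
        xs = table.X[static_cols].to_numpy(dtype=float)
        return xw, xs

    def predict_table(self, table, chunk: int = 4096) -> np.ndarray:
        if self.columns is not None and table.columns != self.columns:
            raise SchemaError("feature columns differ from those seen at training time")
        xw, xs = self.table_inputs(table)
        out = np.empty(len(table))
        for lo in range(0, len(table), chunk):
            hi = lo + chunk
            out[lo:hi] = self.forward(xw[lo:hi], xs[lo:hi])
        return out

    # sklearn-style aliases used by the benchmark harness
    def predict(self, table) -> np.ndarray:
        return self.predict_table(table)


def build_cnn(arch: CnnArchConfig, n_weeks: int, n_static: int = 7) -> YieldCnn:
    """Construct an (unfitted) model; weights are re-initialised at training."""
    return YieldCnn(arch, n_weeks, n_static)


def train_cnn(model: YieldCnn, train, cfg: TrainConfig):
    """Mini-batch Adam training on squared-error loss.

    Rows are canonically sorted by (county_id, year) first, so the fitted
    model is invariant to the incoming row order for a fixed seed. Returns
    ``(model, history)`` where the history holds end-of-epoch losses over the
    full training set (and validation set when configured).
    """
    table = train.sorted_by_key()
    xw, xs = model.table_inputs(table)
    y = table.y.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise TrainingError("training rows with missing yield")

    rng = np.random.default_rng(cfg.seed)
    model.init_params(rng)
    model.params["out_b"][:] = y.mean()
    model.columns = table.columns
    model.train_config = cfg

    n = len(y)
    idx = np.arange(n)
    if cfg.validation_fraction > 0:
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        val_idx = rng.permutation(n)[:n_val]
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        tr_idx = idx[~val_mask]
    else:
        tr_idx, val_mask = idx, None

    opt = L.Adam(model.params, lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_mse": [], "train_rmse": []}
    if val_mask is not None:
        history["val_mse"] = []

    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(tr_idx))
        order = tr_idx[perm]
        for lo in range(0, len(order), cfg.batch_size):
            b = order[lo : lo + cfg.batch_size]
            pred, cache = model.forward(xw[b], xs[b], want_cache=True)
            err = pred - y[b]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {_epoch}")
            grads = model.backward(2.0 * err / len(b), cache)
            opt.step(model.params, grads)
        full = model.forward(xw[tr_idx], xs[tr_idx])
        mse = float(np.mean((full - y[tr_idx]) ** 2))
        if not np.isfinite(mse):
            raise TrainingError(f"non-finite epoch loss at epoch {_epoch}")
        history["train_mse"].append(mse)
        history["train_rmse"].append(float(np.sqrt(mse)))
        if val_mask is not None:
            vp = model.forward(xw[val_mask], xs[val_mask])
            history["val_mse"].append(float(np.mean((vp - y[val_mask]) ** 2)))

    model.history = history
    return model, history


def predict(model: YieldCnn, table) -> np.ndarray:
    """One finite prediction per row; pure function of inputs and weights."""
    out = model.predict_table(table)
    if not np.isfinite(out).all():
        raise TrainingError("non-finite predictions")
    return out
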