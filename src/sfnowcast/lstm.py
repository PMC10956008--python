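"""LSTM regression nowcaster, implemented directly on NumPy.

Architecture and training defaults: stacked LSTM (1 or 2 layers) with sigmoid
gate activations and tanh cell activation, Xavier/Glorot-initialized weights,
dropout 0.2 applied between stacked layers (inert for 1-layer models), a
single linear readout unit on the final hidden state, mean-squared-error
loss, Adam at learning rate 0.001 with L2 weight decay 0.01. The
hyperparameter grid searched per state is hidden layers {1, 2} x hidden
dimensions {16, 32, 64} x epochs {150, 200, 250, 300}, selected by lowest
validation RMSE.

Training uses seeded mini-batch gradient steps (default batch 8) and
initializes the readout bias at the training-target mean; with a fixed small
learning rate and a few hundred epochs this puts the optimizer within reach
of count-valued targets from the first step. Backpropagation through time is
written out explicitly; sequences here are short (w = 2 weeks), so the
unrolled graph is tiny and CPU training takes well under a second per model.

All randomness (initialization, batch order, dropout masks) flows from the
config seed, making training bitwise-reproducible on one device.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import (HEALTH_SOURCES, ONLINE_SOURCES, PROXY_SOURCES, SourceKind,
                    StatePanel)
from .windowing import (FeatureScaler, LagSpec, WindowSample, apply_scaler,
                        fit_scaler, stack_features, targets)

GRID_HIDDEN_LAYERS = (1, 2)
GRID_HIDDEN_DIMS = (16, 32, 64)
GRID_EPOCHS = (150, 200, 250, 300)


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")


@dataclass(frozen=True)
class NowcastConfig:
    """LSTM hyperparameters. Grid-searched fields take the values above when
    used in a grid; they are unrestricted for free-form experiments."""

    hidden_layers: int = 1
    hidden_dim: int = 32
    epochs: int = 200
    dropout: float = 0.2
    learning_rate: float = 0.001
    l2_weight_decay: float = 0.01
    batch_size: int = 8
    seed: int = 0


@dataclass(frozen=True)
class SourceCombination:
    """A named selection of input streams, mirroring the study's model grid."""

    name: str
    sources: tuple[SourceKind, ...]
    include_lagged_deaths: bool

    @property
    def n_features(self) -> int:
        return len(self.sources) + (1 if self.include_lagged_deaths else 0)


def standard_combinations() -> dict[str, SourceCombination]:
    """The model grid reported per state: per-category, per-combination, the
    historical-only baseline, and one model per individual source."""
    combos = {
        "online_only": SourceCombination("online_only", ONLINE_SOURCES, False),
        "health_only": SourceCombination("health_only", HEALTH_SOURCES, False),
        "baseline_plus_health": SourceCombination("baseline_plus_health", HEALTH_SOURCES, True),
        "baseline_plus_online": SourceCombination("baseline_plus_online", ONLINE_SOURCES, True),
        "health_plus_online": SourceCombination("health_plus_online",
                                                HEALTH_SOURCES + ONLINE_SOURCES, False),
        "all_sources": SourceCombination("all_sources", PROXY_SOURCES, True),
        "historical_only": SourceCombination("historical_only", (), True),
    }
    for s in PROXY_SOURCES:
        combos[f"single:{s.value}"] = SourceCombination(f"single:{s.value}", (s,), False)
    return combos


def get_combination(name: str) -> SourceCombination:
    combos = standard_combinations()
    if name not in combos:
        raise KeyError(f"unknown source combination {name!r}; known: {sorted(combos)}")
    return combos[name]


# ---------------------------------------------------------------------------
# network internals

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _xavier(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _LSTMParams:
    """Weights for a stack of LSTM layers plus a linear readout."""

    def __init__(self, n_features: int, hidden_dim: int, n_layers: int, rng):
        self.layers = []
        for l in range(n_layers):
            fin = n_features if l == 0 else hidden_dim
            self.layers.append({
                "Wx": _xavier(rng, fin, 4 * hidden_dim, (fin, 4 * hidden_dim)),
                "Wh": _xavier(rng, hidden_dim, 4 * hidden_dim, (hidden_dim, 4 * hidden_dim)),
                "b": np.zeros(4 * hidden_dim),
            })
        self.V = _xavier(rng, hidden_dim, 1, (hidden_dim, 1))
        self.b_out = np.zeros(1)
        self.hidden_dim = hidden_dim

    def tensors(self):
        out = []
        for l, lay in enumerate(self.layers):
            for k in ("Wx", "Wh", "b"):
                out.append((f"{k}{l}", lay, k))
        out.append(("V", self.__dict__, "V"))
        out.append(("b_out", self.__dict__, "b_out"))
        return out


def _forward(params: _LSTMParams, X: np.ndarray, dropout_masks=None):
    """X: (N, w, F). Returns predictions (N,) and caches for backprop."""
    N, w, _ = X.shape
    H = params.hidden_dim
    inp = X
    caches = []
    for l, lay in enumerate(params.layers):
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        steps = []
        outs = np.empty((N, w, H))
        for t in range(w):
            x = inp[:, t, :]
            z = x @ lay["Wx"] + h @ lay["Wh"] + lay["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            steps.append({"x": x, "h_prev": h, "c_prev": c,
                          "i": i, "f": f, "g": g, "o": o, "c": c_new})
            h, c = h_new, c_new
            outs[:, t, :] = h
        mask = None
        if dropout_masks is not None and l < len(params.layers) - 1:
            mask = dropout_masks[l]
            outs = outs * mask
        caches.append({"steps": steps, "inp": inp, "mask": mask})
        inp = outs
    yhat = (inp[:, -1, :] @ params.V + params.b_out).ravel()
    return yhat, caches


def _backward(params: _LSTMParams, caches, X, dyhat):
    """Gradients of the (already-scaled) loss wrt every tensor."""
    N, w, _ = X.shape
    H = params.hidden_dim
    # readout gradients use the (possibly dropped-out) top-layer output
    top_out_last = _layer_output(caches, -1)[:, -1, :]
    grads = {"V": top_out_last.T @ dyhat[:, None], "b_out": np.array([dyhat.sum()])}
    # dh flowing into the top layer: only at the last timestep
    dh_seq = np.zeros((N, w, H))
    dh_seq[:, -1, :] = dyhat[:, None] * params.V.T
    for l in range(len(params.layers) - 1, -1, -1):
        cache = caches[l]
        lay = params.layers[l]
        if cache["mask"] is not None:
            dh_seq = dh_seq * cache["mask"]
        dWx = np.zeros_like(lay["Wx"])
        dWh = np.zeros_like(lay["Wh"])
        db = np.zeros_like(lay["b"])
        dX = np.zeros_like(cache["inp"])
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in range(w - 1, -1, -1):
            st = cache["steps"][t]
            dh = dh_seq[:, t, :] + dh_next
            tanh_c = np.tanh(st["c"])
            dc = dc_next + dh * st["o"] * (1 - tanh_c ** 2)
            do = dh * tanh_c
            di = dc * st["g"]
            dg = dc * st["i"]
            df = dc * st["c_prev"]
            dz = np.concatenate([
                di * st["i"] * (1 - st["i"]),
                df * st["f"] * (1 - st["f"]),
                dg * (1 - st["g"] ** 2),
                do * st["o"] * (1 - st["o"]),
            ], axis=1)
            dWx += st["x"].T @ dz
            dWh += st["h_prev"].T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ lay["Wx"].T
            dh_next = dz @ lay["Wh"].T
            dc_next = dc * st["f"]
        grads[f"Wx{l}"] = dWx
        grads[f"Wh{l}"] = dWh
        grads[f"b{l}"] = db
        dh_seq = dX
    return grads


def _layer_output(caches, l):
    """Output sequence of layer l after dropout (the input of the next stage)."""
    cache = caches[l]
    outs = np.stack([st["o"] * np.tanh(st["c"]) for st in cache["steps"]], axis=1)
    if cache["mask"] is not None:
        outs = outs * cache["mask"]
    return outs


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: _LSTMParams, grads):
        self.t += 1
        for name, holder, key in params.tensors():
            g = grads[name]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            if isinstance(holder, dict):
                holder[key] = holder[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            else:  # pragma: no cover - holder is always a dict here
                raise AssertionError


# ---------------------------------------------------------------------------
# public training surface

@dataclass
class TrainedNowcaster:
    params: _LSTMParams
    config: NowcastConfig
    scaler: FeatureScaler | None
    n_features: int
    window: int
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    feature_names: list[str] = field(default_factory=list)


def fit_nowcaster(
    config: NowcastConfig,
    train: list[WindowSample],
    val: list[WindowSample] | None = None,
    scaler: FeatureScaler | None = None,
) -> TrainedNowcaster:
    """Train an LSTM nowcaster on windowed samples.

    If ``scaler`` is None a standardizer is fit on ``train`` and applied to
    both splits (validation and test samples passed to :func:`predict` later
    are transformed with the same training statistics).
    """
    if not train:
        raise ValueError("training set is empty")
    import warnings as _warnings
    if scaler is None:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            scaler = fit_scaler(train)
    tr = apply_scaler(scaler, train)
    Xtr = stack_features(tr)
    ytr = targets(tr)
    Xval = yval = None
    if val:
        va = apply_scaler(scaler, val)
        Xval, yval = stack_features(va), targets(va)

    N, w, F = Xtr.shape
    rng = np.random.default_rng(config.seed)
    params = _LSTMParams(F, config.hidden_dim, config.hidden_layers, rng)
    params.b_out[0] = ytr.mean()  # start the readout at the target mean
    shapes = {name: holder[key].shape for name, holder, key in params.tensors()}
    opt = _Adam(shapes, config.learning_rate)
    decayed = {f"Wx{l}" for l in range(config.hidden_layers)} | \
              {f"Wh{l}" for l in range(config.hidden_layers)} | {"V"}

    history = []
    order = np.arange(N)
    bs = max(1, min(config.batch_size, N))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        for start in range(0, N, bs):
            idx = order[start:start + bs]
            Xb, yb = Xtr[idx], ytr[idx]
            masks = None
            if config.hidden_layers > 1 and config.dropout > 0:
                keep = 1.0 - config.dropout
                masks = [
                    (rng.random((len(idx), w, config.hidden_dim)) < keep) / keep
                    for _ in range(config.hidden_layers - 1)
                ]
            yhat, caches = _forward(params, Xb, dropout_masks=masks)
            err = yhat - yb
            dyhat = 2.0 * err / len(idx)          # d(MSE)/d(yhat)
            grads = _backward(params, caches, Xb, dyhat)
            for tname, holder, key in params.tensors():  # L2 decay on weights only
                if tname in decayed:
                    grads[tname] = grads[tname] + config.l2_weight_decay * holder[key]
            opt.step(params, grads)
        train_loss = float(np.mean((_forward(params, Xtr)[0] - ytr) ** 2))
        if not np.isfinite(train_loss):
            raise TrainingDivergenceError(epoch)
        val_loss = float(np.mean((_forward(params, Xval)[0] - yval) ** 2)) \
            if Xval is not None else np.nan
        history.append((epoch, train_loss, val_loss))

    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"])
    return TrainedNowcaster(params=params, config=config, scaler=scaler,
                            n_features=F, window=w, history=hist,
                            feature_names=list(train[0].feature_names))


def predict(model: TrainedNowcaster, samples: list[WindowSample]) -> np.ndarray:
    """Nonnegative weekly death-count predictions, one per sample, in order."""
    if not samples:
        return np.zeros(0)
    if samples[0].features.shape != (model.window, model.n_features):
        raise ValueError(
            f"sample layout {samples[0].features.shape} does not match "
            f"model layout {(model.window, model.n_features)}"
        )
    scaled = apply_scaler(model.scaler, samples) if model.scaler is not None else samples
    yhat, _ = _forward(model.params, stack_features(scaled))
    return np.maximum(yhat, 0.0)


@dataclass
class GridSearchResult:
    table: pd.DataFrame          # hidden_layers, hidden_dim, epochs, val_rmse
    selected: NowcastConfig
    selection_rule: str
    best_model: TrainedNowcaster


def grid_search(
    train: list[WindowSample],
    val: list[WindowSample],
    seed: int = 0,
    hidden_layers=GRID_HIDDEN_LAYERS,
    hidden_dims=GRID_HIDDEN_DIMS,
    epochs_grid=GRID_EPOCHS,
    base: NowcastConfig = NowcastConfig(),
) -> GridSearchResult:
    """Train every (layers, dim, epochs) combination with the shared seed and
    select the lowest validation RMSE; ties break toward fewer layers, then
    smaller hidden dimension, then fewer epochs (the iteration order)."""
    grid = list(itertools.product(sorted(hidden_layers), sorted(hidden_dims),
                                  sorted(epochs_grid)))
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    best = None
    n_diverged = 0
    for nl, hd, ep in grid:
        cfg = replace(base, hidden_layers=nl, hidden_dim=hd, epochs=ep, seed=seed)
        try:
            model = fit_nowcaster(cfg, train, val)
        except TrainingDivergenceError:
            n_diverged += 1
            rows.append((nl, hd, ep, np.nan))
            continue
        rmse = float(np.sqrt(np.mean((predict(model, val) - targets(val)) ** 2)))
        rows.append((nl, hd, ep, rmse))
        if best is None or rmse < best[0]:
            best = (rmse, cfg, model)
    if best is None:
        raise TrainingDivergenceError(-1)
    table = pd.DataFrame(rows, columns=["hidden_layers", "hidden_dim", "epochs", "val_rmse"])
    return GridSearchResult(
        table=table, selected=best[1],
        selection_rule="min validation RMSE; ties -> fewer layers, smaller dim, fewer epochs",
        best_model=best[2],
    )


def build_feature_set(
    panel: StatePanel,
    combo: SourceCombination,
    lag: LagSpec = LagSpec(),
    w: int = 2,
) -> list[WindowSample]:
    """Windowed samples for one source combination (delegates to windowing)."""
    from .windowing import make_windows
    missing = [s.value for s in combo.sources if s.value not in panel.sources.columns]
    if missing:
        raise ValueError(f"panel for {panel.state} lacks sources {missing}")
    return make_windows(panel, list(combo.sources), w=w, lag=lag,
                        include_lagged_deaths=combo.include_lagged_deaths)
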