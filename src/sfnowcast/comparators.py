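"""Sensitivity-analysis comparators: per-stream ensemble and PCA fusion.

Two alternative multi-source pipelines are run head-to-head against the LSTM
nowcaster on identical panels:

* **Two-phase ensemble** — phase 1 fits a pool of six regression families
  (elastic net, LASSO, linear, random forest, ridge, support-vector) to each
  individual data stream's windowed features and keeps, per stream, the
  family with the lowest validation RMSE; phase 2 trains a small feed-forward
  neural network (one hidden layer, width 8) on the validation-period
  per-stream predictions to combine them into a single weekly estimate.
* **PCA fusion** — all streams' windowed features are concatenated per
  sample, standardized, projected onto the principal components fit on
  training samples only (smallest count reaching a 90% explained-variance
  target), and the six regression families compete on the component scores;
  the lowest-validation-RMSE family is kept.

Both emit nonnegative, order-aligned weekly predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .panel import PROXY_SOURCES, SourceKind, StatePanel
from .windowing import (FeatureScaler, LagSpec, SplitSpec, WindowSample,
                        apply_scaler, fit_scaler, flat_features, make_windows,
                        split_windows, targets)

CANDIDATE_FAMILIES = ("elastic_net", "lasso", "linear", "random_forest", "ridge",
                      "support_vector")


def _make_regressor(family: str, seed: int):
    if family == "elastic_net":
        return ElasticNet(random_state=seed)
    if family == "lasso":
        return Lasso(random_state=seed)
    if family == "linear":
        return LinearRegression()
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed)
    if family == "ridge":
        return Ridge(random_state=seed)
    if family == "support_vector":
        return SVR()
    raise ValueError(f"unknown candidate family {family!r}")


class _MeanPredictor:
    """Fallback for a zero-variance stream: always predicts the train mean."""

    def __init__(self, mean: float):
        self.mean = mean

    def predict(self, X):
        return np.full(len(X), self.mean)


@dataclass
class StreamModelChoice:
    source: str
    family: str
    model: object
    val_rmse: float
    rmse_table: pd.DataFrame  # family, val_rmse


def _stream_windows(panel, source: SourceKind | str, w, lag, eligible_first):
    """Windows for one stream, restricted to a common eligible target range."""
    if source == "deaths_lagged":
        samples = make_windows(panel, [], w=w, lag=lag, include_lagged_deaths=True)
    else:
        samples = make_windows(panel, [source], w=w, lag=lag)
    return [s for s in samples if s.target_week in eligible_first]


def _fit_stream(X, y, Xval, yval, seed):
    rows = []
    best = None
    if X.std() == 0 or np.allclose(X.std(axis=0), 0):
        warnings.warn("zero-variance stream: using train-mean predictor", stacklevel=2)
        model = _MeanPredictor(float(y.mean()))
        r = float(np.sqrt(np.mean((model.predict(Xval) - yval) ** 2)))
        return model, "train_mean", r, pd.DataFrame({"family": ["train_mean"], "val_rmse": [r]})
    for fam in CANDIDATE_FAMILIES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = _make_regressor(fam, seed)
            model.fit(X, y)
        r = float(np.sqrt(np.mean((model.predict(Xval) - yval) ** 2)))
        rows.append((fam, r))
        if best is None or r < best[0]:
            best = (r, fam, model)
    return best[2], best[1], best[0], pd.DataFrame(rows, columns=["family", "val_rmse"])


@dataclass
class TwoPhaseEnsemble:
    streams: list[str]
    choices: dict[str, StreamModelChoice]
    scalers: dict[str, FeatureScaler]
    combiner: MLPRegressor
    w: int
    lag: LagSpec


def _ensemble_streams(panel: StatePanel, include_lagged_deaths: bool) -> list:
    streams = [s for s in PROXY_SOURCES if s.value in panel.sources.columns]
    return streams + (["deaths_lagged"] if include_lagged_deaths else [])


def fit_two_phase_ensemble(
    panel: StatePanel,
    splits: SplitSpec = SplitSpec(),
    seed: int = 0,
    w: int = 2,
    lag: LagSpec = LagSpec(),
    include_lagged_deaths: bool = True,
) -> TwoPhaseEnsemble:
    """Fit the per-stream + neural-combiner ensemble on one state's panel."""
    streams = _ensemble_streams(panel, include_lagged_deaths)
    if not streams:
        raise ValueError("panel has no streams")
    # common eligible target weeks: the most restrictive stream (lagged deaths)
    ref = make_windows(panel, [], w=w, lag=lag, include_lagged_deaths=True) \
        if include_lagged_deaths else make_windows(
            panel, [s for s in streams if isinstance(s, SourceKind)][:1], w=w, lag=lag)
    eligible = {s.target_week for s in ref}

    choices: dict[str, StreamModelChoice] = {}
    scalers: dict[str, FeatureScaler] = {}
    val_pred_cols = []
    yval_ref = None
    for stream in streams:
        name = stream.value if isinstance(stream, SourceKind) else stream
        samples = _stream_windows(panel, stream, w, lag, eligible)
        train, val, _ = split_windows(samples, splits)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaler = fit_scaler(train)
        scalers[name] = scaler
        Xtr = flat_features(apply_scaler(scaler, train))
        Xva = flat_features(apply_scaler(scaler, val))
        ytr, yva = targets(train), targets(val)
        model, fam, vrmse, table = _fit_stream(Xtr, ytr, Xva, yva, seed)
        choices[name] = StreamModelChoice(name, fam, model, vrmse, table)
        val_pred_cols.append(model.predict(Xva))
        yval_ref = yva

    P = np.column_stack(val_pred_cols)
    combiner = MLPRegressor(hidden_layer_sizes=(8,), random_state=seed,
                            max_iter=5000, solver="lbfgs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        combiner.fit(P, yval_ref)
    names = [s.value if isinstance(s, SourceKind) else s for s in streams]
    return TwoPhaseEnsemble(streams=names, choices=choices, scalers=scalers,
                            combiner=combiner, w=w, lag=lag)


def _ensemble_stream_preds(model: TwoPhaseEnsemble, panel: StatePanel,
                           target_weeks: set) -> tuple[np.ndarray, np.ndarray, list]:
    cols, y, weeks_out = [], None, None
    for name in model.streams:
        stream = name if name == "deaths_lagged" else SourceKind(name)
        samples = _stream_windows(panel, stream, model.w, model.lag, target_weeks)
        X = flat_features(apply_scaler(model.scalers[name], samples))
        cols.append(model.choices[name].model.predict(X))
        y = targets(samples)
        weeks_out = [s.target_week for s in samples]
    return np.column_stack(cols), y, weeks_out


def predict_ensemble(model: TwoPhaseEnsemble, panel: StatePanel,
                     target_weeks: set) -> tuple[np.ndarray, np.ndarray]:
    """(predictions, actuals) over the requested target weeks, week-ordered."""
    P, y, _ = _ensemble_stream_preds(model, panel, target_weeks)
    return np.maximum(model.combiner.predict(P), 0.0), y


@dataclass
class FusionModel:
    feature_names: list[str]
    scaler: FeatureScaler
    components: np.ndarray            # (k, d) loadings, mutually orthogonal
    explained_variance_ratio: np.ndarray
    train_mean: np.ndarray            # PCA centering vector
    family: str
    model: object
    candidate_table: pd.DataFrame
    w: int
    lag: LagSpec
    include_lagged_deaths: bool
    sources: list[SourceKind] = field(default_factory=list)


def fit_pca_fusion(
    panel: StatePanel,
    splits: SplitSpec = SplitSpec(),
    variance_target: float = 0.90,
    seed: int = 0,
    w: int = 2,
    lag: LagSpec = LagSpec(),
    include_lagged_deaths: bool = True,
) -> FusionModel:
    """Concatenate all streams' windowed features, reduce with PCA, and fit
    the best of the six regression families on the component scores."""
    if not (0 < variance_target <= 1):
        raise ValueError(f"variance_target {variance_target} outside (0, 1]")
    sources = [s for s in PROXY_SOURCES if s.value in panel.sources.columns]
    samples = make_windows(panel, sources, w=w, lag=lag,
                           include_lagged_deaths=include_lagged_deaths)
    train, val, _ = split_windows(samples, splits)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaler = fit_scaler(train)
    Xtr = flat_features(apply_scaler(scaler, train))
    Xva = flat_features(apply_scaler(scaler, val))
    ytr, yva = targets(train), targets(val)

    full = PCA(random_state=seed)
    full.fit(Xtr)
    cum = np.cumsum(full.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, Xtr.shape[0], Xtr.shape[1])
    components = full.components_[:k]
    evr = full.explained_variance_ratio_[:k]
    mean = full.mean_
    Str = (Xtr - mean) @ components.T
    Sva = (Xva - mean) @ components.T

    model, fam, _, table = _fit_stream(Str, ytr, Sva, yva, seed)
    return FusionModel(
        feature_names=list(train[0].feature_names), scaler=scaler,
        components=components, explained_variance_ratio=evr, train_mean=mean,
        family=fam, model=model, candidate_table=table, w=w, lag=lag,
        include_lagged_deaths=include_lagged_deaths, sources=sources,
    )


def predict_fusion(model: FusionModel, samples: list[WindowSample]) -> np.ndarray:
    """Nonnegative weekly predictions for pre-built windowed samples."""
    if samples and list(samples[0].feature_names) != model.feature_names:
        raise ValueError(
            f"sample layout {samples[0].feature_names} != model layout {model.feature_names}")
    X = flat_features(apply_scaler(model.scaler, samples))
    S = (X - model.train_mean) @ model.components.T
    return np.maximum(model.model.predict(S), 0.0)


def predict_comparator(model, panel_or_samples, target_weeks: set | None = None):
    """Uniform prediction surface for both comparator kinds."""
    if isinstance(model, TwoPhaseEnsemble):
        return predict_ensemble(model, panel_or_samples, target_weeks)[0]
    if isinstance(model, FusionModel):
        return predict_fusion(model, panel_or_samples)
    raise TypeError(f"not a comparator model: {type(model)!r}")
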