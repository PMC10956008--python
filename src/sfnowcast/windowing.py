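"""Supervised sliding windows over a state panel, year-based splits, scaling.

Each :class:`WindowSample` pairs a ``w``-week feature block (default w=2: the
target week and the week before it) with the target week's death count. When
historical deaths are used as a predictor they enter only at a lag of at least
one year (default 52 ISO weeks), emulating the real-world reporting delay of
vital-statistics data: the feature block for target week ``t`` then contains
deaths at weeks ``t - lag - w + 1 .. t - lag``.

Splits are by the target week's ISO year (train 2016 / validation 2017 /
test 2018 by default); feature context may reach back across a year boundary,
so the first week of a year is predicted from the last week of the previous
year plus itself.

Feature standardization is fit on training windows only and applied unchanged
to validation and test windows; targets are never scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import SourceKind, StatePanel


@dataclass(frozen=True)
class LagSpec:
    """Minimum delay, in weeks, at which historical deaths may be used as a
    predictor. At least one operational year (52 ISO weeks)."""

    lag_weeks: int = 52

    def __post_init__(self):
        if self.lag_weeks < 52:
            raise ValueError(f"lag_weeks {self.lag_weeks} < 52: deaths must lag at least one year")


@dataclass(frozen=True)
class SplitSpec:
    train_year: int = 2016
    val_year: int = 2017
    test_year: int = 2018

    def __post_init__(self):
        if not (self.train_year < self.val_year < self.test_year):
            raise ValueError("split years must be distinct and ordered train < val < test")


@dataclass
class WindowSample:
    """One supervised example.

    ``features`` has shape (w, n_features); rows are consecutive weeks ending
    at the target week. Columns are the selected proxy sources followed, if
    requested, by the lagged-deaths feature (whose row ``k`` holds deaths at
    week ``target - lag - w + 1 + k``).
    """

    features: np.ndarray
    target_week: tuple[int, int]
    target: float
    feature_names: list[str] = field(default_factory=list)

    @property
    def target_year(self) -> int:
        return self.target_week[0]


class WindowingError(ValueError):
    pass


def make_windows(
    panel: StatePanel,
    sources: list[SourceKind],
    w: int = 2,
    lag: LagSpec = LagSpec(),
    include_lagged_deaths: bool = False,
) -> list[WindowSample]:
    """Build one sample per eligible target week, in week order.

    Sample count is T - w + 1 without lagged-death features and
    T - lag - w + 1 with them (T = panel length).
    """
    if w < 1:
        raise WindowingError("window length must be >= 1")
    for s in sources:
        if s.is_outcome:
            raise WindowingError("deaths cannot be a same-week predictor; use include_lagged_deaths")
        if s.value not in panel.sources.columns:
            raise WindowingError(f"panel for {panel.state} lacks source {s.value}")
    T = panel.n_weeks
    L = lag.lag_weeks
    first = w - 1 if not include_lagged_deaths else L + w - 1
    if first >= T:
        need = (w if not include_lagged_deaths else L + w)
        raise WindowingError(
            f"panel length {T} too short: need more than "
            f"{need - 1} weeks for w={w}" + (f", lag={L}" if include_lagged_deaths else "")
        )
    X = panel.sources[[s.value for s in sources]].to_numpy(dtype=float) if sources else \
        np.zeros((T, 0))
    deaths = panel.deaths.astype(float)
    names = [s.value for s in sources] + (["deaths_lagged"] if include_lagged_deaths else [])
    samples = []
    for t in range(first, T):
        block = X[t - w + 1: t + 1, :]
        if include_lagged_deaths:
            lag_col = deaths[t - L - w + 1: t - L + 1].reshape(w, 1)
            block = np.concatenate([block, lag_col], axis=1)
        samples.append(WindowSample(features=block.copy(), target_week=panel.weeks[t],
                                    target=float(deaths[t]), feature_names=list(names)))
    return samples


def split_windows(
    samples: list[WindowSample], spec: SplitSpec = SplitSpec()
) -> tuple[list[WindowSample], list[WindowSample], list[WindowSample]]:
    """Partition samples by the ISO year of their target week."""
    train = [s for s in samples if s.target_year == spec.train_year]
    val = [s for s in samples if s.target_year == spec.val_year]
    test = [s for s in samples if s.target_year == spec.test_year]
    for name, part, year in (("train", train, spec.train_year),
                             ("val", val, spec.val_year),
                             ("test", test, spec.test_year)):
        if not part:
            raise WindowingError(f"{name} split (year {year}) is empty")
    return train, val, test


@dataclass
class FeatureScaler:
    """Per-feature affine standardization, estimated on training windows only."""

    mean: np.ndarray   # (n_features,)
    scale: np.ndarray  # (n_features,), zero-variance features get scale 1

    def transform(self, samples: list[WindowSample]) -> list[WindowSample]:
        out = []
        for s in samples:
            out.append(WindowSample(
                features=(s.features - self.mean) / self.scale,
                target_week=s.target_week, target=s.target,
                feature_names=list(s.feature_names)))
        return out


def fit_scaler(train: list[WindowSample]) -> FeatureScaler:
    """Column-wise mean/sd over all window rows of the training samples.

    Targets are untouched; zero-variance features get unit scale (warning).
    """
    if not train:
        raise WindowingError("cannot fit a scaler on an empty training set")
    stacked = np.concatenate([s.features for s in train], axis=0)  # (n*w, F)
    mean = stacked.mean(axis=0)
    scale = stacked.std(axis=0)
    flat = scale == 0
    if flat.any():
        names = train[0].feature_names
        bad = [names[i] if i < len(names) else str(i) for i in np.flatnonzero(flat)]
        warnings.warn(f"zero-variance features {bad}: scale set to 1", stacklevel=2)
        scale = np.where(flat, 1.0, scale)
    return FeatureScaler(mean=mean, scale=scale)


def apply_scaler(scaler: FeatureScaler, samples: list[WindowSample]) -> list[WindowSample]:
    return scaler.transform(samples)


def stack_features(samples: list[WindowSample]) -> np.ndarray:
    """(n, w, F) tensor for sequence models."""
    return np.stack([s.features for s in samples])


def flat_features(samples: list[WindowSample]) -> np.ndarray:
    """(n, w*F) matrix for non-sequence regressors (row-major over weeks)."""
    return np.stack([s.features.ravel() for s in samples])


def targets(samples: list[WindowSample]) -> np.ndarray:
    return np.array([s.target for s in samples])
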