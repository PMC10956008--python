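"""Synthetic multi-state worlds for offline testing of the nowcasting pipeline.

The real study inputs (vital-statistics death counts, syndromic-surveillance
ED visits, PHQ-9 screening means, search-trend scores, social-media post
counts) are restricted or API-bound. This module generates weekly panels with
the same statistical shape so every downstream stage is testable:

* a latent weekly mortality intensity ``lambda_t`` that is log-linear with an
  annual sinusoid and an AR(1) disturbance,
* Poisson death counts with mean ``lambda_t`` (weeks with zero deaths are
  possible, as in small-state data),
* proxy streams correlated with the latent signal at source-specific lags,
  gains and noise levels, each drawn in its own value family — Poisson counts,
  clipped Gaussian bounded means, or Gaussian signals max-normalized to the
  0-100 trend-score scale.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import weeks as wk
from .panel import SourceKind, StatePanel, ValueDomain


class StationarityError(ValueError):
    """AR(1) coefficient outside (-1, 1)."""


class SourceConfigError(ValueError):
    """Source family incompatible with the source kind's value domain."""


@dataclass
class LatentConfig:
    """Parameters of the latent weekly mortality intensity.

    lambda_t = exp(intercept + trend_per_week*t
                   + seasonal_amplitude*sin(2*pi*t/52 + seasonal_phase) + u_t)
    with u_t = ar_coefficient*u_{t-1} + eps_t, eps_t ~ N(0, ar_noise_sd^2).

    ``intercept`` is on the log scale: exp(intercept) is the baseline weekly
    death count.
    """

    intercept: float = np.log(15.0)
    trend_per_week: float = 0.0005
    seasonal_amplitude: float = 0.3
    seasonal_phase: float = 0.0
    ar_coefficient: float = 0.6
    ar_noise_sd: float = 0.15

    def validate(self) -> None:
        if abs(self.ar_coefficient) >= 1:
            raise StationarityError(f"ar_coefficient {self.ar_coefficient} not in (-1, 1)")
        if self.seasonal_amplitude < 0 or self.ar_noise_sd < 0:
            raise ValueError("seasonal_amplitude and ar_noise_sd must be >= 0")


_FAMILIES = ("poisson_count", "gaussian_bounded", "trend_score")
_DOMAIN_FAMILY = {
    ValueDomain.COUNT: "poisson_count",
    ValueDomain.BOUNDED_MEAN: "gaussian_bounded",
    ValueDomain.TREND_SCORE: "trend_score",
}


@dataclass
class SourceConfig:
    """How one proxy stream tracks the latent intensity.

    Clean signal: s_t = baseline + gain * lambda_{t - lag_weeks}; the observed
    value is drawn per ``family``.
    """

    source: SourceKind
    lag_weeks: int = 0
    gain: float = 1.0
    baseline: float = 0.0
    noise_sd: float = 0.0
    family: str = ""

    def __post_init__(self):
        if not self.family:
            self.family = _DOMAIN_FAMILY[self.source.domain]

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise SourceConfigError(f"unknown family {self.family!r}")
        if self.family != _DOMAIN_FAMILY[self.source.domain]:
            raise SourceConfigError(
                f"family {self.family!r} incompatible with {self.source.value} "
                f"(domain {self.source.domain.value})"
            )
        if not (0 <= self.lag_weeks <= 8):
            raise SourceConfigError(f"lag_weeks {self.lag_weeks} outside [0, 8]")
        if self.noise_sd < 0:
            raise SourceConfigError("noise_sd must be >= 0")


def default_sources() -> list[SourceConfig]:
    """The informative default: every proxy tracks the latent intensity with
    gain >= 1 (PHQ-9 excepted: its 0-27 scale forces a sub-unit gain) and
    additive noise well below the signal's spread."""
    return [
        SourceConfig(SourceKind.GOOGLE_TRENDS, lag_weeks=0, gain=2.0, baseline=0.0, noise_sd=0.8),
        SourceConfig(SourceKind.YOUTUBE_TRENDS, lag_weeks=0, gain=1.5, baseline=5.0, noise_sd=0.6),
        SourceConfig(SourceKind.TWITTER, lag_weeks=0, gain=3.0, baseline=5.0),
        SourceConfig(SourceKind.ED_VISITS, lag_weeks=0, gain=2.0, baseline=2.0),
        SourceConfig(SourceKind.PHQ9, lag_weeks=0, gain=0.5, baseline=4.0, noise_sd=0.2),
    ]


@dataclass
class ScenarioConfig:
    """A full synthetic world: states, weeks, populations, latent processes,
    per-source stream configs and a master seed.

    ``n_weeks`` defaults to 208 = 4 x 52 nominal weeks spanning 2015-2018, so
    year-based train(2016)/validation(2017)/test(2018) splits plus the 2015
    context needed by one-year-lagged death features all exist.
    """

    states: list[str] = field(default_factory=lambda: ["AA", "BB", "CC", "DD"])
    n_weeks: int = 208
    # 2015 has 53 ISO weeks; starting at W02 makes 208 weeks end exactly at 2018-W52
    start_week: tuple[int, int] = (2015, 2)
    population: dict[str, int] = field(default_factory=dict)
    latent: dict[str, LatentConfig] = field(default_factory=dict)
    sources: dict[str, list[SourceConfig]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for s in self.states:
            self.population.setdefault(s, 4_000_000)
            self.latent.setdefault(s, LatentConfig())
            self.sources.setdefault(s, default_sources())

    def validate(self) -> None:
        if self.n_weeks < 160:
            raise ValueError(f"n_weeks {self.n_weeks} < 160: too short for year-based splits")
        for s in self.states:
            self.latent[s].validate()
            for sc in self.sources[s]:
                sc.validate()


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests: the latent intensity, the
    drawn death counts, and each proxy's clean (pre-noise) signal."""

    latent_intensity: np.ndarray
    deaths: np.ndarray
    clean_signals: dict[str, np.ndarray] = field(default_factory=dict)


def generate_latent(cfg: LatentConfig, n_weeks: int, seed: int) -> SyntheticTruth:
    """Draw the latent intensity path and Poisson death counts."""
    cfg.validate()
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, cfg.ar_noise_sd, size=n_weeks)
    u = np.empty(n_weeks)
    prev = 0.0
    for t in range(n_weeks):
        prev = cfg.ar_coefficient * prev + eps[t]
        u[t] = prev
    t_idx = np.arange(n_weeks)
    log_lam = (cfg.intercept + cfg.trend_per_week * t_idx
               + cfg.seasonal_amplitude * np.sin(2 * np.pi * t_idx / 52 + cfg.seasonal_phase)
               + u)
    lam = np.exp(log_lam)
    deaths = rng.poisson(lam)
    return SyntheticTruth(latent_intensity=lam, deaths=deaths)


def scale_to_trend_score(series: np.ndarray) -> np.ndarray:
    """Max-normalize a nonnegative series to the 0-100 popularity-score scale.

    The maximum element maps to exactly 100; relative order is preserved.
    """
    series = np.asarray(series, dtype=float)
    m = series.max() if series.size else 0.0
    if m <= 0:
        raise ValueError("cannot trend-scale a series with no positive maximum")
    return 100.0 * (series / m)  # m/m == 1 exactly, so the peak is exactly 100


def generate_source(truth: SyntheticTruth, cfg: SourceConfig, seed: int) -> np.ndarray:
    """Draw one proxy stream from the latent intensity.

    The clean signal is baseline + gain * lambda lagged by ``lag_weeks``
    (edge weeks reuse the first available intensity); observation noise is
    drawn per the configured family.
    """
    cfg.validate()
    lam = truth.latent_intensity
    if len(lam) <= cfg.lag_weeks:
        raise ValueError("series shorter than the source lag")
    rng = np.random.default_rng(seed)
    lagged = np.concatenate([np.full(cfg.lag_weeks, lam[0]), lam[: len(lam) - cfg.lag_weeks]])
    clean = cfg.baseline + cfg.gain * lagged
    truth.clean_signals[cfg.source.value] = clean
    if cfg.family == "poisson_count":
        return rng.poisson(np.maximum(clean, 0.01)).astype(float)
    if cfg.family == "gaussian_bounded":
        obs = rng.normal(clean, cfg.noise_sd) if cfg.noise_sd > 0 else clean.copy()
        return np.clip(obs, 0.0, 27.0)
    # trend_score
    obs = rng.normal(clean, cfg.noise_sd) if cfg.noise_sd > 0 else clean.copy()
    return scale_to_trend_score(np.maximum(obs, 0.0))


def generate_scenario(cfg: ScenarioConfig) -> tuple[dict[str, StatePanel], dict[str, SyntheticTruth]]:
    """Generate one panel + truth per state. Fully seed-deterministic."""
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    panels: dict[str, StatePanel] = {}
    truths: dict[str, SyntheticTruth] = {}
    weeks_list = wk.week_range(cfg.start_week, cfg.n_weeks)
    labels = [wk.week_label(*w) for w in weeks_list]
    for state in cfg.states:
        state_seed = int(root.integers(0, 2**31 - 1))
        truth = generate_latent(cfg.latent[state], cfg.n_weeks, state_seed)
        sub = np.random.default_rng(state_seed + 1)
        cols = {}
        for sc in cfg.sources[state]:
            cols[sc.source.value] = generate_source(truth, sc, int(sub.integers(0, 2**31 - 1)))
        df = pd.DataFrame(cols, index=labels)
        panel = StatePanel(state=state, weeks=list(weeks_list), sources=df,
                           deaths=truth.deaths.astype(int), population=cfg.population[state])
        panel.validate()
        panels[state] = panel
        truths[state] = truth
    return panels, truths


def write_truth_csv(truths: dict[str, SyntheticTruth], cfg: ScenarioConfig, path) -> str:
    """Persist latent intensities and death draws (state, iso week, lambda, deaths)."""
    weeks_list = wk.week_range(cfg.start_week, cfg.n_weeks)
    rows = []
    for state, truth in truths.items():
        for (y, w), lam, d in zip(weeks_list, truth.latent_intensity, truth.deaths):
            rows.append((state, y, w, lam, int(d)))
    pd.DataFrame(rows, columns=["state", "iso_year", "iso_week", "lambda", "deaths"]) \
        .to_csv(path, index=False, lineterminator="\n")
    return str(path)


def scenario_from_yaml(path) -> ScenarioConfig:
    """Load a ScenarioConfig from YAML (see docs/methods.md for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = ScenarioConfig(
        states=list(raw.get("states", ["AA", "BB", "CC", "DD"])),
        n_weeks=int(raw.get("n_weeks", 208)),
        start_week=tuple(raw.get("start_week", (2015, 1))),
        seed=int(raw.get("seed", 0)),
    )
    for state, pop in (raw.get("population") or {}).items():
        cfg.population[state] = int(pop)
    for state, lat in (raw.get("latent") or {}).items():
        cfg.latent[state] = replace(LatentConfig(), **lat)
    for state, src_list in (raw.get("sources") or {}).items():
        cfg.sources[state] = [
            SourceConfig(source=SourceKind(d.pop("source")), **d) for d in src_list
        ]
    return cfg
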