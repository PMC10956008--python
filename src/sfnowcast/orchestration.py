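"""End-to-end runs: simulate -> window -> fit -> evaluate -> report.

A :class:`RunConfig` (usually loaded from YAML) names the input panels or a
synthetic scenario, the states, the source combinations to fit, grid bounds,
the year splits, the death-lag floor, seeds and an output directory. All
randomness funnels through one seed expander so a run is reconstructible from
its config alone.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .comparators import fit_pca_fusion, fit_two_phase_ensemble, predict_ensemble, predict_fusion
from .evaluation import EvaluationReport, evaluate_model, write_report_csv
from .lstm import (NowcastConfig, build_feature_set, fit_nowcaster,
                   get_combination, grid_search, predict)
from .panel import StatePanel, read_panel_csv
from .windowing import LagSpec, SplitSpec, make_windows, split_windows, targets


@dataclass
class RunConfig:
    states: list[str]
    population: dict[str, int]
    panel_csv: str | None = None           # long-format CSV with all states
    scenario: synthetic.ScenarioConfig | None = None
    combinations: list[str] = field(default_factory=lambda: ["all_sources", "historical_only"])
    grid_layers: tuple = (1, 2)
    grid_dims: tuple = (16, 32, 64)
    grid_epochs: tuple = (150, 200, 250, 300)
    do_grid_search: bool = True
    run_comparators: bool = False
    splits: SplitSpec = field(default_factory=SplitSpec)
    lag: LagSpec = field(default_factory=LagSpec)
    window: int = 2
    seed: int = 0
    out_dir: str = "runs/out"

    def validate(self) -> None:
        for s in self.states:
            if s not in self.population:
                raise ValueError(f"state {s} has no population entry")
        if self.panel_csv is None and self.scenario is None:
            raise ValueError("either panel_csv or a synthetic scenario is required")


def seed_stream(master: int, n: int) -> list[int]:
    """Expand one master seed into n child seeds (all < 2**31)."""
    rng = np.random.default_rng(master)
    return [int(x) for x in rng.integers(0, 2**31 - 1, size=n)]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scenario = None
    if "scenario" in raw and raw["scenario"]:
        sc = raw["scenario"]
        if isinstance(sc, str):
            scenario = synthetic.scenario_from_yaml(sc)
        else:
            scenario = synthetic.ScenarioConfig(
                states=list(raw["states"]),
                n_weeks=int(sc.get("n_weeks", 208)),
                seed=int(sc.get("seed", raw.get("seed", 0))),
            )
    cfg = RunConfig(
        states=list(raw["states"]),
        population={k: int(v) for k, v in raw["population"].items()},
        panel_csv=raw.get("panel_csv"),
        scenario=scenario,
        combinations=list(raw.get("combinations", ["all_sources", "historical_only"])),
        do_grid_search=bool(raw.get("do_grid_search", True)),
        run_comparators=bool(raw.get("run_comparators", False)),
        splits=SplitSpec(**raw["splits"]) if "splits" in raw else SplitSpec(),
        lag=LagSpec(**raw["lag"]) if "lag" in raw else LagSpec(),
        window=int(raw.get("window", 2)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs/out")),
    )
    cfg.validate()
    return cfg


class RunLog:
    """Line-oriented text log with ISO timestamps."""

    def __init__(self, path: Path | None):
        self.path = path
        self.lines: list[str] = []

    def log(self, msg: str) -> None:
        line = f"{_dt.datetime.now().isoformat(timespec='seconds')} {msg}"
        self.lines.append(line)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")


def load_panels(cfg: RunConfig) -> dict[str, StatePanel]:
    if cfg.panel_csv is not None:
        return {s: read_panel_csv(cfg.panel_csv, s, cfg.population[s]) for s in cfg.states}
    panels, _ = synthetic.generate_scenario(cfg.scenario)
    return {s: panels[s] for s in cfg.states}


def run_state(
    panel: StatePanel,
    cfg: RunConfig,
    log: RunLog,
    seed: int,
) -> tuple[list[EvaluationReport], list[EvaluationReport]]:
    """Fit and evaluate every requested combination (plus comparators) for one
    state. Returns (lstm_reports, comparator_reports)."""
    state = panel.state
    pop = cfg.population[state]
    reports: list[EvaluationReport] = []

    # hyperparameters are searched once on the all-sources stream and reused
    selected = NowcastConfig(seed=seed)
    if cfg.do_grid_search:
        combo = get_combination("all_sources")
        samples = build_feature_set(panel, combo, lag=cfg.lag, w=cfg.window)
        train, val, _ = split_windows(samples, cfg.splits)
        gs = grid_search(train, val, seed=seed, hidden_layers=cfg.grid_layers,
                         hidden_dims=cfg.grid_dims, epochs_grid=cfg.grid_epochs)
        selected = gs.selected
        log.log(f"{state} grid search: {len(gs.table)} configs, selected "
                f"layers={selected.hidden_layers} dim={selected.hidden_dim} "
                f"epochs={selected.epochs}")
        for _, row in gs.table.iterrows():
            log.log(f"{state} grid row layers={int(row.hidden_layers)} "
                    f"dim={int(row.hidden_dim)} epochs={int(row.epochs)} "
                    f"val_rmse={row.val_rmse:.4f}")

    for name in cfg.combinations:
        combo = get_combination(name)
        samples = build_feature_set(panel, combo, lag=cfg.lag, w=cfg.window)
        train, val, test = split_windows(samples, cfg.splits)
        model = fit_nowcaster(replace(selected, seed=seed), train, val)
        preds = predict(model, test)
        rep = evaluate_model(preds, targets(test), pop, state=state, model_name=name)
        reports.append(rep)
        log.log(f"{state} {name}: esr={rep.esr_per_100k:.3f} asr={rep.asr_per_100k:.3f} "
                f"err={rep.annual_error_pct:+.3f}% rmse={rep.rmse:.3f}")

    comp_reports: list[EvaluationReport] = []
    if cfg.run_comparators:
        test_weeks = {s.target_week for s in split_windows(
            make_windows(panel, [], w=cfg.window, lag=cfg.lag, include_lagged_deaths=True),
            cfg.splits)[2]}
        ens = fit_two_phase_ensemble(panel, cfg.splits, seed=seed, w=cfg.window, lag=cfg.lag)
        ep, ey = predict_ensemble(ens, panel, test_weeks)
        comp_reports.append(evaluate_model(ep, ey, pop, state=state, model_name="rmse_ensemble"))
        fus = fit_pca_fusion(panel, cfg.splits, seed=seed, w=cfg.window, lag=cfg.lag)
        fsamples = make_windows(panel, fus.sources, w=cfg.window, lag=cfg.lag,
                                include_lagged_deaths=fus.include_lagged_deaths)
        ftest = split_windows(fsamples, cfg.splits)[2]
        fp = predict_fusion(fus, ftest)
        comp_reports.append(evaluate_model(fp, targets(ftest), pop, state=state,
                                           model_name="pca_concatenation"))
        for rep in comp_reports:
            log.log(f"{state} {rep.model_name}: err={rep.annual_error_pct:+.3f}% "
                    f"pearson={rep.pearson:.3f}")
    return reports, comp_reports


def run_all(cfg: RunConfig, log: RunLog | None = None) -> dict[str, pd.DataFrame]:
    """Full multi-state run; writes report CSVs under cfg.out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if log is None:
        log = RunLog(out / "run.log")
    panels = load_panels(cfg)
    seeds = seed_stream(cfg.seed, len(cfg.states))
    lstm_reports, comp_reports = [], []
    for state, seed in zip(cfg.states, seeds):
        r, c = run_state(panels[state], cfg, log, seed)
        lstm_reports.extend(r)
        comp_reports.extend(c)
    write_report_csv(lstm_reports, out / "report_lstm.csv")
    result = {"lstm": pd.DataFrame([r.to_row() for r in lstm_reports])}
    if comp_reports:
        write_report_csv(comp_reports, out / "report_comparators.csv")
        result["comparators"] = pd.DataFrame([r.to_row() for r in comp_reports])
    return result
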