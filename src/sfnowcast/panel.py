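"""Weekly multi-source state panel: data model, CSV I/O, validation, alignment.

A :class:`StatePanel` is the aligned weekly matrix of proxy-source values plus
the weekly suicide death counts and a population denominator for one state.
Six source kinds exist; ``deaths`` is the outcome and is never available as a
same-week predictor downstream.

Panels are exchanged as long-format CSV with columns
``state,source,iso_year,iso_week,value`` (UTF-8, header row). This avoids
date-dialect ambiguity: weeks are explicit ISO year/week integers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import weeks as wk

PANEL_COLUMNS = ["state", "source", "iso_year", "iso_week", "value"]


class PanelFormatError(ValueError):
    """CSV is structurally malformed (missing columns, unparsable cells)."""


class PanelValidationError(ValueError):
    """A record violates its source's value domain or a panel invariant."""


class PanelGapError(ValueError):
    """The weekly index has missing interior weeks."""

    def __init__(self, missing: list[tuple[int, int]], message: str | None = None):
        self.missing = list(missing)
        labels = ", ".join(wk.week_label(*m) for m in self.missing)
        super().__init__(message or f"missing weeks: {labels}")


class ValueDomain(enum.Enum):
    """Value-domain tag attached to each source kind."""

    TREND_SCORE = "trend_score"    # real in [0, 100]
    COUNT = "count"                # nonnegative integer
    BOUNDED_MEAN = "bounded_mean"  # real in [0, 27] (PHQ-9 total score scale)


class SourceKind(enum.Enum):
    """The six weekly data streams.

    ``deaths`` is the outcome variable; the five others are real-time proxies.
    """

    GOOGLE_TRENDS = "google_trends"
    YOUTUBE_TRENDS = "youtube_trends"
    TWITTER = "twitter"
    ED_VISITS = "ed_visits"
    PHQ9 = "phq9"
    DEATHS = "deaths"

    @property
    def domain(self) -> ValueDomain:
        return _DOMAINS[self]

    @property
    def is_outcome(self) -> bool:
        return self is SourceKind.DEATHS


_DOMAINS = {
    SourceKind.GOOGLE_TRENDS: ValueDomain.TREND_SCORE,
    SourceKind.YOUTUBE_TRENDS: ValueDomain.TREND_SCORE,
    SourceKind.TWITTER: ValueDomain.COUNT,
    SourceKind.ED_VISITS: ValueDomain.COUNT,
    SourceKind.PHQ9: ValueDomain.BOUNDED_MEAN,
    SourceKind.DEATHS: ValueDomain.COUNT,
}

PROXY_SOURCES = tuple(s for s in SourceKind if not s.is_outcome)
ONLINE_SOURCES = (SourceKind.GOOGLE_TRENDS, SourceKind.YOUTUBE_TRENDS, SourceKind.TWITTER)
HEALTH_SOURCES = (SourceKind.ED_VISITS, SourceKind.PHQ9)


def validate_value(source: SourceKind, value: float) -> str | None:
    """Return an error description if ``value`` violates the source's domain, else None."""
    if not math.isfinite(value):
        return "non-finite value"
    dom = source.domain
    if dom is ValueDomain.TREND_SCORE:
        if not (0.0 <= value <= 100.0):
            return f"trend score {value} outside [0, 100]"
    elif dom is ValueDomain.COUNT:
        if value < 0:
            return f"count {value} is negative"
        if abs(value - round(value)) > 1e-9:
            return f"count {value} is not an integer"
    elif dom is ValueDomain.BOUNDED_MEAN:
        if not (0.0 <= value <= 27.0):
            return f"mean score {value} outside [0, 27]"
    return None


@dataclass
class WeeklyRecord:
    """One long-format observation: a source's value for a state-week."""

    state: str
    source: SourceKind
    iso_year: int
    iso_week: int
    value: float

    def validate(self) -> None:
        wk.validate_week(self.iso_year, self.iso_week)
        err = validate_value(self.source, self.value)
        if err is not None:
            raise PanelValidationError(
                f"{self.state} {self.source.value} {wk.week_label(self.iso_year, self.iso_week)}: {err}"
            )


@dataclass
class StatePanel:
    """Aligned weekly matrix of sources + death counts + population for one state.

    ``weeks`` is a gap-free, duplicate-free consecutive list of ISO weeks;
    ``sources`` has one row per week and one column per proxy source kind;
    ``deaths`` aligns with ``weeks``.
    """

    state: str
    weeks: list[tuple[int, int]]
    sources: pd.DataFrame          # index: week labels; columns: source kind values
    deaths: np.ndarray             # int counts, len == len(weeks)
    population: int

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    @property
    def week_labels(self) -> list[str]:
        return [wk.week_label(*w) for w in self.weeks]

    @property
    def source_kinds(self) -> list[SourceKind]:
        return [SourceKind(c) for c in self.sources.columns]

    def week_years(self) -> np.ndarray:
        """ISO year of each week."""
        return np.array([y for y, _ in self.weeks])

    def validate(self) -> None:
        if self.n_weeks == 0:
            raise PanelValidationError(f"panel for {self.state} has no weeks")
        if self.population <= 0:
            raise PanelValidationError(f"nonpositive population {self.population} for {self.state}")
        missing = wk.consecutive(self.weeks)
        if missing:
            raise PanelGapError(missing)
        if len(self.deaths) != self.n_weeks:
            raise PanelValidationError(
                f"deaths length {len(self.deaths)} != {self.n_weeks} weeks for {self.state}"
            )
        if self.sources.shape[0] != self.n_weeks:
            raise PanelValidationError("source matrix row count does not match weeks")
        if self.sources.isna().any().any():
            raise PanelValidationError("source matrix contains missing values after alignment")
        for col in self.sources.columns:
            kind = SourceKind(col)
            for label, v in zip(self.week_labels, self.sources[col].to_numpy()):
                err = validate_value(kind, float(v))
                if err is not None:
                    raise PanelValidationError(f"{self.state} {col} {label}: {err}")
        for label, d in zip(self.week_labels, self.deaths):
            err = validate_value(SourceKind.DEATHS, float(d))
            if err is not None:
                raise PanelValidationError(f"{self.state} deaths {label}: {err}")

    def restrict_weeks(self, start: tuple[int, int], end: tuple[int, int]) -> "StatePanel":
        """Panel restricted to weeks in [start, end] inclusive."""
        keep = [i for i, w in enumerate(self.weeks)
                if 0 <= wk.weeks_between(start, w) <= wk.weeks_between(start, end)]
        return StatePanel(
            state=self.state,
            weeks=[self.weeks[i] for i in keep],
            sources=self.sources.iloc[keep].copy(),
            deaths=self.deaths[keep].copy(),
            population=self.population,
        )


def panel_from_long(df: pd.DataFrame, state: str, population: int) -> StatePanel:
    """Assemble and validate a StatePanel from long-format records for one state."""
    sub = df[df["state"] == state]
    if sub.empty:
        raise PanelValidationError(f"no records for state {state!r}")
    dup = sub.duplicated(subset=["state", "source", "iso_year", "iso_week"])
    if dup.any():
        row = sub[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate record: {row['state']} {row['source']} "
            f"{wk.week_label(int(row['iso_year']), int(row['iso_week']))}"
        )
    for _, row in sub.iterrows():
        try:
            kind = SourceKind(row["source"])
        except ValueError:
            raise PanelValidationError(f"unknown source {row['source']!r}") from None
        WeeklyRecord(state, kind, int(row["iso_year"]), int(row["iso_week"]), float(row["value"])).validate()

    wide = sub.pivot_table(index=["iso_year", "iso_week"], columns="source",
                           values="value", aggfunc="first", observed=True)
    wide = wide.sort_index()
    weeks = [(int(y), int(w)) for y, w in wide.index]
    missing = wk.consecutive(weeks)
    if missing:
        raise PanelGapError(missing)
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise PanelValidationError(f"sources {bad} missing for some weeks of {state}")
    if SourceKind.DEATHS.value not in wide.columns:
        raise PanelFormatError(f"no 'deaths' series for state {state}")
    deaths = wide.pop(SourceKind.DEATHS.value).to_numpy().round().astype(int)
    wide.index = [wk.week_label(y, w) for y, w in weeks]
    wide.columns.name = None
    ordered = [s.value for s in SourceKind if s.value in wide.columns]
    panel = StatePanel(state=state, weeks=weeks, sources=wide[ordered],
                       deaths=deaths, population=int(population))
    panel.validate()
    return panel


def read_panel_csv(path, state: str, population: int) -> StatePanel:
    """Read a long-format panel CSV and return the validated panel for ``state``.

    The population denominator is not part of the CSV; it is supplied from
    configuration (one scalar per state).
    """
    try:
        df = pd.read_csv(path, dtype={"state": str, "source": str})
    except (ValueError, OSError) as exc:
        raise PanelFormatError(f"cannot read panel CSV {path}: {exc}") from exc
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelFormatError(f"panel CSV {path} missing columns: {missing_cols}")
    for col in ("iso_year", "iso_week", "value"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise PanelFormatError(f"column {col!r} is not numeric in {path}")
    return panel_from_long(df, state, population)


def panel_to_long(panel: StatePanel) -> pd.DataFrame:
    rows = []
    for i, (y, w) in enumerate(panel.weeks):
        for col in panel.sources.columns:
            rows.append((panel.state, col, y, w, float(panel.sources.iloc[i][col])))
        rows.append((panel.state, SourceKind.DEATHS.value, y, w, float(panel.deaths[i])))
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panel_csv(panel: StatePanel, path) -> str:
    """Write a panel as long-format CSV. Round-trips exactly through read_panel_csv."""
    if panel.n_weeks == 0:
        raise PanelValidationError("refusing to write an empty panel")
    panel.validate()
    df = panel_to_long(panel)
    df.to_csv(path, index=False, lineterminator="\n")
    return str(path)


def write_panels_csv(panels: list[StatePanel], path) -> str:
    """All states' long-format rows in one CSV."""
    if not panels:
        raise PanelValidationError("no panels to write")
    df = pd.concat([panel_to_long(p) for p in panels], ignore_index=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return str(path)


def align_panels(panels: list[StatePanel], policy: str = "strict") -> list[StatePanel]:
    """Restrict all panels to the intersection of their week ranges.

    policy "strict": any interior gap is an error.
    policy "interpolate": gaps of at most 2 consecutive weeks are filled by
    linear interpolation (counts rounded to the nearest integer); longer gaps
    are errors. Interpolation happens before intersection.
    """
    if policy not in ("strict", "interpolate"):
        raise ValueError(f"unknown alignment policy {policy!r}")
    if not panels:
        return []
    srcs = {tuple(p.sources.columns) for p in panels}
    if len(srcs) != 1:
        raise PanelValidationError(f"panels do not share a source set: {sorted(srcs)}")

    fixed = [_fill_gaps(p) if policy == "interpolate" else p for p in panels]
    for p in fixed:
        missing = wk.consecutive(p.weeks)
        if missing:
            raise PanelGapError(missing)

    start = max((p.weeks[0] for p in fixed), key=lambda w: wk.week_to_monday(*w))
    end = min((p.weeks[-1] for p in fixed), key=lambda w: wk.week_to_monday(*w))
    if wk.weeks_between(start, end) < 0:
        raise PanelValidationError("panels have no overlapping weeks")
    out = [p.restrict_weeks(start, end) for p in fixed]
    for p in out:
        p.validate()
    return out


def _fill_gaps(panel: StatePanel, max_gap: int = 2) -> StatePanel:
    missing = wk.consecutive(panel.weeks)
    if not missing:
        return panel
    # reject any run of >max_gap consecutive missing weeks
    runs: list[list[tuple[int, int]]] = [[missing[0]]]
    for m in missing[1:]:
        if wk.weeks_between(runs[-1][-1], m) == 1:
            runs[-1].append(m)
        else:
            runs.append([m])
    too_long = [r for r in runs if len(r) > max_gap]
    if too_long:
        raise PanelGapError(
            [m for r in too_long for m in r],
            f"gap of {len(too_long[0])} weeks exceeds interpolation limit {max_gap}",
        )
    full_weeks = wk.week_range(panel.weeks[0], wk.weeks_between(panel.weeks[0], panel.weeks[-1]) + 1)
    pos = {w: i for i, w in enumerate(panel.weeks)}
    x_known = np.array([wk.weeks_between(full_weeks[0], w) for w in panel.weeks], dtype=float)
    x_all = np.arange(len(full_weeks), dtype=float)
    new_sources = {}
    for col in panel.sources.columns:
        y = panel.sources[col].to_numpy(dtype=float)
        filled = np.interp(x_all, x_known, y)
        if SourceKind(col).domain is ValueDomain.COUNT:
            filled = np.round(filled)
        new_sources[col] = filled
    deaths = np.round(np.interp(x_all, x_known, panel.deaths.astype(float))).astype(int)
    df = pd.DataFrame(new_sources, index=[wk.week_label(*w) for w in full_weeks])
    return StatePanel(panel.state, full_weeks, df, deaths, panel.population)
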