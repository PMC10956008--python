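"""Profile-location -> US state attribution and weekly post aggregation.

Social-media authors self-report a free-text location on their profile; posts
inherit the author's resolved state. Instead of calling geocoding web
services, resolution goes through a packaged offline gazetteer with explicit,
deterministic precedence rules:

1. a standalone uppercase USPS state-code token ("Salt Lake City, UT" -> UT);
   lowercase two-letter tokens are never treated as codes because several
   codes (IN, OR, ME, OK, LA) collide with ordinary English words,
2. a full state-name substring ("upstate new york" -> NY),
3. an unambiguous city lookup ("Denver" -> CO).

Ambiguity at any rule (two different codes, two state names, an ambiguous
city) resolves to ``None`` rather than a guess. Resolution is total: any text,
including empty, yields a state code or ``None``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import weeks as wk

_PUNCT_RE = re.compile(r"[^\w\s]")


@dataclass
class Gazetteer:
    state_names: dict[str, str]   # lowercase full name -> USPS code
    state_codes: set[str]         # USPS codes (upper)
    cities: dict[str, str]        # lowercase city name -> unique state code

    def validate(self) -> None:
        if len(self.state_codes) != 51:
            raise ValueError(f"expected 50 states + DC, got {len(self.state_codes)} codes")
        if len(self.state_names) != 51:
            raise ValueError("state_names must cover 50 states + DC")


@dataclass(frozen=True)
class ProfilePost:
    """One post: opaque author id, the author's free-text profile location,
    and the ISO week of posting."""

    author_id: str
    profile_location: str
    iso_year: int
    iso_week: int

    def __post_init__(self):
        if not self.author_id:
            raise ValueError("author_id must be nonempty")


def load_gazetteer(path=None) -> Gazetteer:
    """Load the packaged gazetteer, or one from ``path`` (CSV: kind,name,state)."""
    if path is None:
        ref = resources.files("sfnowcast").joinpath("data/gazetteer.csv")
        with ref.open() as fh:
            rows = list(csv.DictReader(fh))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    names: dict[str, str] = {}
    codes: set[str] = set()
    cities: dict[str, str] = {}
    for row in rows:
        kind, name, state = row["kind"], row["name"], row["state"].upper()
        if kind == "code":
            codes.add(name.upper())
        elif kind == "state":
            names[name.lower()] = state
        elif kind == "city":
            key = name.lower()
            if key in cities and cities[key] != state:
                raise ValueError(f"ambiguous city {name!r} in gazetteer")
            cities[key] = state
        else:
            raise ValueError(f"unknown gazetteer row kind {kind!r}")
    gaz = Gazetteer(state_names=names, state_codes=codes, cities=cities)
    gaz.validate()
    return gaz


def _normalize(text: str) -> str:
    return _PUNCT_RE.sub(" ", text).lower().strip()


def resolve_state(text: str, gazetteer: Gazetteer) -> str | None:
    """Resolve free text to a state code, or None. Deterministic and total."""
    norm = _normalize(text or "")
    if not norm:
        return None
    tokens = norm.split()
    # rule 1: standalone USPS code token. Codes must be written in uppercase:
    # several codes (IN, OR, ME, OK, LA, ...) collide with ordinary English
    # words, so "somewhere in Louisiana" must fall through to the name rule.
    raw_tokens = _PUNCT_RE.sub(" ", text).split()
    hits = {t for t in raw_tokens if t.isupper() and t in gazetteer.state_codes}
    if len(hits) == 1:
        return hits.pop()
    if len(hits) > 1:
        return None
    # rule 2: full state name substring
    padded = f" {' '.join(tokens)} "
    name_hits = {code for name, code in gazetteer.state_names.items() if f" {name} " in padded}
    if len(name_hits) == 1:
        return name_hits.pop()
    if len(name_hits) > 1:
        return None
    # rule 3: unambiguous city lookup on comma-separated segments and the full text
    segments = [_normalize(s) for s in re.split(r"[,/|]", text)] + [norm]
    city_hits = {gazetteer.cities[s] for s in segments if s in gazetteer.cities}
    if len(city_hits) == 1:
        return city_hits.pop()
    return None


def attribute_posts(
    posts: list[ProfilePost],
    gazetteer: Gazetteer,
    states: set[str] | None = None,
) -> list[tuple[ProfilePost, str]]:
    """Label posts with their author's state.

    Resolution happens once per unique author, never per post; authors whose
    location resolves to None or to a state outside ``states`` are dropped
    with all their posts. Output order follows input post order.
    """
    author_state: dict[str, str | None] = {}
    for p in posts:
        if p.author_id not in author_state:
            author_state[p.author_id] = resolve_state(p.profile_location, gazetteer)
    out = []
    for p in posts:
        st = author_state[p.author_id]
        if st is None or (states is not None and st not in states):
            continue
        out.append((p, st))
    return out


def weekly_post_counts(
    labeled_posts: list[tuple[ProfilePost, str]],
    state: str,
    start_week: tuple[int, int] | None = None,
    n_weeks: int | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Weekly post counts for one state, zero-filled over a gap-free week range.

    Returns (weeks, counts). The range defaults to [earliest, latest] post week
    for the state; weeks with no posts get an explicit 0, so the series always
    passes panel gap validation and can serve as a twitter source column.
    """
    mine = [p for p, st in labeled_posts if st == state]
    if start_week is None:
        if not mine:
            return [], np.zeros(0, dtype=int)
        start_week = min(((p.iso_year, p.iso_week) for p in mine),
                         key=lambda w: wk.week_to_monday(*w))
    if n_weeks is None:
        end = max(((p.iso_year, p.iso_week) for p in mine),
                  key=lambda w: wk.week_to_monday(*w))
        n_weeks = wk.weeks_between(start_week, end) + 1
    weeks_list = wk.week_range(start_week, n_weeks)
    index = {w: i for i, w in enumerate(weeks_list)}
    counts = np.zeros(n_weeks, dtype=int)
    for p in mine:
        i = index.get((p.iso_year, p.iso_week))
        if i is not None:
            counts[i] += 1
    return weeks_list, counts


def read_posts_csv(path) -> list[ProfilePost]:
    """Posts from CSV with columns author_id,profile_location,iso_year,iso_week."""
    with open(path, newline="") as fh:
        return [
            ProfilePost(row["author_id"], row["profile_location"],
                        int(row["iso_year"]), int(row["iso_week"]))
            for row in csv.DictReader(fh)
        ]
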