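"""ISO-8601 week arithmetic for the weekly panel index.

Weeks are identified by ``(iso_year, iso_week)`` pairs under the ISO-8601
convention (Monday-start weeks; years have 52 or 53 weeks). Labels are
rendered as ``"2016-W07"``.
"""

from __future__ import annotations

import datetime as _dt
import re

_LABEL_RE = re.compile(r"^(\d{4})-W(\d{2})$")


def week_label(iso_year: int, iso_week: int) -> str:
    """Render ``(2016, 7)`` as ``"2016-W07"``."""
    return f"{iso_year:04d}-W{iso_week:02d}"


def parse_week_label(label: str) -> tuple[int, int]:
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not an ISO week label: {label!r}")
    return int(m.group(1)), int(m.group(2))


def week_to_monday(iso_year: int, iso_week: int) -> _dt.date:
    return _dt.date.fromisocalendar(iso_year, iso_week, 1)


def validate_week(iso_year: int, iso_week: int) -> None:
    """Raise ValueError if the pair is not a real ISO week (e.g. W53 in a 52-week year)."""
    try:
        _dt.date.fromisocalendar(iso_year, iso_week, 1)
    except ValueError as exc:
        raise ValueError(f"invalid ISO week {week_label(iso_year, iso_week)}: {exc}") from None


def next_week(iso_year: int, iso_week: int) -> tuple[int, int]:
    d = week_to_monday(iso_year, iso_week) + _dt.timedelta(days=7)
    y, w, _ = d.isocalendar()
    return y, w


def week_range(start: tuple[int, int], n_weeks: int) -> list[tuple[int, int]]:
    """``n_weeks`` consecutive ISO weeks beginning at ``start``."""
    out = [start]
    for _ in range(n_weeks - 1):
        out.append(next_week(*out[-1]))
    return out


def weeks_between(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Signed number of weeks from a to b (b - a)."""
    return (week_to_monday(*b) - week_to_monday(*a)).days // 7


def consecutive(weeks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Return the list of missing weeks that break consecutiveness (empty if none)."""
    missing: list[tuple[int, int]] = []
    for prev, cur in zip(weeks, weeks[1:]):
        gap = weeks_between(prev, cur)
        if gap <= 0:
            raise ValueError(f"weeks out of order or duplicated: {week_label(*prev)} -> {week_label(*cur)}")
        step = prev
        for _ in range(gap - 1):
            step = next_week(*step)
            missing.append(step)
    return missing
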