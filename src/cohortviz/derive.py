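"""Derived per-subject and aggregate variables consumed by the renderers.

This module turns joined HICDEP tables into analysis-ready structures: one
timeline per subject for the longitudinal/survival panel (anchor date,
truncated follow-up, event flag, day-indexed observations, group label,
optional death marker), and one (country, year) proportion table for the
choropleths.

Day arithmetic is exact calendar-day difference with day 0 at the anchor
date.  Subjects whose event falls beyond ``maxtime`` are administratively
censored at ``maxtime`` rather than excluded, matching standard
product-limit truncation.  The death-attribution window is inclusive: an
observation exactly ``window`` days before the event still qualifies.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .expressions import subset_mask
from .hicdep_io import CohortData
from .spec_config import Panel1Spec

TRUE_TOKENS = {"1", "y", "yes", "true", "t"}


@dataclass
class SubjectTimeline:
    """One subject's follow-up on the panel clock (day 0 = start date)."""

    id: object
    start_date: dt.date
    followup_day: int
    event: bool
    observations: list[tuple[int, float]]
    group: str
    event_marker: tuple[int, float] | None = None


@dataclass
class CountryYearTable:
    """Per-(country, year) indicator counts and proportions."""

    rows: pd.DataFrame  # columns iso3, year, numerator, denominator, proportion

    def __post_init__(self) -> None:
        df = self.rows
        if len(df) and not ((df["denominator"] > 0).all()
                            and df["proportion"].between(0, 1).all()):
            raise DataError("country-year table violates count invariants")


def select_start_date(dates: Iterable[dt.date | None], starttype: str) -> dt.date | None:
    """Earliest (``first``) or latest (``last``) non-missing date; None if none."""
    valid = [d for d in dates if d is not None]
    if not valid:
        return None
    return min(valid) if starttype == "first" else max(valid)


def compute_follow_up(
    start: dt.date, end: dt.date, event: bool, maxtime: int
) -> tuple[int, bool]:
    """Calendar-day follow-up truncated at ``maxtime``.

    Beyond ``maxtime`` the subject is administratively censored: the event
    flag is dropped along with the excess time.
    """
    if end < start:
        raise DataError(f"end date {end} precedes start date {start}")
    raw = (end - start).days
    if raw > maxtime:
        return maxtime, False
    return raw, bool(event)


def attribute_last_value(
    observations: Sequence[tuple[int, float]], event_day: int, window: int
) -> float | None:
    """Latest observation at most ``window`` days (inclusive) before the event."""
    best_day, best_value = None, None
    for day, value in observations:
        if day <= event_day and event_day - day <= window:
            if best_day is None or day >= best_day:
                best_day, best_value = day, value
    return best_value


_TRANSFORM_FUNCS = {
    "identity": lambda v: v,
    "sqrt": np.sqrt,
    "log": np.log,
    "log10": np.log10,
}


def transform(values, trans: str):
    """Elementwise axis transform; domain violations are hard errors.

    The transform affects plotting scale only — tick labels remain on the
    original scale — so silently producing NaN would corrupt the display.
    """
    if trans not in _TRANSFORM_FUNCS:
        raise DomainError(f"unknown transform {trans!r}")
    arr = np.asarray(values, dtype=float)
    if trans == "sqrt" and np.any(arr < 0):
        raise DomainError("sqrt transform requires values >= 0")
    if trans in ("log", "log10") and np.any(arr <= 0):
        raise DomainError(f"{trans} transform requires values > 0")
    out = _TRANSFORM_FUNCS[trans](arr)
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out


def discretize_period(date: dt.date, period: str) -> str:
    """Calendar period label that sorts chronologically as text."""
    if period == "year":
        return f"{date.year:04d}"
    if period == "quarter":
        return f"{date.year:04d}-Q{(date.month - 1) // 3 + 1}"
    if period == "month":
        return f"{date.year:04d}-{date.month:02d}"
    raise DomainError(f"unknown period {period!r}")


def baseline_value(
    observations: Sequence[tuple[dt.date, float]],
    anchor: dt.date,
    window_before: int = 180,
    window_after: int = 30,
) -> float | None:
    """Observation closest to ``anchor`` within [-window_before, +window_after].

    Ties at equal distance resolve to the earlier observation.
    """
    best = None  # (abs distance, date, value)
    for date, value in observations:
        delta = (date - anchor).days
        if -window_before <= delta <= window_after:
            key = (abs(delta), date)
            if best is None or key < (best[0], best[1]):
                best = (abs(delta), date, value)
    return None if best is None else best[2]


def aggregate_country_year(
    table: pd.DataFrame,
    country_col: str,
    year_col: str,
    indicator,
) -> CountryYearTable:
    """Count an indicator per (country, year).

    ``indicator`` is an array-like of True/False/missing aligned with
    ``table``; missing rows contribute to neither numerator nor denominator,
    and (country, year) cells with an empty denominator are omitted.
    """
    ind = pd.array(indicator, dtype="boolean")
    df = pd.DataFrame({
        "iso3": table[country_col].astype(str).to_numpy(),
        "year": table[year_col].astype(str).to_numpy(),
        "flag": ind,
    })
    df = df[df["flag"].notna()]
    if df.empty:
        return CountryYearTable(pd.DataFrame(
            columns=["iso3", "year", "numerator", "denominator", "proportion"]))
    grouped = df.groupby(["iso3", "year"], sort=True)["flag"].agg(
        numerator=lambda s: int(s.sum()), denominator="count")
    out = grouped.reset_index()
    out["proportion"] = out["numerator"] / out["denominator"]
    return CountryYearTable(out)


# ---------------------------------------------------------------------------
# Timeline assembly


def _is_true(cell) -> bool:
    if cell is None:
        return False
    if isinstance(cell, (int, float)):
        return float(cell) == 1.0
    return str(cell).strip().lower() in TRUE_TOKENS


def build_timelines(
    cohort: CohortData, spec: Panel1Spec
) -> tuple[list[SubjectTimeline], list[str]]:
    """Assemble one :class:`SubjectTimeline` per usable subject.

    Subjects lacking a start date, end date or group value are dropped with
    a warning message; group values outside ``groupsubset`` are filtered;
    observations are day-indexed from the start date, restricted to the
    truncated follow-up span, and filtered by ``longsubset``.
    """
    warnings: list[str] = []
    idf = cohort.id_field

    required = {
        "starttablename": spec.starttablename, "startdate": spec.startdate,
        "eventtablename": spec.eventtablename, "event": spec.event,
        "enddate": spec.enddate, "grouptablename": spec.grouptablename,
        "group": spec.group, "longtablename": spec.longtablename,
        "longvar": spec.longvar, "longvardate": spec.longvardate,
    }
    unset = [k for k, v in required.items() if not v]
    if unset:
        raise DataError(f"panel1 spec is missing required settings: {unset}")

    start_tbl = cohort.table(spec.starttablename)
    starts: dict = {}
    for pid, grp in start_tbl.groupby(idf, sort=False):
        chosen = select_start_date(list(grp[spec.startdate]), spec.starttype)
        if chosen is None:
            warnings.append(f"subject {pid!r}: all start dates missing; excluded")
        else:
            starts[pid] = chosen

    follow_tbl = cohort.table(spec.eventtablename)
    follow: dict = {}
    for pid, grp in follow_tbl.groupby(idf, sort=False):
        ends = [(d, _is_true(e)) for d, e in zip(grp[spec.enddate], grp[spec.event])
                if d is not None]
        if not ends:
            warnings.append(f"subject {pid!r}: no end date; excluded")
            continue
        follow[pid] = max(ends)  # latest end date wins

    group_tbl = cohort.table(spec.grouptablename)
    groups: dict = {}
    for pid, grp in group_tbl.groupby(idf, sort=False):
        vals = [v for v in grp[spec.group] if v is not None]
        if not vals:
            warnings.append(f"subject {pid!r}: missing group value; excluded")
            continue
        groups[pid] = str(vals[0])

    long_tbl = cohort.table(spec.longtablename)
    if spec.longsubset is not None:
        long_tbl = long_tbl[subset_mask(spec.longsubset, long_tbl)]
    obs: dict[object, list[tuple[dt.date, float]]] = {}
    for pid, date_cell, val_cell in zip(
        long_tbl[idf], long_tbl[spec.longvardate], long_tbl[spec.longvar]
    ):
        if date_cell is None or val_cell is None:
            continue
        try:
            value = float(val_cell)
        except (TypeError, ValueError):
            continue
        obs.setdefault(pid, []).append((date_cell, value))

    allowed = set(spec.groupsubset) if spec.groupsubset is not None else None
    timelines: list[SubjectTimeline] = []
    for pid in sorted(starts, key=str):
        if pid not in follow or pid not in groups:
            if pid not in follow:
                warnings.append(f"subject {pid!r}: no follow-up record; excluded")
            if pid not in groups:
                warnings.append(f"subject {pid!r}: no group record; excluded")
            continue
        group = groups[pid]
        if allowed is not None and group not in allowed:
            continue
        start = starts[pid]
        end, event_flag = follow[pid]
        followup_day, event = compute_follow_up(start, end, event_flag, spec.maxtime)
        days = []
        for date, value in sorted(obs.get(pid, [])):
            day = (date - start).days
            if 0 <= day <= followup_day:
                days.append((day, value))
        marker = None
        if event:
            attributed = attribute_last_value(days, followup_day, spec.long2eventwindow)
            if attributed is not None:
                marker = (followup_day, attributed)
        timelines.append(SubjectTimeline(
            id=pid, start_date=start, followup_day=followup_day, event=event,
            observations=days, group=group, event_marker=marker,
        ))
    return timelines, warnings
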