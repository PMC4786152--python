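"""Typed plot specifications parsed from ``name,specification`` CSV files.

Each plot class is driven by a small CSV the user edits directly: two
required columns ``name`` and ``specification`` (a third ``details`` column
is ignored), one row per setting.  Omitted or blank settings take documented
defaults; unknown names warn rather than fail so forward-compatible spec
files still run.

Numeric lists and pairs accept both the R-style ``c(0,25,100)`` notation and
a plain ``0,25,100``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import ConfigError, LoadError
from .expressions import Predicate, parse_expression

START_TYPES = ("first", "last")
TRANSFORMS = ("identity", "sqrt", "log", "log10")
EVENT_PERIODS = ("month", "quarter", "year")
VAR_SCALES = ("auto", "proportion", "percentage")


class UnknownSpecNameWarning(UserWarning):
    """A spec row's name is not recognized by this plot class."""


@dataclass
class Panel1Spec:
    """Longitudinal + event-probability panel configuration.

    Field defaults: 730 days of follow-up, a 360-day window for attributing
    the last longitudinal value to a death, "first" start-date selection and
    the identity transform.
    """

    id_field: str = "patient"
    longtablename: str | None = None
    longvar: str | None = None
    longvardate: str | None = None
    longsubset: Predicate | None = None
    eventtablename: str | None = None
    event: str | None = None
    enddate: str | None = None
    grouptablename: str | None = None
    group: str | None = None
    groupsubset: list[str] | None = None
    starttablename: str | None = None
    startdate: str | None = None
    starttype: str = "first"
    longvartrans: str = "identity"
    maxtime: int = 730
    long2eventwindow: int = 360
    longvarlim: tuple[float, float] | None = None
    problim: tuple[float, float] | None = None
    longticks: list[float] | None = None
    longlabel: str = "Longitudinal Value"
    timelabel: str = "Days"
    eventlabel: str = "Probability of Death"
    grouplabels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.starttype not in START_TYPES:
            raise ConfigError(f"starttype {self.starttype!r} not in {START_TYPES}")
        if self.longvartrans not in TRANSFORMS:
            raise ConfigError(f"longvartrans {self.longvartrans!r} not in {TRANSFORMS}")
        if self.maxtime <= 0:
            raise ConfigError("maxtime must be a positive number of days")
        if self.long2eventwindow < 0:
            raise ConfigError("long2eventwindow must be >= 0")
        for name in ("longvarlim", "problim"):
            pair = getattr(self, name)
            if pair is not None and not pair[0] < pair[1]:
                raise ConfigError(f"{name} must be strictly increasing, got {pair}")

    def group_label(self, value: str) -> str:
        if self.grouplabels and str(value) in self.grouplabels:
            return self.grouplabels[str(value)]
        return f"Group {value}"


@dataclass
class BubbleSpec:
    """Bubble / marginal-allocation panel configuration."""

    vartable: str | None = None
    var1: Predicate | None = None
    var2: Predicate | None = None
    vartablesubset: Predicate | None = None
    eventdate: str | None = None
    eventperiod: str = "year"
    group: str | None = None
    var1label1: str = "1"
    var1label0: str = "0"
    var2label1: str = "1"
    var2label0: str = "0"
    var1label: str = "Proportion (indicator 1)"
    var2label: str = "Proportion (indicator 2)"
    minnum: int = 10

    def __post_init__(self) -> None:
        if self.eventperiod not in EVENT_PERIODS:
            raise ConfigError(f"eventperiod {self.eventperiod!r} not in {EVENT_PERIODS}")
        if self.minnum < 0:
            raise ConfigError("minnum must be >= 0")


@dataclass
class MapSpec:
    """Temporal choropleth configuration (country × period proportions)."""

    countrytable: str | None = None
    var: str | None = None
    country: str = "country"
    year: str = "year"
    varlabel: str = "Proportion"
    varscale: str = "auto"

    def __post_init__(self) -> None:
        if self.varscale not in VAR_SCALES:
            raise ConfigError(f"varscale {self.varscale!r} not in {VAR_SCALES}")


# ---------------------------------------------------------------------------
# Value parsers


def _parse_int(name: str, text: str) -> int:
    try:
        value = float(text)
    except ValueError:
        raise ConfigError(f"{name} must be numeric, got {text!r}")
    if value != int(value):
        raise ConfigError(f"{name} must be an integer, got {text!r}")
    return int(value)


def parse_numeric_list(text: str) -> list[float]:
    """Parse ``c(0,25,100)`` or ``0,25,100`` into a list of floats."""
    body = text.strip()
    if body.lower().startswith("c(") and body.endswith(")"):
        body = body[2:-1]
    parts = [p.strip() for p in body.split(",") if p.strip()]
    if not parts:
        raise ConfigError(f"empty numeric list: {text!r}")
    try:
        return [float(p) for p in parts]
    except ValueError:
        raise ConfigError(f"non-numeric entry in list {text!r}")


def _parse_pair(name: str, text: str) -> tuple[float, float]:
    values = parse_numeric_list(text)
    if len(values) != 2:
        raise ConfigError(f"{name} needs exactly two numbers, got {text!r}")
    return (values[0], values[1])


def parse_group_labels(text: str) -> dict[str, str] | None:
    """Parse ``value = label|value = label`` pipe syntax; empty means absent."""
    if not text or not text.strip():
        return None
    labels: dict[str, str] = {}
    for part in text.split("|"):
        if "=" not in part:
            raise ConfigError(f"grouplabels entry {part!r} lacks '='")
        value, label = part.split("=", 1)
        key = value.strip()
        if key in labels:
            raise ConfigError(f"duplicate group value {key!r} in grouplabels")
        labels[key] = label.strip()
    return labels


def _parse_value_list(text: str) -> list[str]:
    body = text.strip()
    if body.lower().startswith("c(") and body.endswith(")"):
        body = body[2:-1]
    sep = "|" if "|" in body else ","
    values = [p.strip() for p in body.split(sep) if p.strip()]
    if not values:
        raise ConfigError(f"empty value list: {text!r}")
    return values


# ---------------------------------------------------------------------------
# Spec-file parsing

_PANEL1_FIELDS = {
    "id": ("id_field", str),
    "longtablename": ("longtablename", str),
    "longvar": ("longvar", str),
    "longvardate": ("longvardate", str),
    "longsubset": ("longsubset", parse_expression),
    "eventtablename": ("eventtablename", str),
    "event": ("event", str),
    "enddate": ("enddate", str),
    "grouptablename": ("grouptablename", str),
    "group": ("group", str),
    "groupsubset": ("groupsubset", _parse_value_list),
    "starttablename": ("starttablename", str),
    "startdate": ("startdate", str),
    "starttype": ("starttype", str),
    "longvartrans": ("longvartrans", str),
    "maxtime": ("maxtime", lambda t: _parse_int("maxtime", t)),
    "long2eventwindow": ("long2eventwindow", lambda t: _parse_int("long2eventwindow", t)),
    "longvarlim": ("longvarlim", lambda t: _parse_pair("longvarlim", t)),
    "problim": ("problim", lambda t: _parse_pair("problim", t)),
    "longticks": ("longticks", parse_numeric_list),
    "longlabel": ("longlabel", str),
    "timelabel": ("timelabel", str),
    "eventlabel": ("eventlabel", str),
    "grouplabels": ("grouplabels", parse_group_labels),
}

_BUBBLE_FIELDS = {
    "vartable": ("vartable", str),
    "var1": ("var1", parse_expression),
    "var2": ("var2", parse_expression),
    "vartablesubset": ("vartablesubset", parse_expression),
    "eventdate": ("eventdate", str),
    "eventperiod": ("eventperiod", str),
    "group": ("group", str),
    "var1label1": ("var1label1", str),
    "var1label0": ("var1label0", str),
    "var2label1": ("var2label1", str),
    "var2label0": ("var2label0", str),
    "var1label": ("var1label", str),
    "var2label": ("var2label", str),
    "minnum": ("minnum", lambda t: _parse_int("minnum", t)),
}

_MAP_FIELDS = {
    "countrytable": ("countrytable", str),
    "var": ("var", str),
    "country": ("country", str),
    "year": ("year", str),
    "varlabel": ("varlabel", str),
    "varscale": ("varscale", str),
}

_SPEC_KINDS = {
    "panel1": (Panel1Spec, _PANEL1_FIELDS),
    "bubble": (BubbleSpec, _BUBBLE_FIELDS),
    "map": (MapSpec, _MAP_FIELDS),
}


def read_spec_rows(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, specification) rows, skipping an optional header row."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"spec file not found: {path}")
    rows: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8-sig") as fh:
        for raw in csv.reader(fh):
            if not raw or all(not c.strip() for c in raw):
                continue
            name = raw[0].strip()
            value = raw[1].strip() if len(raw) > 1 else ""
            if name.lower() == "name" and value.lower() == "specification":
                continue  # header
            rows.append((name, value))
    return rows


def parse_spec(path: str | Path, kind: str):
    """Parse a spec file of the given kind (``panel1``, ``bubble``, ``map``).

    Recognized names bind to typed fields; blank values and omitted names
    fall back to class defaults; unknown names emit
    :class:`UnknownSpecNameWarning`.
    """
    if kind not in _SPEC_KINDS:
        raise ConfigError(f"unknown spec kind {kind!r}; expected one of {sorted(_SPEC_KINDS)}")
    cls, fields = _SPEC_KINDS[kind]
    kwargs = {}
    for name, value in read_spec_rows(path):
        if name not in fields:
            warnings.warn(f"unknown {kind} spec name {name!r} ignored", UnknownSpecNameWarning)
            continue
        if value == "":
            continue  # blank row keeps the default
        attr, converter = fields[name]
        parsed = converter(value)
        if parsed is not None:
            kwargs[attr] = parsed
    return cls(**kwargs)
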