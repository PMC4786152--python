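"""Reading, validating and joining HICDEP-style flat tables.

HICDEP (HIV Cohort Data Exchange Protocol) distributes cohort data as a set
of relational tables — patient demographics (``basic``), laboratory series
(``lab_cd4``), treatment episodes (``art``), follow-up status (``follow``) —
keyed by a shared subject identifier.  This module consumes the flat-file
subset of that layout: one RFC 4180 CSV per table, header row included,
filename equal to the table name.

Dates must be ISO 8601 ``YYYY-MM-DD``; anything else is an error rather than
a guess, because silent coercion hides cohort-data bugs.  Empty cells and the
literal ``NA`` both mean missing.  Unknown extra columns are retained
untouched so that spec expressions may reference them.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, DateParseError, LoadError, SchemaError

MISSING_TOKENS = {"", "NA"}

_ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def parse_date(text: str | None) -> dt.date | None:
    """Parse an ISO ``YYYY-MM-DD`` cell; empty/whitespace/``NA`` is missing.

    Raises :class:`DateParseError` for any other dialect, including
    syntactically ISO strings that are not valid calendar dates.
    """
    if text is None:
        return None
    stripped = text.strip()
    if stripped in MISSING_TOKENS:
        return None
    if not _ISO_DATE_RE.match(stripped):
        raise DateParseError(f"not an ISO YYYY-MM-DD date: {text!r}")
    try:
        return dt.date.fromisoformat(stripped)
    except ValueError as exc:
        raise DateParseError(f"invalid calendar date: {text!r}") from exc


@dataclass
class RawTable:
    """One HICDEP table: ordered columns and text cells (``None`` = missing)."""

    name: str
    columns: list[str]
    rows: list[list]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            dupes = sorted({c for c in self.columns if self.columns.count(c) > 1})
            raise SchemaError(f"table {self.name!r}: duplicate column(s) {dupes}")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.columns):
                raise SchemaError(
                    f"table {self.name!r} row {i}: {len(row)} cells for "
                    f"{len(self.columns)} columns"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        if name not in self.columns:
            raise KeyError(f"table {self.name!r} has no column {name!r}")
        j = self.columns.index(name)
        return [row[j] for row in self.rows]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns, dtype=object)


@dataclass
class ValidationReport:
    """Load-time problems: ``errors`` block downstream use, ``warnings`` don't."""

    errors: list[tuple[str, str, int, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, table: str, column: str, row: int, message: str) -> None:
        self.errors.append((table, column, row, message))

    def add_warning(self, table: str, column: str, row: int, message: str) -> None:
        self.warnings.append((table, column, row, message))


@dataclass
class CohortData:
    """Validated cohort: tables as DataFrames with parsed date columns.

    ``tables`` values are object-dtype DataFrames whose cells are text,
    ``datetime.date`` (declared date columns) or ``None`` (missing).
    ``subjects`` is the identifier set of the patient-level anchor table
    (the ``basic`` equivalent).
    """

    tables: dict[str, pd.DataFrame]
    id_field: str
    subjects: set
    date_columns: dict[str, list[str]] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        if name not in self.tables:
            raise KeyError(
                f"cohort has no table {name!r}; available: {sorted(self.tables)}"
            )
        return self.tables[name]


def read_table(path: str | Path, name: str | None = None) -> RawTable:
    """Read one CSV into a :class:`RawTable`, cells kept as text.

    UTF-8 with BOM is tolerated.  Missing tokens become ``None``.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    if not path.exists():
        raise LoadError(f"table file not found: {path}")
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"table {name!r}: file {path} is empty")
        rows = []
        for raw in reader:
            if not raw:
                continue  # blank line
            rows.append([None if cell in MISSING_TOKENS else cell for cell in raw])
    return RawTable(name=name, columns=[c.strip() for c in header], rows=rows)


def load_cohort(
    directory: str | Path,
    table_names: Sequence[str],
    id_field: str = "patient",
    date_columns: Mapping[str, Sequence[str]] | None = None,
    subject_table: str = "basic",
) -> tuple[CohortData, ValidationReport]:
    """Load, date-parse and cross-check a directory of HICDEP tables.

    Every requested table must exist as ``<name>.csv``.  Declared date
    columns are parsed under the strict ISO rule; invalid dates are reported
    as errors (the cell becomes missing).  Subjects appearing in non-anchor
    tables but absent from the anchor table are warned about and retained.
    """
    directory = Path(directory)
    date_columns = {k: list(v) for k, v in (date_columns or {}).items()}
    report = ValidationReport()
    tables: dict[str, pd.DataFrame] = {}

    for name in table_names:
        raw = read_table(directory / f"{name}.csv", name)
        df = raw.to_dataframe()
        if id_field not in df.columns:
            report.add_error(name, id_field, -1, f"id field {id_field!r} missing")
        for col in date_columns.get(name, []):
            if col not in df.columns:
                report.add_error(name, col, -1, "declared date column missing")
                continue
            parsed = []
            for i, cell in enumerate(df[col]):
                try:
                    parsed.append(parse_date(cell))
                except DateParseError as exc:
                    report.add_error(name, col, i, str(exc))
                    parsed.append(None)
            df[col] = pd.Series(parsed, dtype=object)
        tables[name] = df

    if subject_table not in tables:
        raise LoadError(f"anchor table {subject_table!r} not among {list(table_names)}")
    anchor = tables[subject_table]
    subjects = set(anchor[id_field].dropna()) if id_field in anchor.columns else set()

    for name, df in tables.items():
        if name == subject_table or id_field not in df.columns:
            continue
        for i, pid in enumerate(df[id_field]):
            if pid is not None and pid not in subjects:
                report.add_warning(
                    name, id_field, i,
                    f"subject {pid!r} absent from {subject_table!r}; row retained",
                )

    cohort = CohortData(
        tables=tables, id_field=id_field, subjects=subjects, date_columns=date_columns
    )
    return cohort, report


def write_cohort(cohort: CohortData, directory: str | Path, force: bool = False) -> list[Path]:
    """Write each table back to ``<name>.csv``; dates serialize as ISO."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in cohort.tables.items():
        path = directory / f"{name}.csv"
        if path.exists() and not force:
            raise LoadError(f"refusing to overwrite {path} (use force)")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(df.columns))
            for _, row in df.iterrows():
                writer.writerow(["" if v is None else _cell_text(v) for v in row])
        written.append(path)
    return written


def _cell_text(value) -> str:
    if isinstance(value, dt.date):
        return value.isoformat()
    return str(value)
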