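"""Command-line entry points: one subcommand per plot class plus `simulate`.

Each run loads the cohort (or country table), parses the plot spec, writes
the PNG frame sequence under ``<out>/scroll_images/`` and a scrubber HTML
under ``<out>/``, and prints a run report (also saved to
``<out>/run_report.txt``).  Partial frame output from a failed run is
removed.  Existing frame sequences are never overwritten without --force.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import click
import pandas as pd

from . import bubbles as bubbles_mod
from . import maps as maps_mod
from . import panel1 as panel1_mod
from .derive import CountryYearTable
from .errors import CohortVizError, DataError, LoadError
from .hicdep_io import load_cohort, read_table
from .spec_config import parse_spec
from .synthetic import SimParams, simulate_cohort, write_fixture
from .viewer import write_viewer

#: date columns parsed when loading the four standard tables
DEFAULT_DATE_COLUMNS = {
    "basic": ["enrol_d", "baseline_d"],
    "lab_cd4": ["cd4_d"],
    "art": ["art_sd"],
    "follow": ["l_alive_d"],
}
DEFAULT_TABLES = ("basic", "lab_cd4", "art", "follow")


@dataclass
class RunReport:
    plot_class: str
    frames: int
    viewer: str
    warnings: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def text(self) -> str:
        lines = [
            f"plot class : {self.plot_class}",
            f"frames     : {self.frames}",
            f"viewer     : {self.viewer}",
        ]
        for note in self.notes:
            lines.append(f"note       : {note}")
        lines.append(f"warnings   : {len(self.warnings)}")
        lines.extend(f"  - {w}" for w in self.warnings[:50])
        if len(self.warnings) > 50:
            lines.append(f"  ... and {len(self.warnings) - 50} more")
        return "\n".join(lines) + "\n"


def _prepare_output(out: Path, prefix: str, force: bool) -> Path:
    frames_dir = out / "scroll_images"
    existing = sorted(frames_dir.glob(f"{prefix}_*.png"))
    if existing and not force:
        raise LoadError(
            f"output already contains {len(existing)} {prefix} frame(s) under "
            f"{frames_dir}; rerun with --force to overwrite")
    for f in existing:
        f.unlink()
    frames_dir.mkdir(parents=True, exist_ok=True)
    return frames_dir


def _cleanup(paths: list) -> None:
    for p in paths:
        try:
            Path(p).unlink()
        except OSError:
            pass


def _finish(report: RunReport, out: Path) -> None:
    (out / "run_report.txt").write_text(report.text(), encoding="utf-8")
    click.echo(report.text(), nl=False)


def _load_default_cohort(data_dir: str, strict: bool = True):
    cohort, report = load_cohort(
        data_dir, DEFAULT_TABLES, id_field="patient",
        date_columns=DEFAULT_DATE_COLUMNS)
    if strict and not report.ok:
        first = report.errors[0]
        raise DataError(
            f"cohort failed validation with {len(report.errors)} error(s); "
            f"first: table {first[0]!r} column {first[1]!r} row {first[2]}: {first[3]}")
    return cohort, report


def run_panel1(data, spec_path, out, frame_step=1, canvas=(900, 720), force=False) -> RunReport:
    out = Path(out)
    spec = parse_spec(spec_path, "panel1")
    cohort, load_report = _load_default_cohort(data)
    frames_dir = _prepare_output(out, "panel", force)
    frameset = panel1_mod.build_frames(cohort, spec, frame_step=frame_step)
    paths = []
    try:
        paths = panel1_mod.save_frames(frameset, frames_dir, "panel", canvas=canvas)
        viewer = write_viewer(paths, "Longitudinal and event-probability panel",
                              out / "panel1_viewer.html")
    except Exception:
        _cleanup(paths)
        raise
    report = RunReport(
        plot_class="panel1", frames=len(paths), viewer=str(viewer),
        warnings=[f"{w}" for w in load_report.warnings[:20]] + frameset.warnings,
        notes=[f"subjects plotted: {len(frameset.timelines)}",
               f"groups: {', '.join(frameset.fixed.groups)}"],
    )
    _finish(report, out)
    return report


def run_bubbles(data, spec_path, out, trail=False, canvas=(900, 720), force=False) -> RunReport:
    out = Path(out)
    spec = parse_spec(spec_path, "bubble")
    cohort, load_report = _load_default_cohort(data)
    prefix = "panel3" if trail else "panel2"
    frames_dir = _prepare_output(out, prefix, force)
    series = bubbles_mod.build_bubble_series(cohort, spec)
    paths = []
    try:
        paths = bubbles_mod.save_bubble_frames(series, frames_dir, trail=trail, canvas=canvas)
        viewer = write_viewer(
            paths, "Bubble trails by group" if trail else "Bubble and marginal panel",
            out / f"{prefix}_viewer.html")
    except Exception:
        _cleanup(paths)
        raise
    suppressed = len(series.periods) * len(series.groups) - len(series.points)
    report = RunReport(
        plot_class=prefix, frames=len(paths), viewer=str(viewer),
        warnings=[f"{w}" for w in load_report.warnings[:20]],
        notes=[f"periods: {series.periods[0]}..{series.periods[-1]}",
               f"(group, period) cells below minnum or empty: {suppressed}"],
    )
    _finish(report, out)
    return report


def load_country_table(path) -> CountryYearTable:
    """Read an iso3,year,numerator,denominator,proportion CSV."""
    raw = read_table(path, "country")
    df = raw.to_dataframe()
    required = {"iso3", "year", "numerator", "denominator", "proportion"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"country table lacks column(s) {sorted(missing)}")
    for col in ("numerator", "denominator"):
        df[col] = df[col].astype(int)
    df["proportion"] = df["proportion"].astype(float)
    return CountryYearTable(df)


def run_maps(table, spec_path, boundaries_path, out, canvas=(900, 600), force=False) -> RunReport:
    out = Path(out)
    spec = parse_spec(spec_path, "map")
    country_table = load_country_table(table)
    boundaries = maps_mod.load_boundaries(boundaries_path)
    frames_dir = _prepare_output(out, "map1", force)
    _prepare_output(out, "map2", force)
    unmatched = maps_mod.unmatched_codes(boundaries, country_table)
    paths_w, paths_r = [], []
    try:
        paths_w, paths_r = maps_mod.save_map_frames(
            boundaries, country_table, frames_dir,
            varlabel=spec.varlabel, scale=spec.varscale, canvas=canvas)
        viewer_w = write_viewer(paths_w, "World map", out / "map1_viewer.html")
        viewer_r = write_viewer(paths_r, "Region map", out / "map2_viewer.html")
    except Exception:
        _cleanup(paths_w + paths_r)
        raise
    report = RunReport(
        plot_class="maps", frames=len(paths_w) + len(paths_r),
        viewer=f"{viewer_w}; {viewer_r}",
        warnings=[f"no boundary polygon for data code {c!r}" for c in unmatched],
        notes=[f"periods: {len(paths_w)} (x2 modes)",
               f"skipped boundary features without ISO-3: {boundaries.skipped}"],
    )
    _finish(report, out)
    return report


# ---------------------------------------------------------------------------
# click wiring


@click.group()
def main() -> None:
    """Animated HIV-cohort visualizations from HICDEP-style tables."""


def _canvas(text: str) -> tuple[int, int]:
    try:
        w, h = text.lower().split("x")
        return int(w), int(h)
    except ValueError:
        raise click.BadParameter(f"canvas must look like 900x720, got {text!r}")


@main.command()
@click.option("--data", required=True, type=click.Path(exists=True, file_okay=False))
@click.option("--spec", "spec_path", required=True, type=click.Path(exists=True, dir_okay=False))
@click.option("--out", required=True, type=click.Path(file_okay=False))
@click.option("--frame-step", default=1, show_default=True, type=int)
@click.option("--canvas", default="900x720", show_default=True)
@click.option("--force", is_flag=True)
def panel1(data, spec_path, out, frame_step, canvas, force):
    """Longitudinal scatter + Kaplan-Meier panel (one frame per day)."""
    _run(run_panel1, data, spec_path, out, frame_step=frame_step,
         canvas=_canvas(canvas), force=force)


@main.command()
@click.option("--data", required=True, type=click.Path(exists=True, file_okay=False))
@click.option("--spec", "spec_path", required=True, type=click.Path(exists=True, dir_okay=False))
@click.option("--out", required=True, type=click.Path(file_okay=False))
@click.option("--trail", is_flag=True, help="Darkening multi-period trails instead of mosaics.")
@click.option("--canvas", default="900x720", show_default=True)
@click.option("--force", is_flag=True)
def bubbles(data, spec_path, out, trail, canvas, force):
    """Per-period bubble plot of two indicator proportions by group."""
    _run(run_bubbles, data, spec_path, out, trail=trail,
         canvas=_canvas(canvas), force=force)


@main.command()
@click.option("--table", required=True, type=click.Path(exists=True, dir_okay=False))
@click.option("--spec", "spec_path", required=True, type=click.Path(exists=True, dir_okay=False))
@click.option("--boundaries", "boundaries_path", required=True,
              type=click.Path(exists=True, dir_okay=False))
@click.option("--out", required=True, type=click.Path(file_okay=False))
@click.option("--canvas", default="900x600", show_default=True)
@click.option("--force", is_flag=True)
def maps(table, spec_path, boundaries_path, out, canvas, force):
    """World + region choropleths of a country-year proportion table."""
    _run(run_maps, table, spec_path, boundaries_path, out,
         canvas=_canvas(canvas), force=force)


@main.command()
@click.option("--out", required=True, type=click.Path(file_okay=False))
@click.option("--seed", default=20160310, show_default=True, type=int)
@click.option("--n", "n_subjects", default=500, show_default=True, type=int)
@click.option("--params", "params_path", type=click.Path(exists=True, dir_okay=False),
              help="JSON file overriding SimParams fields.")
@click.option("--force", is_flag=True)
def simulate(out, seed, n_subjects, params_path, force):
    """Generate a synthetic HICDEP-style cohort fixture."""
    overrides = {}
    if params_path:
        overrides = json.loads(Path(params_path).read_text(encoding="utf-8"))
        valid = {f.name for f in fields(SimParams)}
        unknown = set(overrides) - valid
        if unknown:
            raise click.ClickException(f"unknown SimParams field(s): {sorted(unknown)}")
    overrides.setdefault("seed", seed)
    overrides.setdefault("n_subjects", n_subjects)
    if "sites" in overrides:
        overrides["sites"] = tuple(tuple(s) for s in overrides["sites"])
    if "enrollment_years" in overrides:
        overrides["enrollment_years"] = tuple(overrides["enrollment_years"])
    try:
        params = SimParams(**overrides)
        cohort = simulate_cohort(params)
        written = write_fixture(cohort, out, force=force)
    except CohortVizError as exc:
        raise click.ClickException(str(exc))
    click.echo(f"wrote {len(written)} tables ({params.n_subjects} subjects, "
               f"seed {params.seed}) to {out}")


def _run(func, *args, **kwargs):
    try:
        func(*args, **kwargs)
    except CohortVizError as exc:
        raise click.ClickException(str(exc))


if __name__ == "__main__":  # pragma: no cover
    main()
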