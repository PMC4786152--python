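"""Plot classes 2-3: per-period bubble plots of two indicator proportions.

One animation frame per calendar period (month/quarter/year of an anchor
date such as enrollment).  Each group contributes one bubble at
(x = proportion with indicator 2, y = proportion with indicator 1) with
bubble *area* proportional to the number of fully observed subjects.  The
class-2 frame adds per-group mosaic panels of the joint 2x2 allocation; the
class-3 frame shows, per group, a trail of all prior periods' bubbles that
darkens with age (the current period is lightest and topmost).  Both are
built from the same series, and both keep fixed [0, 1] axes so frames stay
comparable.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.colors import to_rgb
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle

from .derive import discretize_period
from .errors import DataError
from .expressions import evaluate, subset_mask
from .hicdep_io import CohortData
from .panel1 import GROUP_COLORS
from .spec_config import BubbleSpec
from .stats_core import BubblePoint, Cells, bubble_stats

MAX_BUBBLE_AREA = 2000.0  # points^2 for the largest n in the series
TRAIL_MIN_LIGHTNESS = 0.35
TRAIL_MAX_LIGHTNESS = 0.75


@dataclass
class BubbleSeries:
    """All periods' bubble points plus fixed rendering state."""

    periods: list[str]                      # chronological labels, one frame each
    points: list[BubblePoint]
    groups: list[str]
    colors: dict[str, str]
    max_n: int
    spec: BubbleSpec

    def points_for(self, period: str) -> list[BubblePoint]:
        return [p for p in self.points if p.period == period]

    def radius(self, n: int) -> float:
        """Bubble radius in points; area (radius^2) is proportional to n."""
        return float(np.sqrt(self.area(n) / np.pi))

    def area(self, n: int) -> float:
        return MAX_BUBBLE_AREA * n / self.max_n


def build_bubble_series(cohort: CohortData, spec: BubbleSpec) -> BubbleSeries:
    """Evaluate the spec's indicators and aggregate per (group, period).

    Every period observed after subsetting gets a frame, even if all of its
    points fall below ``minnum`` — an empty frame keeps the time axis honest.
    """
    for name in ("vartable", "var1", "var2", "eventdate", "group"):
        if getattr(spec, name) is None:
            raise DataError(f"bubble spec is missing required setting {name!r}")
    table = cohort.table(spec.vartable)
    if spec.vartablesubset is not None:
        table = table[subset_mask(spec.vartablesubset, table)]
    if table.empty:
        raise DataError("no data after subsetting")

    v1 = evaluate(spec.var1, table)
    v2 = evaluate(spec.var2, table)
    periods = []
    for cell in table[spec.eventdate]:
        periods.append(None if cell is None else discretize_period(cell, spec.eventperiod))
    keep = [p is not None for p in periods]
    if not any(keep):
        raise DataError("no usable anchor dates after subsetting")
    v1 = pd.array([x for x, k in zip(v1, keep) if k], dtype="boolean")
    v2 = pd.array([x for x, k in zip(v2, keep) if k], dtype="boolean")
    groups = [str(g) for g, k in zip(table[spec.group], keep) if k]
    period_list = [p for p, k in zip(periods, keep) if k]

    points = bubble_stats(v1, v2, groups, period_list, minnum=spec.minnum)
    all_periods = sorted(set(period_list))
    group_names = sorted(set(groups))
    colors = {g: GROUP_COLORS[i % len(GROUP_COLORS)] for i, g in enumerate(group_names)}
    max_n = max((p.n for p in points), default=1)
    return BubbleSeries(
        periods=all_periods, points=points, groups=group_names,
        colors=colors, max_n=max_n, spec=spec,
    )


def mosaic_rects(cells: Cells) -> list[tuple[float, float, float, float, bool, bool]]:
    """Unit-square mosaic of a 2x2 table.

    Columns split by the var2 margin (widths proportional to var2 counts,
    var2-true on the left); each column splits by var1 within (var1-true on
    top).  Returns (x0, y0, width, height, var1, var2) per nonempty cell.
    """
    n = cells.total
    if n == 0:
        return []
    n2t = cells.tt + cells.ft
    n2f = cells.tf + cells.ff
    rects = []
    x = 0.0
    for var2, width_n, top_n, bottom_n in (
        (True, n2t, cells.tt, cells.ft),
        (False, n2f, cells.tf, cells.ff),
    ):
        if width_n == 0:
            continue
        w = width_n / n
        h_top = top_n / width_n
        if bottom_n:
            rects.append((x, 0.0, w, 1.0 - h_top, False, var2))
        if top_n:
            rects.append((x, 1.0 - h_top, w, h_top, True, var2))
        x += w
    return rects


def trail_palette(base_color: str, length: int) -> list[tuple[float, float, float]]:
    """Shades for a trail of ``length`` bubbles, oldest first.

    The current (last) bubble takes the group hue at lightness 0.75; shades
    darken linearly back to lightness 0.35 at the oldest bubble, so
    luminance decreases strictly with age.
    """
    if length < 1:
        return []
    h, _, s = colorsys.rgb_to_hls(*to_rgb(base_color))
    if length == 1:
        return [colorsys.hls_to_rgb(h, TRAIL_MAX_LIGHTNESS, s)]
    out = []
    for age in range(length - 1, -1, -1):  # oldest first
        frac = age / (length - 1)
        lightness = TRAIL_MAX_LIGHTNESS - frac * (TRAIL_MAX_LIGHTNESS - TRAIL_MIN_LIGHTNESS)
        out.append(colorsys.hls_to_rgb(h, lightness, s))
    return out


def render_panel2_frame(
    series: BubbleSeries, period: str, canvas: tuple[int, int] = (900, 720),
    dpi: int = 100,
) -> Figure:
    """Bubble pane over per-group mosaic panels for one period."""
    if period not in series.periods:
        raise DataError(f"period {period!r} not in series")
    spec = series.spec
    fig = Figure(figsize=(canvas[0] / dpi, canvas[1] / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    gs = fig.add_gridspec(2, 1, height_ratios=[2, 1], hspace=0.35,
                          left=0.1, right=0.97, top=0.92, bottom=0.08)
    ax = fig.add_subplot(gs[0])
    points = series.points_for(period)
    for p in points:
        ax.scatter([p.p2], [p.p1], s=series.area(p.n),
                   color=series.colors[p.group], alpha=0.7,
                   edgecolors="black", linewidths=0.5, label=p.group)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel(spec.var2label)
    ax.set_ylabel(spec.var1label)
    ax.set_title(str(period))
    if points:
        ax.legend(loc="upper right", fontsize=7, frameon=False)

    ax2 = fig.add_subplot(gs[1])
    ax2.set_xlim(0, max(len(series.groups), 1))
    ax2.set_ylim(0, 1.25)
    ax2.axis("off")
    by_group = {p.group: p for p in points}
    for i, g in enumerate(series.groups):
        p = by_group.get(g)
        ax2.text(i + 0.5, 1.12, g, ha="center", fontsize=7)
        if p is None:
            continue
        base = to_rgb(series.colors[g])
        light = tuple(0.55 + 0.45 * c for c in base)
        for (x0, y0, w, h, v1, _v2) in mosaic_rects(p.cells):
            ax2.add_patch(Rectangle(
                (i + 0.06 + 0.88 * x0, 0.88 * y0), 0.88 * w, 0.88 * h,
                facecolor=base if v1 else light, edgecolor="white", linewidth=0.8,
            ))
    ax2.text(0.0, -0.12, f"{spec.var1label1} (dark) vs {spec.var1label0} (light); "
             f"columns: {spec.var2label1} | {spec.var2label0}",
             fontsize=7, transform=ax2.transAxes)
    return fig


def render_panel3_frame(
    series: BubbleSeries, period: str, canvas: tuple[int, int] = (900, 720),
    dpi: int = 100,
) -> Figure:
    """One pane per group showing the darkening trail up to ``period``."""
    if period not in series.periods:
        raise DataError(f"period {period!r} not in series")
    spec = series.spec
    upto = [p for p in series.periods if p <= period]
    n_groups = max(len(series.groups), 1)
    ncols = int(np.ceil(np.sqrt(n_groups)))
    nrows = int(np.ceil(n_groups / ncols))
    fig = Figure(figsize=(canvas[0] / dpi, canvas[1] / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    axes = fig.subplots(nrows, ncols, squeeze=False)
    fig.suptitle(str(period))
    for ax in axes.flat:
        ax.set_visible(False)
    for gi, g in enumerate(series.groups):
        ax = axes.flat[gi]
        ax.set_visible(True)
        shades = trail_palette(series.colors[g], len(upto))
        # oldest drawn first so the current (lightest) bubble lands on top
        for shade, per in zip(shades, upto):
            for p in series.points_for(per):
                if p.group != g:
                    continue
                ax.scatter([p.p2], [p.p1], s=series.area(p.n), color=shade,
                           edgecolors="black", linewidths=0.4, zorder=2)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_title(g, fontsize=8)
        ax.tick_params(labelsize=6)
    fig.supxlabel(spec.var2label, fontsize=9)
    fig.supylabel(spec.var1label, fontsize=9)
    return fig


def save_bubble_frames(
    series: BubbleSeries, outdir, trail: bool = False,
    canvas: tuple[int, int] = (900, 720), dpi: int = 100,
) -> list:
    """Write one PNG per period: ``panel2_0001.png`` or ``panel3_0001.png``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = "panel3" if trail else "panel2"
    render = render_panel3_frame if trail else render_panel2_frame
    paths = []
    for i, period in enumerate(series.periods):
        fig = render(series, period, canvas=canvas, dpi=dpi)
        path = outdir / f"{prefix}_{i + 1:04d}.png"
        fig.savefig(path, format="png")
        paths.append(path)
    return paths
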