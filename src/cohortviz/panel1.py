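"""Plot class 1: animated longitudinal scatter over a cumulative-event pane.

Each frame is one day (configurable step) since each subject's anchor date
— typically cART initiation.  The top pane scatters observed values up to
the frame day, with X markers where deceased subjects' last attributable
value sits, a per-group LOESS curve revealed up to the frame day, and
right-margin density curves of the current per-subject values.  The bottom
pane shows per-group Kaplan-Meier cumulative probability of death up to the
frame day.  All statistics are fit once over the whole span before the
first frame; the renderer only reveals them, so axis state never jitters
between frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.lines import Line2D

from .derive import SubjectTimeline, build_timelines, transform
from .errors import DataError
from .hicdep_io import CohortData
from .spec_config import Panel1Spec
from .stats_core import (DensityCurve, SmoothedCurve, SurvivalCurve, kde,
                         km_estimate, loess_fit)

GROUP_COLORS = (
    "#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

DOT_ALPHA = 0.2  # scatter dots are semi-transparent; X markers opaque


def frame_days(maxtime: int, step: int = 1) -> list[int]:
    """Frame schedule 0..maxtime by ``step``, terminal frame always included."""
    if step <= 0:
        raise DataError("frame step must be positive")
    days = list(range(0, maxtime + 1, step))
    if days[-1] != maxtime:
        days.append(maxtime)
    return days


def pretty_breaks(lo: float, hi: float, n: int = 5) -> list[float]:
    """~n 'pretty' axis breaks on the 1/2/5 x 10^k ladder, within [lo, hi]."""
    if hi < lo:
        lo, hi = hi, lo
    if hi == lo:
        return [lo]
    raw = (hi - lo) / n
    mag = 10.0 ** math.floor(math.log10(raw))
    step = next(m * mag for m in (1, 2, 5, 10) if m * mag >= raw)
    first = math.ceil(lo / step - 1e-9) * step
    breaks = []
    b = first
    while b <= hi + 1e-9 * step:
        breaks.append(round(b / step) * step)
        b += step
    return [0.0 if v == 0 else v for v in breaks]


def default_limits(
    timelines: list[SubjectTimeline], spec: Panel1Spec,
    km_by_group: dict[str, SurvivalCurve] | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Axis limits per the spec-sheet rules when not set explicitly.

    Longitudinal limits default to the 0.5th and 99.5th percentiles of the
    original-scale values; the event-probability upper limit defaults to 1.4
    times the highest final group rate.  Degenerate limits widen by +-5%
    (+-1 around zero).
    """
    if not timelines:
        raise DataError("no timelines to derive limits from")
    if spec.longvarlim is not None:
        longlim = spec.longvarlim
    else:
        values = np.asarray([v for tl in timelines for _, v in tl.observations])
        if values.size == 0:
            raise DataError("no observations to derive longitudinal limits from")
        lo, hi = np.percentile(values, [0.5, 99.5])
        longlim = (float(lo), float(hi))
    if longlim[0] == longlim[1]:
        v = longlim[0]
        pad = abs(v) * 0.05 if v != 0 else 1.0
        longlim = (v - pad, v + pad)

    if spec.problim is not None:
        problim = spec.problim
    else:
        if km_by_group is None:
            groups = sorted({tl.group for tl in timelines})
            km_by_group = {
                g: km_estimate(
                    [tl.followup_day for tl in timelines if tl.group == g],
                    [tl.event for tl in timelines if tl.group == g],
                )
                for g in groups
            }
        top = max(curve.final_cumulative_death for curve in km_by_group.values())
        if top == 0:
            problim = (0.0, 1.0)
        else:
            problim = (0.0, 1.4 * top)
    return longlim, problim


def axis_ticks(
    spec: Panel1Spec, limits: tuple[float, float]
) -> tuple[list[float], list[str]]:
    """Tick positions (transformed scale) and labels (original scale).

    Explicit ``longticks`` values outside the original-scale limits are
    dropped; the default is ~5 pretty breaks over the original-scale range.
    """
    lo, hi = limits
    if spec.longticks is not None:
        values = [v for v in spec.longticks if lo - 1e-9 <= v <= hi + 1e-9]
    else:
        values = pretty_breaks(lo, hi, 5)
    positions = [float(transform(v, spec.longvartrans)) for v in values]
    labels = [f"{v:g}" for v in values]
    return positions, labels


@dataclass
class FixedState:
    """Axis and statistical state shared by every frame."""

    longvarlim: tuple[float, float]          # original scale
    ylim: tuple[float, float]                # transformed scale
    problim: tuple[float, float]
    tick_positions: list[float]
    tick_labels: list[str]
    groups: list[str]
    colors: dict[str, str]
    labels: dict[str, str]
    loess: dict[str, SmoothedCurve]
    km: dict[str, SurvivalCurve]
    maxtime: int


@dataclass
class FrameSet:
    """Precomputed animation state: frame schedule + fixed state + timelines."""

    frame_days: list[int]
    fixed: FixedState
    timelines: list[SubjectTimeline]
    spec: Panel1Spec
    warnings: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frame_days)

    def visible_observations(self, day: int, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(days, transformed values) of observations at or before ``day``."""
        xs, ys = [], []
        for tl in self.timelines:
            if tl.group != group:
                continue
            for d, v in tl.observations:
                if d <= day:
                    xs.append(d)
                    ys.append(v)
        return (np.asarray(xs, dtype=float),
                transform(np.asarray(ys, dtype=float), self.spec.longvartrans)
                if xs else np.asarray([]))

    def visible_markers(self, day: int, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Death markers (day, attributed transformed value) at or before ``day``."""
        xs, ys = [], []
        for tl in self.timelines:
            if tl.group == group and tl.event_marker is not None:
                md, mv = tl.event_marker
                if md <= day:
                    xs.append(md)
                    ys.append(mv)
        return (np.asarray(xs, dtype=float),
                transform(np.asarray(ys, dtype=float), self.spec.longvartrans)
                if xs else np.asarray([]))

    def current_values(self, day: int, group: str) -> np.ndarray:
        """Per-subject latest transformed value at the frame day.

        A subject contributes if still under follow-up at ``day`` and its
        last observation at or before ``day`` is no older than the
        attribution window — keeping the terminal-frame margin density
        readable as the end-of-span value distribution.
        """
        window = self.spec.long2eventwindow
        vals = []
        for tl in self.timelines:
            if tl.group != group or tl.followup_day < day:
                continue
            latest = None
            for d, v in tl.observations:
                if d <= day and day - d <= window:
                    if latest is None or d >= latest[0]:
                        latest = (d, v)
            if latest is not None:
                vals.append(latest[1])
        arr = np.asarray(vals, dtype=float)
        return transform(arr, self.spec.longvartrans) if arr.size else arr

    def frame_density(self, day: int, group: str) -> DensityCurve | None:
        vals = self.current_values(day, group)
        if np.unique(vals).size < 2:
            return None
        grid = np.linspace(self.fixed.ylim[0], self.fixed.ylim[1], 128)
        return kde(vals, grid=grid)


def build_frames(
    cohort: CohortData, spec: Panel1Spec, frame_step: int = 1,
    loess_span: float = 0.75, loess_degree: int = 1,
) -> FrameSet:
    """Derive timelines, fit all statistics once, and enumerate frames."""
    timelines, warnings = build_timelines(cohort, spec)
    if not timelines:
        raise DataError("no subjects remain after filtering")

    groups = sorted({tl.group for tl in timelines})
    colors = {g: GROUP_COLORS[i % len(GROUP_COLORS)] for i, g in enumerate(groups)}
    labels = {g: spec.group_label(g) for g in groups}

    km_by_group: dict[str, SurvivalCurve] = {}
    loess_by_group: dict[str, SmoothedCurve] = {}
    kept_groups = []
    grid = np.linspace(0, spec.maxtime, min(spec.maxtime + 1, 201))
    for g in groups:
        members = [tl for tl in timelines if tl.group == g]
        if not members:
            continue
        km_by_group[g] = km_estimate(
            [tl.followup_day for tl in members], [tl.event for tl in members],
            horizon=spec.maxtime,
        )
        xs = np.asarray([d for tl in members for d, _ in tl.observations], dtype=float)
        ys = np.asarray([v for tl in members for _, v in tl.observations], dtype=float)
        if xs.size >= loess_degree + 2 and np.unique(xs).size >= loess_degree + 2:
            loess_by_group[g] = loess_fit(
                xs, transform(ys, spec.longvartrans),
                span=loess_span, degree=loess_degree, grid=grid,
            )
        else:
            warnings.append(f"group {g!r}: too few observations for a LOESS curve")
        kept_groups.append(g)

    longlim, problim = default_limits(timelines, spec, km_by_group)
    ylim = (
        float(transform(max(longlim[0], _domain_floor(spec.longvartrans, longlim)),
                        spec.longvartrans)),
        float(transform(longlim[1], spec.longvartrans)),
    )
    positions, tick_labels = axis_ticks(spec, longlim)

    fixed = FixedState(
        longvarlim=longlim, ylim=ylim, problim=problim,
        tick_positions=positions, tick_labels=tick_labels,
        groups=kept_groups, colors=colors, labels=labels,
        loess=loess_by_group, km=km_by_group, maxtime=spec.maxtime,
    )
    return FrameSet(
        frame_days=frame_days(spec.maxtime, frame_step),
        fixed=fixed, timelines=timelines, spec=spec, warnings=warnings,
    )


def _domain_floor(trans: str, limits: tuple[float, float]) -> float:
    if trans in ("log", "log10") and limits[0] <= 0:
        return min(1.0, limits[1] / 100.0)
    if trans == "sqrt" and limits[0] < 0:
        return 0.0
    return limits[0]


def render_frame(
    frameset: FrameSet, index: int, canvas: tuple[int, int] = (900, 720), dpi: int = 100,
) -> Figure:
    """Render one frame to a matplotlib figure (Agg, deterministic)."""
    if not 0 <= index < frameset.n_frames:
        raise IndexError(f"frame index {index} out of range 0..{frameset.n_frames - 1}")
    day = frameset.frame_days[index]
    fx = frameset.fixed
    spec = frameset.spec

    fig = Figure(figsize=(canvas[0] / dpi, canvas[1] / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    gs = fig.add_gridspec(
        2, 2, width_ratios=[5, 1], height_ratios=[2, 1],
        hspace=0.28, wspace=0.05, left=0.1, right=0.97, top=0.92, bottom=0.09,
    )
    ax_scatter = fig.add_subplot(gs[0, 0])
    ax_density = fig.add_subplot(gs[0, 1], sharey=ax_scatter)
    ax_km = fig.add_subplot(gs[1, 0], sharex=ax_scatter)
    ax_legend = fig.add_subplot(gs[1, 1])
    ax_legend.axis("off")

    for g in fx.groups:
        color = fx.colors[g]
        xs, ys = frameset.visible_observations(day, g)
        if xs.size:
            ax_scatter.plot(xs, ys, ".", color=color, alpha=DOT_ALPHA,
                            markersize=3, markeredgewidth=0)
        mx, my = frameset.visible_markers(day, g)
        if mx.size:
            ax_scatter.plot(mx, my, "x", color=color, markersize=5)
        curve = fx.loess.get(g)
        if curve is not None:
            mask = curve.grid <= day
            if mask.any():
                ax_scatter.plot(curve.grid[mask], curve.fitted[mask],
                                color=color, linewidth=2)
        dens = frameset.frame_density(day, g)
        if dens is not None:
            ax_density.plot(dens.density, dens.grid, color=color, linewidth=1)
        km_xy = fx.km.get(g)
        if km_xy is not None:
            sx, sy = km_xy.step_points(min(day, fx.maxtime))
            ax_km.plot(sx, sy, color=color, linewidth=1.5)

    ax_scatter.set_xlim(0, fx.maxtime)
    ax_scatter.set_ylim(*fx.ylim)
    ax_scatter.set_yticks(fx.tick_positions)
    ax_scatter.set_yticklabels(fx.tick_labels)
    ax_scatter.set_ylabel(spec.longlabel)
    ax_scatter.set_title(f"Day {day}")
    ax_density.set_xticks([])
    ax_density.tick_params(labelleft=False)
    ax_density.set_xlabel("density", fontsize=8)
    ax_km.set_xlim(0, fx.maxtime)
    ax_km.set_ylim(*fx.problim)
    ax_km.set_xlabel(spec.timelabel)
    ax_km.set_ylabel(spec.eventlabel, fontsize=9)
    handles = [
        Line2D([], [], color=fx.colors[g], marker="o", linestyle="-",
               label=fx.labels[g])
        for g in fx.groups
    ]
    ax_legend.legend(handles=handles, loc="center", frameon=False, fontsize=8)
    return fig


def save_frames(
    frameset: FrameSet, outdir, prefix: str = "panel",
    canvas: tuple[int, int] = (900, 720), dpi: int = 100,
) -> list:
    """Write every frame as ``<prefix>_0001.png`` ... under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(frameset.n_frames):
        fig = render_frame(frameset, i, canvas=canvas, dpi=dpi)
        path = outdir / f"{prefix}_{i + 1:04d}.png"
        fig.savefig(path, format="png")
        paths.append(path)
    return paths
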