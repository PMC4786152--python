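"""Plot classes map 1-2: temporal choropleths of country-level proportions.

One frame per time period, shading each country by its binned proportion on
a sequential single-hue (red) palette, lightest for the lowest bin.  Two
modes share identical fills: ``world`` draws every boundary polygon for
context, ``region`` crops the viewport (plus a 5% margin) to the bounding
box of countries that have data in *any* period, so the viewport never
moves between frames.  Rendering uses an equirectangular (plate carree)
projection, which is adequate for choropleth reading and dependency-free.

Boundaries come from any ISO-3-keyed GeoJSON FeatureCollection (CShapes,
Natural Earth, ...); a six-country toy file ships with the package for
tests and examples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Patch, Polygon as MplPolygon
from shapely.geometry import MultiPolygon, Polygon, shape

from .derive import CountryYearTable
from .errors import DataError, LoadError

NEUTRAL_FILL = "#d9d9d9"  # countries with no value in the current period


@dataclass
class BoundarySet:
    """ISO-3 code -> list of shapely Polygons (MultiPolygons flattened)."""

    polygons: dict[str, list[Polygon]]
    skipped: int = 0

    @property
    def codes(self) -> set[str]:
        return set(self.polygons)

    def bounding_box(self, codes) -> tuple[float, float, float, float]:
        """(min lon, min lat, max lon, max lat) over the given codes."""
        boxes = [p.bounds for c in codes if c in self.polygons
                 for p in self.polygons[c]]
        if not boxes:
            raise DataError("no boundary polygons for the requested codes")
        xs0, ys0, xs1, ys1 = zip(*boxes)
        return min(xs0), min(ys0), max(xs1), max(ys1)


def load_boundaries(path: str | Path, code_property: str = "iso_a3") -> BoundarySet:
    """Read a GeoJSON FeatureCollection keyed by an ISO-3 property.

    Features lacking the property are skipped (counted in ``skipped``);
    non-polygonal geometries raise.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"boundary file not found: {path}")
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        features = doc["features"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise LoadError(f"unparseable GeoJSON {path}: {exc}") from exc
    polygons: dict[str, list[Polygon]] = {}
    skipped = 0
    for feat in features:
        code = (feat.get("properties") or {}).get(code_property)
        if not code:
            skipped += 1
            continue
        geom = shape(feat["geometry"])
        if isinstance(geom, Polygon):
            parts = [geom]
        elif isinstance(geom, MultiPolygon):
            parts = list(geom.geoms)
        else:
            raise LoadError(f"feature {code!r}: unsupported geometry {geom.geom_type}")
        polygons.setdefault(str(code), []).extend(parts)
    return BoundarySet(polygons=polygons, skipped=skipped)


@dataclass
class ColorBinning:
    """Percent-scale bins: half-open [lo, hi) except the last, which is closed."""

    edges: list[float]                      # len = n_bins + 1, strictly increasing
    colors: list[tuple]                     # lightest first
    labels: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_index(self, value_percent: float) -> int:
        v = float(value_percent)
        if not self.edges[0] <= v <= self.edges[-1]:
            raise DataError(f"value {v}% outside binning range "
                            f"[{self.edges[0]}, {self.edges[-1]}]")
        if v == self.edges[-1]:
            return self.n_bins - 1
        for i in range(self.n_bins):
            if self.edges[i] <= v < self.edges[i + 1]:
                return i
        raise AssertionError("unreachable")

    def color_for(self, value_percent: float) -> tuple:
        return self.colors[self.bin_index(value_percent)]


def as_percent(values, scale: str = "auto") -> np.ndarray:
    """Normalize proportions/percentages to the percent scale.

    ``auto`` treats inputs with max <= 1 as proportions; an explicit
    ``proportion``/``percentage`` declaration overrides that inference.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("no values to bin")
    if np.any(v < 0):
        raise DataError("negative proportion/percentage values")
    if scale == "proportion" or (scale == "auto" and v.max() <= 1.0):
        if np.any(v > 1.0):
            raise DataError("declared proportions exceed 1")
        return v * 100.0
    if np.any(v > 100.0):
        raise DataError("percentage values exceed 100")
    return v


def build_binning(values, bin_width: float = 10.0, scale: str = "auto") -> ColorBinning:
    """Width-10 percent bins covering the observed range, reds light-to-dark.

    Labels follow the "20-29%" convention; the final (closed) bin is
    labelled with its true upper edge.
    """
    if bin_width <= 0:
        raise DataError("bin width must be positive")
    pct = as_percent(values, scale)
    lo = math.floor(pct.min() / bin_width) * bin_width
    hi = math.ceil(pct.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = [lo + i * bin_width for i in range(int(round((hi - lo) / bin_width)) + 1)]
    n_bins = len(edges) - 1
    cmap = colormaps["Reds"]
    colors = [cmap(x) for x in np.linspace(0.25, 0.9, n_bins)]
    labels = []
    for i in range(n_bins):
        if i < n_bins - 1:
            labels.append(f"{edges[i]:g}-{edges[i + 1] - 1:g}%")
        else:
            labels.append(f"{edges[i]:g}-{edges[i + 1]:g}%")
    return ColorBinning(edges=edges, colors=colors, labels=labels)


def unmatched_codes(boundaries: BoundarySet, table: CountryYearTable) -> list[str]:
    """Data rows whose ISO-3 code has no boundary polygon (never dropped silently)."""
    return sorted(set(table.rows["iso3"].astype(str)) - boundaries.codes)


def render_map_frame(
    boundaries: BoundarySet,
    table: CountryYearTable,
    binning: ColorBinning,
    year: str,
    mode: str = "world",
    canvas: tuple[int, int] = (900, 600),
    dpi: int = 100,
    varlabel: str = "Proportion",
    scale: str = "auto",
) -> Figure:
    """Draw one choropleth frame for ``year`` in ``world`` or ``region`` mode."""
    if mode not in ("world", "region"):
        raise DataError(f"mode must be 'world' or 'region', got {mode!r}")
    df = table.rows
    years = set(df["year"].astype(str))
    if str(year) not in years:
        raise DataError(f"year {year!r} not present in the country table")
    frame_rows = df[df["year"].astype(str) == str(year)]
    pct = as_percent(frame_rows["proportion"].to_numpy(), scale)
    fills = {
        str(code): binning.color_for(v)
        for code, v in zip(frame_rows["iso3"], pct)
        if str(code) in boundaries.codes
    }

    fig = Figure(figsize=(canvas[0] / dpi, canvas[1] / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for code in sorted(boundaries.codes):
        color = fills.get(code, NEUTRAL_FILL)
        for poly in boundaries.polygons[code]:
            ax.add_patch(MplPolygon(
                np.asarray(poly.exterior.coords), closed=True,
                facecolor=color, edgecolor="black", linewidth=0.4,
            ))
    if mode == "world":
        x0, y0, x1, y1 = boundaries.bounding_box(boundaries.codes)
    else:
        with_data = set(df["iso3"].astype(str)) & boundaries.codes
        x0, y0, x1, y1 = boundaries.bounding_box(with_data)
    mx, my = 0.05 * (x1 - x0 or 1.0), 0.05 * (y1 - y0 or 1.0)
    ax.set_xlim(x0 - mx, x1 + mx)
    ax.set_ylim(y0 - my, y1 + my)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{varlabel} — {year}")
    handles = [Patch(facecolor=c, edgecolor="black", label=l)
               for c, l in zip(binning.colors, binning.labels)]
    handles.append(Patch(facecolor=NEUTRAL_FILL, edgecolor="black", label="no data"))
    ax.legend(handles=handles, loc="lower left", fontsize=7, frameon=False)
    return fig


def save_map_frames(
    boundaries: BoundarySet, table: CountryYearTable, outdir,
    varlabel: str = "Proportion", scale: str = "auto",
    canvas: tuple[int, int] = (900, 600), dpi: int = 100,
) -> tuple[list, list]:
    """Write world (``map1_*.png``) and region (``map2_*.png``) sequences.

    A single binning over all periods keeps colors comparable across frames.
    Returns (world paths, region paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    binning = build_binning(table.rows["proportion"].to_numpy(), scale=scale)
    years = sorted(set(table.rows["year"].astype(str)))
    world, region = [], []
    for i, year in enumerate(years):
        for mode, prefix, bucket in (("world", "map1", world), ("region", "map2", region)):
            fig = render_map_frame(
                boundaries, table, binning, year, mode=mode,
                canvas=canvas, dpi=dpi, varlabel=varlabel, scale=scale,
            )
            path = outdir / f"{prefix}_{i + 1:04d}.png"
            fig.savefig(path, format="png")
            bucket.append(path)
    return world, region
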