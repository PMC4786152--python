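"""Statistical primitives behind the panels.

Four internal estimators, implemented here because the renderers depend on
their exact conventions:

* Kaplan-Meier product-limit survival, with the universal tie rule that
  events precede censorings in the risk-set accounting;
* locally weighted polynomial regression (LOESS) with tricube weights over
  nearest-neighbor spans, degree 1 or 2;
* Gaussian kernel density with Silverman's rule-of-thumb bandwidth
  ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``;
* grouped two-indicator proportion tables with minimum-count suppression
  for the bubble plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit step function with S(0) = 1.

    ``event_times`` are the distinct times at which deaths occur;
    ``survival[i]`` is S(t) just after ``event_times[i]``; ``at_risk[i]`` is
    the risk-set size at ``event_times[i]`` (events counted before
    censorings at tied times).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def cumulative_death_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    @property
    def final_cumulative_death(self) -> float:
        return 1.0 - (float(self.survival[-1]) if len(self.survival) else 1.0)

    def step_points(self, horizon: float) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) vertices of the cumulative-death step curve on [0, horizon]."""
        xs = [0.0]
        ys = [0.0]
        for t, s in zip(self.event_times, self.survival):
            if t > horizon:
                break
            xs.extend([float(t), float(t)])
            ys.extend([ys[-1], 1.0 - float(s)])
        xs.append(float(horizon))
        ys.append(ys[-1])
        return np.asarray(xs), np.asarray(ys)


def km_estimate(times, events, horizon: float | None = None) -> SurvivalCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``times`` are follow-up days, ``events`` True for deaths and False for
    censorings.  At tied death/censoring times the censored subjects remain
    in the risk set for the deaths at that time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise DataError("km_estimate needs at least one subject")
    if np.any(t < 0):
        raise DataError("negative follow-up time")
    if horizon is not None and np.any(t > horizon):
        raise DataError("follow-up time exceeds the stated horizon")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    event_times, survival, at_risk = [], [], []
    s = 1.0
    i = 0
    while i < n:
        ti = t[i]
        j = i
        d = 0
        while j < n and t[j] == ti:
            d += int(e[j])
            j += 1
        if d > 0:
            n_i = n - i  # everyone with time >= ti, censored-at-ti included
            s *= 1.0 - d / n_i
            event_times.append(ti)
            survival.append(s)
            at_risk.append(n_i)
        i = j
    return SurvivalCurve(
        event_times=np.asarray(event_times),
        survival=np.asarray(survival),
        at_risk=np.asarray(at_risk),
        n=n,
    )


# ---------------------------------------------------------------------------
# LOESS


@dataclass
class SmoothedCurve:
    grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int


def loess_fit(
    x, y, span: float = 0.75, degree: int = 1, grid=None
) -> SmoothedCurve:
    """Locally weighted polynomial regression on a grid.

    For each grid point the ``ceil(span * n)`` nearest x-neighbors are fit
    with a weighted least-squares polynomial of the given degree, using
    tricube weights ``(1 - (d/d_max)^3)^3``; the fitted value is the
    polynomial evaluated at the grid point.  Exactly reproduces any
    polynomial of degree <= ``degree``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-d arrays")
    if degree not in (1, 2):
        raise DataError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise DataError("span must lie in (0, 1]")
    n = x.size
    if np.unique(x).size < degree + 2:
        raise DataError(f"need at least {degree + 2} distinct x values")
    k = int(math.ceil(span * n))
    if k < degree + 1:
        raise DataError(f"span {span} gives {k} neighbors; need >= {degree + 1}")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    grid = np.asarray(grid, dtype=float)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = np.empty(grid.size)
    for gi, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            u = np.clip(d[idx] / dmax, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
            if not np.any(w > 0):
                w = np.ones(k)
        # weighted LS via sqrt-weighted design matrix
        xi = xs[idx] - g  # center for conditioning; fitted value = intercept
        cols = [np.ones(k), xi] + ([xi**2] if degree == 2 else [])
        A = np.column_stack(cols)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(A * sw[:, None], ys[idx] * sw, rcond=None)
        fitted[gi] = beta[0]
    if not np.all(np.isfinite(fitted)):
        raise DataError("non-finite smoothed values")
    return SmoothedCurve(grid=grid, fitted=fitted, span=span, degree=degree)


# ---------------------------------------------------------------------------
# Kernel density


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5), ignoring a zero spread term."""
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0:
        raise DataError("degenerate sample: zero spread")
    return 0.9 * spread * v.size ** (-1 / 5)


def kde(values, grid=None, bandwidth: float | None = None) -> DensityCurve:
    """Gaussian kernel density estimate with Silverman's bandwidth."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise DataError("kde needs at least 2 distinct values")
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if grid is None:
        grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, 256)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - v[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * h * math.sqrt(2 * math.pi))
    return DensityCurve(grid=grid, density=dens, bandwidth=h)


# ---------------------------------------------------------------------------
# Bubble proportions


@dataclass
class Cells:
    """Joint 2x2 counts of (var1, var2) among fully observed rows."""

    tt: int
    tf: int
    ft: int
    ff: int

    @property
    def total(self) -> int:
        return self.tt + self.tf + self.ft + self.ff


@dataclass
class BubblePoint:
    group: str
    period: str
    p1: float
    p2: float
    n: int
    cells: Cells


def bubble_stats(var1, var2, groups, periods, minnum: int = 10) -> list[BubblePoint]:
    """Per-(group, period) joint indicator counts with minimum-n suppression.

    Rows where either indicator is missing are excluded from that point's
    denominator; points with ``n < minnum`` are suppressed entirely.
    Output is sorted by (period, group) for stable rendering order.
    """
    acc: dict[tuple[str, str], Cells] = {}
    for v1, v2, g, p in zip(var1, var2, groups, periods):
        b1 = _tri(v1)
        b2 = _tri(v2)
        if b1 is None or b2 is None:
            continue
        key = (str(g), str(p))
        cells = acc.setdefault(key, Cells(0, 0, 0, 0))
        if b1 and b2:
            cells.tt += 1
        elif b1:
            cells.tf += 1
        elif b2:
            cells.ft += 1
        else:
            cells.ff += 1
    points = []
    for (g, p), cells in sorted(acc.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        n = cells.total
        if n < minnum:
            continue
        points.append(BubblePoint(
            group=g, period=p,
            p1=(cells.tt + cells.tf) / n,
            p2=(cells.tt + cells.ft) / n,
            n=n, cells=cells,
        ))
    return points


def _tri(value) -> bool | None:
    """Coerce a cell to three-valued boolean."""
    if value is None:
        return None
    try:
        import pandas as pd
        if value is pd.NA:
            return None
    except ImportError:  # pragma: no cover
        pass
    if isinstance(value, float) and math.isnan(value):
        return None
    return bool(value)
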