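import math
import random

import numpy as np
import pytest

from cohortviz.errors import DataError
from cohortviz.stats_core import (Cells, bubble_stats, kde, km_estimate,
                                  loess_fit, silverman_bandwidth)
from tests.oracles import km_brute_force, km_survival_at, loess_brute_force


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = km_estimate([1, 2, 3], [True, True, True])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(1 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_censoring_stops_the_drop(self):
        km = km_estimate([1, 2], [True, False])
        assert km.survival_at(1) == pytest.approx(0.5)
        assert km.survival_at(100) == pytest.approx(0.5)

    def test_tied_event_and_censoring_event_first(self):
        # the censored subject is still at risk for the death at t=2
        km = km_estimate([2, 2], [True, False])
        assert km.survival_at(2) == pytest.approx(0.5)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            t = rng.integers(0, 15, size=rng.integers(1, 20)).astype(float)
            km = km_estimate(t, np.ones_like(t, dtype=bool))
            for u in np.unique(t):
                ecdf = np.mean(t <= u)
                assert km.survival_at(u) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = random.Random(6)
        for _ in range(300):
            n = rng.randint(1, 12)
            t = [rng.randint(0, 6) for _ in range(n)]  # heavy ties
            e = [rng.random() < 0.6 for _ in range(n)]
            km = km_estimate(t, e)
            et, sv = km_brute_force(t, e)
            assert np.allclose(km.event_times, et)
            assert np.allclose(km.survival, sv, atol=1e-12)

    def test_survival_nonincreasing_and_at_risk_nonincreasing(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(100, 200)
        e = rng.random(200) < 0.5
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 0)
        assert np.all(np.diff(km.at_risk) <= 0)
        assert km.survival_at(0) <= 1.0 and km.survival_at(-1) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            km_estimate([], [])

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(8)
        t = np.round(rng.exponential(300, 150))
        e = rng.random(150) < 0.6
        km = km_estimate(t, e)
        fitter = lifelines.KaplanMeierFitter().fit(t, e)
        for u in (50, 100, 250, 500):
            ref = float(fitter.survival_function_at_times(u).iloc[0])
            assert km.survival_at(u) == pytest.approx(ref, abs=1e-10)


class TestLoess:
    def test_exact_on_linear_data(self):
        x = np.linspace(0, 10, 40)
        grid = np.linspace(0, 10, 17)
        for span in (0.3, 0.75, 1.0):
            fit = loess_fit(x, 2 * x, span=span, degree=1, grid=grid)
            assert np.allclose(fit.fitted, 2 * grid, atol=1e-9)

    def test_exact_on_constant(self):
        x = np.linspace(0, 5, 20)
        fit = loess_fit(x, np.full(20, 5.0), span=0.5, degree=1)
        assert np.allclose(fit.fitted, 5.0, atol=1e-10)

    def test_degree2_exact_on_quadratic(self):
        x = np.linspace(-3, 3, 50)
        y = 1.5 * x**2 - 2 * x + 0.5
        grid = np.linspace(-3, 3, 11)
        fit = loess_fit(x, y, span=0.6, degree=2, grid=grid)
        assert np.allclose(fit.fitted, 1.5 * grid**2 - 2 * grid + 0.5, atol=1e-8)

    def test_matches_brute_force_oracle_on_noisy_sine(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 6, 200))
        y = np.sin(x) + rng.normal(0, 0.3, 200)
        grid = np.linspace(0.2, 5.8, 31)
        fit = loess_fit(x, y, span=0.3, degree=1, grid=grid)
        oracle = loess_brute_force(x, y, 0.3, 1, grid)
        assert np.max(np.abs(fit.fitted - oracle)) < 1e-9

    def test_insufficient_points_rejected(self):
        with pytest.raises(DataError):
            loess_fit([0, 1], [0, 1], degree=1)
        with pytest.raises(DataError):
            loess_fit(np.arange(10.0), np.arange(10.0), span=0.1, degree=2)


class TestKde:
    def test_normalization(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            v = rng.normal(0, 1 + rng.random(), rng.integers(5, 200))
            curve = kde(v)
            integral = np.trapezoid(curve.density, curve.grid)
            assert 0.98 <= integral <= 1.02

    def test_symmetric_sample_gives_symmetric_density(self):
        curve = kde([-1.0, 1.0], grid=np.linspace(-3, 3, 101))
        assert np.max(np.abs(curve.density - curve.density[::-1])) < 1e-12

    def test_two_separated_clusters_have_two_modes(self):
        rng = np.random.default_rng(11)
        v = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(10, 0.2, 100)])
        curve = kde(v)
        d = curve.density
        modes = np.sum((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]) & (d[1:-1] > d.max() * 0.05))
        assert modes == 2

    def test_silverman_rule_value(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sd = np.std(v, ddof=1)
        iqr = np.percentile(v, 75) - np.percentile(v, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * 5 ** (-0.2)
        assert silverman_bandwidth(v) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DataError):
            kde([3.0, 3.0, 3.0])


class TestBubbleStats:
    @staticmethod
    def toy(cells_by_key):
        """Expand {(group, period): (tt, tf, ft, ff)} into flat rows."""
        v1, v2, g, p = [], [], [], []
        for (grp, per), (tt, tf, ft, ff) in cells_by_key.items():
            for flag1, flag2, count in ((True, True, tt), (True, False, tf),
                                        (False, True, ft), (False, False, ff)):
                v1 += [flag1] * count
                v2 += [flag2] * count
                g += [grp] * count
                p += [per] * count
        return v1, v2, g, p

    def test_known_cell_counts(self):
        points = bubble_stats(*self.toy({("A", "2011"): (2, 1, 3, 4)}), minnum=10)
        (pt,) = points
        assert pt.n == 10
        assert pt.p1 == pytest.approx(0.3) and pt.p2 == pytest.approx(0.5)
        assert (pt.cells.tt, pt.cells.tf, pt.cells.ft, pt.cells.ff) == (2, 1, 3, 4)

    def test_below_minimum_suppressed(self):
        points = bubble_stats(*self.toy({("A", "2011"): (2, 1, 3, 3)}), minnum=10)
        assert points == []

    def test_missing_flags_excluded_from_denominator(self):
        v1 = [True, None, True]
        v2 = [True, True, None]
        points = bubble_stats(v1, v2, ["A"] * 3, ["2011"] * 3, minnum=1)
        assert points[0].n == 1

    def test_cells_sum_to_n_and_suppression_monotone(self):
        rng = random.Random(12)
        for _ in range(30):
            keys = {("A", "2010"): tuple(rng.randint(0, 6) for _ in range(4)),
                    ("B", "2011"): tuple(rng.randint(0, 6) for _ in range(4))}
            data = self.toy(keys)
            prev = None
            for minnum in (0, 5, 10, 15):
                pts = bubble_stats(*data, minnum=minnum)
                for p in pts:
                    assert p.cells.total == p.n >= minnum
                emitted = {(p.group, p.period) for p in pts}
                if prev is not None:
                    assert emitted <= prev
                prev = emitted
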