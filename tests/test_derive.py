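import datetime as dt
import random

import numpy as np
import pandas as pd
import pytest

from cohortviz.derive import (aggregate_country_year, attribute_last_value,
                              baseline_value, build_timelines,
                              compute_follow_up, discretize_period,
                              select_start_date, transform)
from cohortviz.errors import DataError, DomainError
from tests.conftest import make_table


class TestSelectStartDate:
    dates = [dt.date(2010, 1, 1), dt.date(2011, 1, 1)]

    def test_first(self):
        assert select_start_date(self.dates, "first") == dt.date(2010, 1, 1)

    def test_last(self):
        assert select_start_date(self.dates, "last") == dt.date(2011, 1, 1)

    def test_single_date_either_mode(self):
        one = [dt.date(2012, 6, 1)]
        assert select_start_date(one, "first") == select_start_date(one, "last")

    def test_all_missing(self):
        assert select_start_date([None, None], "first") is None


class TestFollowUp:
    def test_event_within_horizon_exact_day_count(self):
        # calendar oracle: 2010-01-01 .. 2010-12-31 is 364 days
        start, death = dt.date(2010, 1, 1), dt.date(2010, 12, 31)
        assert (death - start).days == 364
        assert compute_follow_up(start, death, True, 730) == (364, True)

    def test_administrative_censoring_at_maxtime(self):
        got = compute_follow_up(dt.date(2010, 1, 1), dt.date(2013, 1, 1), False, 730)
        assert got == (730, False)

    def test_event_beyond_maxtime_is_censored_not_kept(self):
        got = compute_follow_up(dt.date(2010, 1, 1), dt.date(2013, 1, 1), True, 730)
        assert got == (730, False)

    def test_same_day_event(self):
        s = dt.date(2010, 1, 1)
        assert compute_follow_up(s, s, True, 730) == (0, True)

    def test_end_before_start(self):
        with pytest.raises(DataError):
            compute_follow_up(dt.date(2010, 1, 2), dt.date(2010, 1, 1), True, 730)

    def test_truncation_monotone_in_maxtime(self):
        rng = random.Random(1)
        start = dt.date(2009, 1, 1)
        for _ in range(200):
            span = rng.randint(0, 2000)
            event = rng.random() < 0.5
            m1 = rng.randint(1, 1500)
            m2 = m1 + rng.randint(0, 500)
            end = start + dt.timedelta(days=span)
            d1, e1 = compute_follow_up(start, end, event, m1)
            d2, e2 = compute_follow_up(start, end, event, m2)
            assert d2 >= d1
            if span <= m1:  # below the old horizon nothing may change
                assert (d1, e1) == (d2, e2)


class TestAttributeLastValue:
    def test_latest_qualifying_observation(self):
        assert attribute_last_value([(10, 50.0), (300, 120.0)], 400, 360) == 120.0

    def test_gap_beyond_window_absent(self):
        assert attribute_last_value([(10, 50.0)], 400, 360) is None

    def test_boundary_gap_inclusive(self):
        assert attribute_last_value([(40, 120.0)], 400, 360) == 120.0

    def test_observation_after_event_ignored(self):
        assert attribute_last_value([(500, 80.0)], 400, 360) is None

    def test_infinite_window_equals_last_at_or_before(self):
        rng = random.Random(2)
        for _ in range(100):
            obs = sorted((rng.randint(0, 400), float(rng.randint(1, 999)))
                         for _ in range(rng.randint(0, 6)))
            event_day = rng.randint(0, 400)
            wide = attribute_last_value(obs, event_day, 10**9)
            before = [v for d, v in obs if d <= event_day]
            assert wide == (before[-1] if before else None)
            zero = attribute_last_value(obs, event_day, 0)
            same_day = [v for d, v in obs if d == event_day]
            assert zero == (same_day[-1] if same_day else None)


class TestTransform:
    def test_pointwise_values(self):
        assert transform(400.0, "sqrt") == 20.0
        assert transform(1000.0, "log10") == 3.0
        assert transform(5.0, "identity") == 5.0

    def test_domain_violations(self):
        with pytest.raises(DomainError):
            transform([0.0], "log")
        with pytest.raises(DomainError):
            transform([-1.0], "sqrt")


class TestPeriods:
    @pytest.mark.parametrize("date,period,label", [
        (dt.date(2011, 3, 15), "year", "2011"),
        (dt.date(2011, 3, 15), "quarter", "2011-Q1"),
        (dt.date(2011, 12, 1), "month", "2011-12"),
        (dt.date(2011, 10, 1), "quarter", "2011-Q4"),
    ])
    def test_labels(self, date, period, label):
        assert discretize_period(date, period) == label

    def test_labels_sort_chronologically(self):
        rng = random.Random(3)
        for period in ("year", "quarter", "month"):
            dates = sorted(dt.date(2000 + rng.randint(0, 20), rng.randint(1, 12), 1)
                           for _ in range(50))
            labels = [discretize_period(d, period) for d in dates]
            assert labels == sorted(labels)


class TestBaselineValue:
    anchor = dt.date(2010, 6, 1)

    def obs(self, *deltas):
        return [(self.anchor + dt.timedelta(days=d), float(100 + d)) for d in deltas]

    def test_closest_wins(self):
        assert baseline_value(self.obs(-30, 10), self.anchor, 180, 30) == 110.0

    def test_no_observation_in_window(self):
        assert baseline_value(self.obs(-300, 60), self.anchor, 180, 30) is None

    def test_tie_goes_to_earlier(self):
        assert baseline_value(self.obs(-5, 5), self.anchor, 180, 30) == 95.0


class TestAggregateCountryYear:
    def test_known_counts(self):
        table = make_table(["country", "year"], [["PER", "2008"]] * 3)
        out = aggregate_country_year(
            table, "country", "year", pd.array([True, True, False], dtype="boolean"))
        row = out.rows.iloc[0]
        assert (row["numerator"], row["denominator"]) == (2, 3)
        assert row["proportion"] == pytest.approx(2 / 3, abs=1e-12)

    def test_all_missing_year_omitted(self):
        table = make_table(["country", "year"], [["PER", "2008"], ["PER", "2009"]])
        out = aggregate_country_year(
            table, "country", "year", pd.array([True, None], dtype="boolean"))
        assert list(out.rows["year"]) == ["2008"]

    def test_single_true_row(self):
        table = make_table(["country", "year"], [["ARG", "2010"]])
        out = aggregate_country_year(
            table, "country", "year", pd.array([True], dtype="boolean"))
        assert out.rows.iloc[0]["proportion"] == 1.0

    def test_matches_brute_force_on_random_tables(self):
        rng = random.Random(4)
        for _ in range(50):
            n = rng.randint(1, 30)
            rows = [[rng.choice(["PER", "ARG", "BRA"]),
                     str(rng.choice([2008, 2009]))] for _ in range(n)]
            flags = [rng.choice([True, False, None]) for _ in range(n)]
            table = make_table(["country", "year"], rows)
            out = aggregate_country_year(
                table, "country", "year", pd.array(flags, dtype="boolean"))
            # brute force
            expected = {}
            for (c, y), f in zip(rows, flags):
                if f is None:
                    continue
                num, den = expected.get((c, y), (0, 0))
                expected[(c, y)] = (num + int(f), den + 1)
            got = {(r["iso3"], r["year"]): (r["numerator"], r["denominator"])
                   for _, r in out.rows.iterrows()}
            assert got == expected
            assert (out.rows["numerator"] <= out.rows["denominator"]).all()


class TestBuildTimelines:
    def test_sim_cohort_timelines_consistent(self, sim_cohort, panel1_spec):
        timelines, warnings = build_timelines(sim_cohort, panel1_spec)
        assert timelines, "simulated cohort should produce timelines"
        for tl in timelines:
            assert 0 <= tl.followup_day <= panel1_spec.maxtime
            assert all(0 <= day <= tl.followup_day for day, _ in tl.observations)
            if tl.event_marker is not None:
                assert tl.event
                day, value = tl.event_marker
                assert value in [v for _, v in tl.observations]
                assert tl.followup_day - max(
                    d for d, v in tl.observations if v == value and d <= day
                ) <= panel1_spec.long2eventwindow

    def test_groupsubset_filters(self, sim_cohort, panel1_spec):
        import dataclasses
        spec = dataclasses.replace(panel1_spec, groupsubset=["1"])
        timelines, _ = build_timelines(sim_cohort, spec)
        assert timelines and {tl.group for tl in timelines} == {"1"}
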