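"""Deterministic multi-site cohort simulator with known ground truth.

Real multi-network HIV cohort data cannot be redistributed, so every
pipeline stage here is exercised against simulated HICDEP-style tables
whose generating process is fully known: enrollment spread over calendar
years at a handful of Latin-American sites, a clinical-AIDS stratum with
lower baseline CD4 and higher mortality, square-root-scale linear CD4
recovery after ART start, exponential death and censoring times, and a
linear calendar trend in the probability of presenting with CD4 < 200.

All randomness flows from one named generator seeded by ``SimParams.seed``,
so identical parameters reproduce byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .hicdep_io import CohortData, write_cohort

#: (site code, ISO-3 country) pairs matching the bundled toy boundary file.
DEFAULT_SITES = (
    ("argentina", "ARG"),
    ("brazil", "BRA"),
    ("chile", "CHL"),
    ("honduras", "HND"),
    ("mexico", "MEX"),
    ("peru", "PER"),
)


@dataclass
class SimParams:
    """Generating-process parameters; defaults emulate a mid-size regional cohort.

    Rates are per day; CD4 medians are cells/uL; ``recovery_slope`` is the
    mean square-root-scale CD4 gain per 100 days on treatment.  The AIDS
    stratum starts lower and climbs faster, with roughly three times the
    death hazard of the non-AIDS stratum (two-year mortality ~= 12% vs 4%).
    ``enrollment_trend`` is the additive per-year drift in the probability
    of a baseline CD4 below 200 (negative = earlier presentation over time).
    """

    n_subjects: int = 500
    sites: tuple = DEFAULT_SITES
    enrollment_years: tuple[int, int] = (2000, 2011)
    p_aids: float = 0.35
    baseline_cd4_median: dict = field(
        default_factory=lambda: {"no_aids": 280.0, "aids": 90.0})
    baseline_cd4_sigma: float = 0.8          # lognormal dispersion (log scale)
    recovery_slope: dict = field(
        default_factory=lambda: {"no_aids": 0.9, "aids": 1.2})
    visit_interval: float = 90.0             # mean days between CD4 measurements
    hazard: dict = field(
        default_factory=lambda: {"no_aids": 5.5e-5, "aids": 1.75e-4})
    censor_rate: float = 4.0e-4
    admin_horizon: int = 1100                # administrative cut, days after ART
    p_low_cd4_start: float = 0.55            # P(baseline CD4 < 200) in first year
    enrollment_trend: float = -0.015
    obs_noise_sd: float = 1.8                # sqrt-scale measurement noise
    seed: int = 20160310

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or not self.sites:
            raise DataError("need at least one subject and one site")
        if not 0 <= self.p_aids <= 1:
            raise DataError("p_aids must lie in [0, 1]")
        if self.enrollment_years[0] > self.enrollment_years[1]:
            raise DataError("empty enrollment year range")
        for rate in (*self.hazard.values(), self.censor_rate):
            if rate < 0:
                raise DataError("rates must be >= 0")


def _exp_draw(rng: np.random.Generator, rate: float) -> float:
    return float(rng.exponential(1.0 / rate)) if rate > 0 else math.inf


def simulate_cohort(params: SimParams) -> CohortData:
    """Generate ``basic``, ``lab_cd4``, ``art`` and ``follow`` tables.

    The ``basic`` table also carries the enrollment-level columns the bubble
    and map examples consume (``aids_cl_y``, ``cd4_v_cmp`` = baseline CD4,
    ``baseline_d`` = enrollment date, ``site``, ``country``), so one
    simulated cohort drives all three plot classes.
    """
    rng = np.random.default_rng(params.seed)
    y0, y1 = params.enrollment_years

    basic_rows, lab_rows, art_rows, follow_rows = [], [], [], []
    for i in range(params.n_subjects):
        pid = f"P{i + 1:05d}"
        site, country = params.sites[int(rng.integers(len(params.sites)))]
        year = int(rng.integers(y0, y1 + 1))
        enroll = dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
        aids = bool(rng.random() < params.p_aids)
        stratum = "aids" if aids else "no_aids"

        # Baseline CD4: calendar trend in P(<200), lognormal within stratum.
        p_low = min(1.0, max(0.0, params.p_low_cd4_start
                             + params.enrollment_trend * (year - y0)))
        low = bool(rng.random() < p_low)
        median = params.baseline_cd4_median[stratum]
        for _ in range(200):
            draw = float(rng.lognormal(math.log(median), params.baseline_cd4_sigma))
            if (draw < 200) == low:
                break
        else:  # fall back to a uniform draw on the right side of 200
            draw = float(rng.uniform(25, 199)) if low else float(rng.uniform(200, 800))
        base_cd4 = max(1, round(draw))

        art_start = enroll + dt.timedelta(days=int(rng.integers(0, 31)))
        t_death = _exp_draw(rng, params.hazard[stratum])
        t_censor = _exp_draw(rng, params.censor_rate)
        t_end = min(t_death, t_censor, params.admin_horizon)
        died = t_death <= min(t_censor, params.admin_horizon)
        end_day = int(math.floor(t_end))
        end_date = art_start + dt.timedelta(days=end_day)

        # CD4 series: sqrt-scale linear recovery with noise, ~quarterly visits.
        slope = params.recovery_slope[stratum]
        day = 0
        while day <= end_day:
            mean_sqrt = math.sqrt(base_cd4) + slope * day / 100.0
            value = max(1, round((mean_sqrt + rng.normal(0, params.obs_noise_sd)) ** 2))
            lab_rows.append((pid, str(value), (art_start + dt.timedelta(days=day)).isoformat()))
            gap = max(7, int(rng.normal(params.visit_interval, params.visit_interval / 4)))
            day += gap

        basic_rows.append((
            pid, site, country, enroll.isoformat(), "1" if aids else "0",
            "1" if aids else "0", str(base_cd4), enroll.isoformat(),
        ))
        art_rows.append((pid, art_start.isoformat()))
        follow_rows.append((pid, "1" if died else "0", end_date.isoformat()))

    def df(rows, cols):
        return pd.DataFrame(rows, columns=cols, dtype=object)

    from .hicdep_io import parse_date

    tables = {
        "basic": df(basic_rows, ["patient", "site", "country", "enrol_d",
                                 "aids_y", "aids_cl_y", "cd4_v_cmp", "baseline_d"]),
        "lab_cd4": df(lab_rows, ["patient", "cd4_v", "cd4_d"]),
        "art": df(art_rows, ["patient", "art_sd"]),
        "follow": df(follow_rows, ["patient", "death_y", "l_alive_d"]),
    }
    date_columns = {
        "basic": ["enrol_d", "baseline_d"],
        "lab_cd4": ["cd4_d"],
        "art": ["art_sd"],
        "follow": ["l_alive_d"],
    }
    for name, cols in date_columns.items():
        for col in cols:
            tables[name][col] = tables[name][col].map(parse_date)

    return CohortData(
        tables=tables, id_field="patient",
        subjects=set(tables["basic"]["patient"]),
        date_columns=date_columns,
    )


def write_fixture(cohort: CohortData, directory, force: bool = False) -> list:
    """Write the simulated tables as loadable HICDEP-style CSVs."""
    return write_cohort(cohort, directory, force=force)
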