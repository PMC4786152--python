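import datetime as dt

import pandas as pd
import pytest

from cohortviz.hicdep_io import CohortData
from cohortviz.spec_config import Panel1Spec
from cohortviz.synthetic import SimParams, simulate_cohort


def make_table(columns, rows):
    """Object-dtype DataFrame from literal rows (None = missing)."""
    return pd.DataFrame(rows, columns=columns, dtype=object)


def make_cohort(tables, id_field="patient"):
    basic = tables.get("basic")
    subjects = set(basic[id_field]) if basic is not None else set()
    return CohortData(tables=tables, id_field=id_field, subjects=subjects)


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(n_subjects=250, seed=11)


@pytest.fixture(scope="session")
def sim_cohort(sim_params):
    return simulate_cohort(sim_params)


@pytest.fixture(scope="session")
def panel1_spec():
    return Panel1Spec(
        longtablename="lab_cd4", longvar="cd4_v", longvardate="cd4_d",
        eventtablename="follow", event="death_y", enddate="l_alive_d",
        grouptablename="basic", group="aids_y",
        starttablename="art", startdate="art_sd",
        longvartrans="sqrt",
        grouplabels={"0": "No AIDS", "1": "AIDS"},
    )


@pytest.fixture()
def d():
    """Shorthand date constructor."""
    return dt.date
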