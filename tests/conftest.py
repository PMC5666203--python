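import datetime as dt

import numpy as np
import pandas as pd
import pytest

import occmort as om


@pytest.fixture(scope="session")
def esp():
    return om.datasets.esp2013()


@pytest.fixture
def two_group_scheme():
    return om.GroupingScheme(
        [
            om.OccupationGroup("821", "Transport drivers and operatives",
                               frozenset({"821"}), "male"),
            om.OccupationGroup("none", "No occupation reported", frozenset(),
                               "male", includes_no_occupation=True),
        ],
        sex="male",
        geography="EW",
    )


def make_record(age, years, died, soc="821", pid="p1"):
    entry = dt.date(2001, 4, 29)
    days = int(round(years * 365.25))
    return om.CohortRecord(
        person_id=pid, sex="male", age_at_census=age, soc_code=soc,
        geography="EW", entry_date=entry,
        exit_date=entry + dt.timedelta(days=days), died=died,
    )


@pytest.fixture
def small_cohort_frame():
    """Hand-built four-person cohort crossing band boundaries."""
    entry = dt.date(2001, 4, 29)
    rows = [
        # age, follow-up years, died, soc
        (23.0, 6.2, 1, "821"),
        (40.0, 10.0, 0, "821"),
        (59.5, 10.0, 0, ""),
        (35.0, 2.5, 1, ""),
    ]
    return pd.DataFrame({
        "person_id": [f"p{i}" for i in range(len(rows))],
        "sex": "male",
        "age_at_census": [r[0] for r in rows],
        "soc_code": [r[3] for r in rows],
        "geography": "EW",
        "entry_date": entry,
        "exit_date": [
            entry + dt.timedelta(days=int(round(r[1] * 365.25))) for r in rows
        ],
        "died": [r[2] for r in rows],
    })
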