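import datetime

import pytest

from pvsignal import defaults
from pvsignal.reports import DrugEntry, EventEntry, ReportRecord, ReportSet


@pytest.fixture(scope="session")
def gerd_pts():
    return defaults.gerd_pt_set()


@pytest.fixture(scope="session")
def glp1():
    return defaults.glp1_class()


@pytest.fixture(scope="session")
def dpp4():
    return defaults.dpp4_class()


def make_report(
    case_id="C1",
    sex="male",
    age="60-69",
    diseases=("type 2 diabetes mellitus",),
    drugs=(),
    events=(("10047700", "Vomiting"),),
):
    """Compact report builder for hand-written fixtures."""
    return ReportRecord(
        case_id=case_id,
        sex=sex,
        age_bucket=age,
        primary_diseases=frozenset(diseases),
        drugs=tuple(
            DrugEntry(drug_name=d[0], role=d[1] if len(d) > 1 else "suspect",
                      start_date=d[2] if len(d) > 2 else None,
                      end_date=d[3] if len(d) > 3 else None)
            for d in drugs
        ),
        events=tuple(
            EventEntry(pt_id=e[0], pt_name=e[1] if len(e) > 1 else "",
                       onset_date=e[2] if len(e) > 2 else None)
            for e in events
        ),
    )


def day(y, m, d):
    return datetime.date(y, m, d)


@pytest.fixture
def mixed_reports():
    """Five complete-ish reports exercising the inclusion filters."""
    return ReportSet([
        make_report("C1", drugs=[("exenatide",)]),
        make_report("C2", sex=None),
        make_report("C3", age="elderly"),
        make_report("C4", sex="female", drugs=[("sitagliptin", "concomitant")]),
        make_report("C5", events=[("10019211", "Hepatitis")]),
    ])
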