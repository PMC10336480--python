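from datetime import datetime

import pytest

from octomdm.case_model import (
    FeasibilityProfile,
    Histology,
    PatientCase,
    TumorSite,
    parse_tnm,
)
from octomdm.io_fixtures import load_table1_fixtures


def make_case(
    site=TumorSite.larynx_glottic,
    tnm="T1N0M0",
    histology=Histology.epidermoid_carcinoma,
    surgery=True,
    radiation=True,
    chemotherapy=True,
    relapse=False,
    case_id="case-1",
    submitted_by="res-1",
    submitted_at=None,
    factors=(),
) -> PatientCase:
    return PatientCase(
        case_id=case_id,
        site=site,
        tnm=parse_tnm(tnm),
        histology=histology,
        feasibility=FeasibilityProfile(
            surgery_feasible=surgery,
            radiation_feasible=radiation,
            chemotherapy_feasible=chemotherapy,
        ),
        relapse=relapse,
        poor_prognosis_factors=list(factors),
        submitted_by=submitted_by,
        submitted_at=submitted_at,
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixtures()


@pytest.fixture()
def draft_case():
    return make_case()


@pytest.fixture()
def t0():
    return datetime(2023, 1, 1, 9, 0)
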