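from datetime import date

import pytest

from regilink.records import (
    IcuRecord,
    LinkConfig,
    PersonIdentity,
    ProcedureType,
    Sex,
    SurgeryRecord,
    Urgency,
)
from regilink.slk581 import build_slk


def make_surgery(record_id="S1", surname="CITIZEN", forename="JOHN", mrn="1234567",
                 dob=date(1955, 3, 2), sex=Sex.MALE, proc=date(2018, 6, 10),
                 icu_dis=date(2018, 6, 13), hosp_adm=date(2018, 6, 6),
                 hosp_dis=date(2018, 6, 23), age=60, urgency=Urgency.ELECTIVE,
                 ptype=ProcedureType.CABG, risk=0.011):
    return SurgeryRecord(
        record_id=record_id,
        identity=PersonIdentity(surname, forename, mrn, dob, sex),
        procedure_date=proc, icu_dis_date=icu_dis,
        hosp_adm_date=hosp_adm, hosp_dis_date=hosp_dis,
        age=age, urgency=urgency, procedure_type=ptype, risk_of_death=risk,
    )


def make_icu(record_id="I1", surname="CITIZEN", forename="JOHN", mrn="1234567",
             dob=date(1955, 3, 2), sex=Sex.MALE, slk=None,
             icu_adm=date(2018, 6, 10), icu_dis=date(2018, 6, 13),
             hosp_adm=date(2018, 6, 6), hosp_dis=date(2018, 6, 23), age=60):
    identity = PersonIdentity(surname, forename, mrn, dob, sex)
    if slk is None:
        slk = build_slk(identity).value if dob else ""
    return IcuRecord(
        record_id=record_id, identity=identity, slk=slk,
        icu_adm_date=icu_adm, icu_dis_date=icu_dis,
        hosp_adm_date=hosp_adm, hosp_dis_date=hosp_dis, age=age,
    )


@pytest.fixture
def cfg():
    return LinkConfig()


@pytest.fixture
def matched_pair():
    """One fully consistent (surgery, ICU) pair."""
    return make_surgery(), make_icu()
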