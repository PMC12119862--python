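from datetime import date as Date, timedelta

import pytest

from rcdrecur.model import (
    Behaviour,
    CodedEvent,
    CodingSystem,
    Intent,
    Laterality,
    PatientHistory,
    Source,
    TumourRegistration,
)

INDEX_DATE = Date(2004, 1, 1)


def make_registration(
    tumour_id="T0",
    patient_id="P1",
    day=0,
    site_code="C50.9",
    laterality=Laterality.LEFT,
    behaviour=Behaviour.INVASIVE,
    provisional=False,
):
    return TumourRegistration(
        tumour_id,
        patient_id,
        INDEX_DATE + timedelta(days=day),
        site_code,
        behaviour,
        laterality,
        provisional,
    )


def make_event(
    day,
    code,
    patient_id="P1",
    source=Source.HES,
    system=CodingSystem.ICD10,
    laterality=Laterality.UNKNOWN,
    intent=Intent.UNKNOWN,
    attributes=None,
):
    return CodedEvent(
        patient_id,
        source,
        INDEX_DATE + timedelta(days=day),
        system,
        code,
        laterality,
        intent,
        attributes or {},
    )


def make_history(events=(), registrations=(), death=None, laterality=Laterality.LEFT):
    return PatientHistory(
        patient_id="P1",
        index_registration=make_registration(laterality=laterality),
        other_registrations=list(registrations),
        events=list(events),
        death=death,
    )


@pytest.fixture
def index_date():
    return INDEX_DATE
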