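import datetime as dt

import pytest

from ipahes import (
    CodeSystem,
    EpisodeEvent,
    Gender,
    PatientDemographics,
    PatientRecord,
    SelectionConfig,
    Setting,
    normalize_code,
)
from ipahes.selection import ExclusionRule


def ev(
    pid,
    day,
    setting=Setting.OUTPATIENT,
    primary=None,
    secondary=(),
    procedures=(),
    specialty="OTHER",
    provider="GEN01",
):
    """Shorthand episode-event builder for fixtures."""
    return EpisodeEvent(
        patient_id=pid,
        setting=Setting(setting),
        event_date=dt.date.fromisoformat(day) if isinstance(day, str) else day,
        primary_diagnosis=normalize_code(primary, CodeSystem.ICD10) if primary else None,
        secondary_diagnoses=tuple(normalize_code(c, CodeSystem.ICD10) for c in secondary),
        procedures=tuple(normalize_code(c, CodeSystem.OPCS) for c in procedures),
        treatment_specialty=specialty,
        provider=provider,
    )


def patient(pid, events, birth=(1955, 6), gender=Gender.F, region="ENGLAND", opt_out=False):
    return PatientRecord(
        demographics=PatientDemographics(
            patient_id=pid,
            gender=gender,
            birth_year=birth[0],
            birth_month=birth[1],
            gp_postcode="S10 2AB",
            residence_region=region,
            research_opt_out=opt_out,
        ),
        events=tuple(events),
    )


def _scaffold(pid, dx_kwargs=None, reg_day="2009-05-01", extra=()):
    """Events for a cleanly includable patient: an early registration visit,
    a mid-record cardiology contact, and an RHC + PH-coded diagnosis
    admission at an adult specialist center."""
    dx = dict(
        setting=Setting.INPATIENT,
        primary="I27.0",
        procedures=("K652",),
        specialty="CARDIOLOGY",
        provider="PHC01",
    )
    dx.update(dx_kwargs or {})
    return [
        ev(pid, reg_day),
        ev(pid, "2012-06-10", primary="I10", specialty="CARDIOLOGY"),
        ev(pid, "2013-06-01", **dx),
        *extra,
    ]


@pytest.fixture(scope="session")
def selection_config():
    return SelectionConfig(earliest_diagnosis_for_inclusion=dt.date(2012, 4, 1))


@pytest.fixture(scope="session")
def selection_fixture():
    """Hand-traced cascade fixture: one violator per exclusion rule plus one
    clean case.  The expected first-failing rule per patient is the oracle."""
    filler = [ev("HEAVY", "2010-01-01", primary="I10") for _ in range(247)]
    records = [
        patient("CLEAN", _scaffold("CLEAN")),
        patient("OPTOUT", _scaffold("OPTOUT"), opt_out=True),
        patient("NOPH", _scaffold("NOPH", dx_kwargs={"primary": "I10"})),
        patient("NORHC", _scaffold("NORHC", dx_kwargs={"procedures": ()})),
        patient("NOSPEC", _scaffold("NOSPEC", dx_kwargs={"provider": "GEN02"})),
        patient(
            "NONIPAH",
            _scaffold("NONIPAH", extra=[ev("NONIPAH", "2012-08-01", primary="I10", secondary=("I50.9",))]),
        ),
        patient("PED", _scaffold("PED"), birth=(1996, 1)),
        patient("SHORT", _scaffold("SHORT", reg_day="2011-02-01")),
        patient("WALES", _scaffold("WALES"), region="WALES"),
        patient("HEAVY", _scaffold("HEAVY", extra=filler)),
    ]
    expected = {
        "CLEAN": ExclusionRule.NONE,
        "OPTOUT": ExclusionRule.OPT_OUT,
        "NOPH": ExclusionRule.NO_PH_CODE,
        "NORHC": ExclusionRule.NO_RHC,
        "NOSPEC": ExclusionRule.NO_SPECIALIST_CENTER,
        "NONIPAH": ExclusionRule.NON_IPAH_CODE,
        "PED": ExclusionRule.PEDIATRIC,
        "SHORT": ExclusionRule.INSUFFICIENT_LOOKBACK,
        "WALES": ExclusionRule.NON_ENGLAND,
        "HEAVY": ExclusionRule.HCRU_CAP,
    }
    return records, expected
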