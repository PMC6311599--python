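import datetime as dt

import pytest

from ipahes import synth
from ipahes.anchors import (
    AnchorConfig,
    derive_anchors,
    derive_first_symptom,
    derive_index_date,
    derive_lookback_date,
    first_symptom_specialty_distribution,
    validation_eligibility,
)
from ipahes.records import Setting
from tests.conftest import ev, patient

CFG = AnchorConfig()
VISIT = dt.date(2015, 6, 1)


class TestIndexDate:
    def test_latest_relevant_event_before_first_visit(self):
        rec = patient(
            "X",
            [
                ev("X", "2015-02-21", specialty="CARDIOLOGY"),
                ev("X", "2015-04-12", specialty="OTHER"),  # not relevant
                ev("X", "2014-01-01", specialty="RESPIRATORY"),
            ],
        )
        assert derive_index_date(rec, VISIT, CFG) == dt.date(2015, 2, 21)

    def test_event_on_visit_day_not_eligible(self):
        """'Before the first visit' is strict: a relevant event on the visit
        day itself cannot be the index."""
        rec = patient(
            "X",
            [ev("X", "2015-06-01", specialty="RESPIRATORY"), ev("X", "2015-01-01", specialty="CARDIOLOGY")],
        )
        assert derive_index_date(rec, VISIT, CFG) == dt.date(2015, 1, 1)

    def test_no_relevant_event_gives_none(self):
        rec = patient("X", [ev("X", "2015-01-01", specialty="OTHER")])
        assert derive_index_date(rec, VISIT, CFG) is None

    def test_invariant_under_post_visit_insertions(self):
        base = [ev("X", "2015-02-21", specialty="CARDIOLOGY")]
        extra = [ev("X", "2015-06-01", specialty="CARDIOLOGY"), ev("X", "2016-01-01", specialty="NEUROLOGY")]
        assert derive_index_date(patient("X", base), VISIT, CFG) == derive_index_date(
            patient("X", base + extra), VISIT, CFG
        )


class TestLookbackDate:
    INDEX = dt.date(2015, 1, 1)

    def _rec(self, first_day):
        return patient("X", [ev("X", first_day), ev("X", "2014-12-01", specialty="CARDIOLOGY")])

    def test_capped_at_five_years(self):
        rec = self._rec("2008-01-01")  # 7 years of history
        assert derive_lookback_date(rec, self.INDEX, CFG) == self.INDEX - dt.timedelta(days=5 * 365)

    def test_short_history_uses_first_event(self):
        rec = self._rec("2013-01-01")
        assert derive_lookback_date(rec, self.INDEX, CFG) == dt.date(2013, 1, 1)

    def test_branches_coincide_at_exactly_five_years(self):
        first = self.INDEX - dt.timedelta(days=5 * 365)
        rec = self._rec(first.isoformat())
        assert derive_lookback_date(rec, self.INDEX, CFG) == first

    def test_empty_record_is_error(self):
        with pytest.raises(ValueError):
            derive_lookback_date(patient("X", []), self.INDEX, CFG)


class TestFirstSymptom:
    LOOKBACK = dt.date(2010, 1, 1)
    INDEX = dt.date(2015, 1, 1)

    def test_primary_field_only_for_diagnoses(self):
        """A symptom code in a secondary position does not qualify."""
        rec = patient(
            "X",
            [
                ev("X", "2011-05-01", primary="I10", secondary=("R06.0",)),
                ev("X", "2012-05-01", primary="R06.0", specialty="RESPIRATORY"),
            ],
        )
        got = derive_first_symptom(rec, self.LOOKBACK, self.INDEX, CFG)
        assert got == (dt.date(2012, 5, 1), "RESPIRATORY")

    def test_opcs_procedure_matches_any_position(self):
        rec = patient("X", [ev("X", "2011-05-01", procedures=("U20.2",), specialty="CARDIOLOGY")])
        got = derive_first_symptom(rec, self.LOOKBACK, self.INDEX, CFG)
        assert got == (dt.date(2011, 5, 1), "CARDIOLOGY")

    def test_same_day_tie_broken_by_setting_order(self):
        rec = patient(
            "X",
            [
                ev("X", "2012-05-01", setting=Setting.OUTPATIENT, primary="R55", specialty="CARDIOLOGY"),
                ev("X", "2012-05-01", setting=Setting.AE, primary="R55", specialty="AE"),
            ],
        )
        got = derive_first_symptom(rec, self.LOOKBACK, self.INDEX, CFG)
        assert got[1] == "AE"

    def test_outside_window_or_absent(self):
        rec = patient("X", [ev("X", "2009-05-01", primary="R06.0")])  # before lookback
        assert derive_first_symptom(rec, self.LOOKBACK, self.INDEX, CFG) is None


@pytest.fixture(scope="module")
def eligibility_fixture():
    """Five-patient validation fixture: one per exclusion rule + two clean."""
    def clean(pid, reg_day="2008-01-01", index_day="2015-03-01", symptom_day="2012-05-01", extra=()):
        return patient(
            pid,
            [
                ev(pid, reg_day),
                ev(pid, symptom_day, primary="R06.0", specialty="RESPIRATORY"),
                ev(pid, index_day, specialty="CARDIOLOGY"),
                *extra,
            ],
        )

    heavy_filler = [ev("V4", "2012-01-01", primary="I10") for _ in range(247)]
    records = {
        "V1": clean("V1"),
        "V2": clean("V2"),
        "V3": clean("V3"),  # will not link
        "V4": clean("V4", extra=heavy_filler),  # 250 events
        # 2.3 years of data before the index event
        "V5": clean("V5", reg_day="2013-01-01", index_day="2015-05-01", symptom_day="2013-05-01"),
    }
    visits = {pid: VISIT for pid in records}
    linked = ["V1", "V2", "V4", "V5"]
    return records, visits, linked


def test_validation_eligibility_hand_traced(eligibility_fixture):
    records, visits, linked = eligibility_fixture
    eligible, attrition = validation_eligibility(records, visits, linked, CFG)
    assert set(eligible) == {"V1", "V2"}
    assert attrition == [
        ("CANDIDATES", 5),
        ("NOT_LINKED", 4),
        ("HCRU_CAP", 3),
        ("NO_INDEX_EVENT", 3),
        ("INSUFFICIENT_PRE_INDEX", 2),
    ]


def test_eligible_anchor_ordering(eligibility_fixture):
    records, visits, linked = eligibility_fixture
    eligible, _ = validation_eligibility(records, visits, linked, CFG)
    for a in eligible.values():
        assert a.lookback_date <= a.index_date <= a.first_center_visit
        if a.first_symptom_date:
            assert a.lookback_date <= a.first_symptom_date <= a.index_date


def test_specialty_distribution_arithmetic():
    records = {
        "A": patient("A", [ev("A", "2012-05-01", primary="R06.0", specialty="GENERAL_MEDICINE"),
                           ev("A", "2015-03-01", specialty="CARDIOLOGY"), ev("A", "2008-01-01")]),
    }
    eligible, _ = validation_eligibility(records, {"A": VISIT}, ["A"], CFG)
    dist, absent = first_symptom_specialty_distribution(eligible.values())
    assert dist == {"GENERAL_MEDICINE": 100.0}
    assert absent == 0
    with pytest.raises(ValueError):
        first_symptom_specialty_distribution([])


@pytest.fixture(scope="module")
def phase2():
    cfg = synth.GeneratorConfig(seed=42, subpopulations=[synth.phase2_case_spec(150)])
    ds = synth.generate(cfg)
    records = {r.patient_id: r for r in ds.records()}
    gt = ds.ground_truth.set_index("patient_id")
    visits = {pid: dt.date.fromisoformat(gt.loc[pid, "first_center_visit"]) for pid in records}
    eligible, _ = validation_eligibility(records, visits, list(records), CFG)
    return ds, records, gt, eligible


class TestSyntheticRecovery:
    """Against generator ground truth: the planted index event is recovered
    exactly, the planted first-symptom event is recovered exactly, and
    anchor ordering holds for every eligible patient."""

    def test_planted_index_recovered(self, phase2):
        _, _, gt, eligible = phase2
        assert eligible  # cohort non-trivial
        for pid, a in eligible.items():
            assert a.index_date.isoformat() == gt.loc[pid, "index_date"]

    def test_planted_symptom_recovered(self, phase2):
        _, _, gt, eligible = phase2
        n_checked = 0
        for pid, a in eligible.items():
            true_date = gt.loc[pid, "first_symptom_date"]
            if true_date:
                assert a.first_symptom_date.isoformat() == true_date
                assert a.first_symptom_specialty == gt.loc[pid, "first_symptom_specialty"]
                n_checked += 1
        assert n_checked > 100

    def test_anchor_ordering_invariant(self, phase2):
        _, _, _, eligible = phase2
        for a in eligible.values():
            assert a.lookback_date <= a.index_date <= a.first_center_visit
            if a.first_symptom_date:
                assert a.lookback_date <= a.first_symptom_date <= a.index_date
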