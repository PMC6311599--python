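import datetime as dt
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipahes import synth
from ipahes.hcru import (
    WindowSpec,
    age_stratified_summary,
    brute_force_window_counts,
    summarize,
    window_of,
)
from ipahes.records import PatientRecord, Setting
from tests.conftest import ev, patient

ANCHOR = dt.date(2014, 6, 1)
SPEC = WindowSpec(anchor=ANCHOR)


class TestWindowOf:
    @pytest.mark.parametrize(
        "days_before, expected",
        [
            (1, "Y1"),
            (365, "Y1"),
            (366, "Y2"),
            (730, "Y2"),
            (731, "Y3"),
            (1095, "Y3"),
            (1096, None),
            (0, None),     # the anchor day itself is in no window
            (-10, None),   # post-anchor events excluded
        ],
    )
    def test_half_open_year_boundaries(self, days_before, expected):
        assert window_of(ANCHOR - dt.timedelta(days=days_before), SPEC) == expected

    @given(st.integers(min_value=-400, max_value=1500))
    @settings(max_examples=200, derandomize=True)
    def test_matches_interval_definition(self, days_before):
        """Window assignment agrees with direct half-open interval membership
        [anchor - k*365, anchor - (k-1)*365)."""
        d = ANCHOR - dt.timedelta(days=days_before)
        got = window_of(d, SPEC)
        expected = None
        for k in (1, 2, 3):
            lo = ANCHOR - dt.timedelta(days=k * 365)
            hi = ANCHOR - dt.timedelta(days=(k - 1) * 365)
            if lo <= d < hi:
                expected = f"Y{k}"
        assert got == expected


def _two_patient_cohort():
    a = patient(
        "A",
        [ev("A", (ANCHOR - dt.timedelta(days=d)).isoformat(), specialty=s, provider=p)
         for d, s, p in [(10, "CARDIOLOGY", "GEN01"), (400, "OTHER", "GEN02"), (800, "RESPIRATORY", "GEN01")]],
    )
    b = patient(
        "B",
        [ev("B", (ANCHOR - dt.timedelta(days=d)).isoformat(), specialty="GENERAL_MEDICINE")
         for d in (5, 6, 7, 370, 1090, 2000)],  # last one outside the span
    )
    return {"A": a, "B": b}, {"A": ANCHOR, "B": ANCHOR}


def test_summarize_means_and_additivity():
    records, anchors = _two_patient_cohort()
    s = summarize(records, anchors)
    assert s.n_patients == 2
    # A has 3 in-span events, B has 5 -> mean 4.0
    assert s.mean_total_span == pytest.approx(4.0)
    assert sum(s.window_mean_total.values()) == pytest.approx(s.mean_total_span)
    # per-window mean equals the sum of its setting-level means
    for w in ("Y1", "Y2", "Y3"):
        setting_sum = sum(s.setting_window_mean(w, st_) for st_ in Setting)
        assert setting_sum == pytest.approx(s.window_mean_total[w])
    # cardio/thoracic share: 2 of 8 in-span events
    assert s.cardio_thoracic_share == pytest.approx(2 / 8)
    # distinct providers/specialties per patient, averaged: A=2/3, B=1/1
    assert s.mean_distinct_providers == pytest.approx(1.5)
    assert s.mean_distinct_specialties == pytest.approx(2.0)


def test_summarize_requires_cohort_and_anchors():
    records, anchors = _two_patient_cohort()
    with pytest.raises(ValueError):
        summarize(records, {})
    with pytest.raises(ValueError, match="GHOST"):
        summarize(records, {"GHOST": ANCHOR})


def test_permutation_invariance():
    """Shuffling patients and events leaves the summary unchanged."""
    records, anchors = _two_patient_cohort()
    s1 = summarize(records, anchors)
    shuffled_records = {
        pid: PatientRecord(
            demographics=r.demographics,
            events=tuple(random.Random(0).sample(list(r.events), len(r.events))),
        )
        for pid, r in reversed(list(records.items()))
    }
    shuffled_anchors = dict(reversed(list(anchors.items())))
    s2 = summarize(shuffled_records, shuffled_anchors)
    assert s1.mean_total_span == s2.mean_total_span
    assert s1.window_mean_total == s2.window_mean_total
    assert s1.table.sort_values(["window", "setting", "specialty"]).reset_index(drop=True).equals(
        s2.table.sort_values(["window", "setting", "specialty"]).reset_index(drop=True)
    )


def test_observed_patient_denominator():
    """A patient whose observation starts inside the span is dropped from
    complete-case denominators of earlier windows only."""
    records, anchors = _two_patient_cohort()
    obs = {"A": ANCHOR - dt.timedelta(days=2000), "B": ANCHOR - dt.timedelta(days=500)}
    s = summarize(records, anchors, observation_start=obs)
    y1 = s.table[s.table.window == "Y1"]
    y3 = s.table[s.table.window == "Y3"]
    assert (y1.n_observed == 2).all()
    assert (y3.n_observed == 1).all()


def test_age_stratified_bands():
    records, anchors = _two_patient_cohort()
    demo = {
        "A": records["A"].demographics,  # born 1955 -> 59 at anchor
        "B": records["B"].demographics,
    }
    import dataclasses
    demo["B"] = dataclasses.replace(demo["B"], birth_year=1970)  # 44 at anchor
    out = age_stratified_summary(records, anchors, demo)
    assert out[">=50"].n_patients == 1
    assert out["<50"].n_patients == 1
    only_old = age_stratified_summary(records, anchors, {"A": demo["A"], "B": demo["A"]})
    assert only_old["<50"] is None


@pytest.fixture(scope="module")
def dataset():
    cfg = synth.default_phase1_config(9, n_cases=40, n_per_violator=10)
    ds = synth.generate(cfg)
    return ds, {r.patient_id: r for r in ds.records()}


class TestAgainstGroundTruth:
    """Conservation: summary totals equal the generator's per-patient
    brute-force window counts, patient by patient and in aggregate."""

    def test_ground_truth_matches_brute_force(self, dataset):
        ds, records = dataset
        gt = ds.ground_truth.set_index("patient_id")
        for pid, rec in records.items():
            anchor = dt.date.fromisoformat(
                gt.loc[pid, "index_date"] or gt.loc[pid, "diagnosis_date"]
            )
            brute = brute_force_window_counts(rec, anchor)
            for w in ("Y1", "Y2", "Y3"):
                truth = synth.ground_truth_counts(ds.ground_truth, pid, w)
                for s in Setting:
                    assert brute.get((w, s.value), 0) == truth[s.value]

    def test_window_additivity_over_span(self, dataset):
        ds, records = dataset
        gt = ds.ground_truth.set_index("patient_id")
        for pid, rec in records.items():
            anchor = dt.date.fromisoformat(gt.loc[pid, "diagnosis_date"])
            total3y = sum(
                synth.ground_truth_counts(ds.ground_truth, pid, w)[s.value]
                for w in ("Y1", "Y2", "Y3")
                for s in Setting
            )
            in_span = sum(
                1 for e in rec.events if 0 < (anchor - e.event_date).days <= 3 * 365
            )
            assert total3y == in_span

    def test_summary_conserves_event_counts(self, dataset):
        ds, records = dataset
        gt = ds.ground_truth.set_index("patient_id")
        anchors = {
            pid: dt.date.fromisoformat(gt.loc[pid, "diagnosis_date"]) for pid in records
        }
        s = summarize(records, anchors)
        expected_total = int(
            sum(
                gt[f"y{k}_{st_.value.lower()}"].sum()
                for k in (1, 2, 3)
                for st_ in Setting
            )
        )
        assert int(s.table["total"].sum()) == expected_total == s.n_events_span

    def test_unknown_patient_in_ground_truth_lookup(self, dataset):
        ds, _ = dataset
        with pytest.raises(KeyError):
            synth.ground_truth_counts(ds.ground_truth, "NOBODY", "Y1")
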