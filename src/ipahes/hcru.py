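"""Windowed pre-anchor healthcare-utilization summaries.

Utilization is reported in year windows counting back from a per-patient
anchor (the diagnosis date, or the index date in the validation cohort):
Yk covers [anchor - k*365 d, anchor - (k-1)*365 d).  The anchor day itself
belongs to the diagnostic episode and is in no window; half-open intervals
make the windows a disjoint cover of the three pre-anchor years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import (
    CANONICAL_SPECIALTIES,
    CARDIO_THORACIC,
    PatientDemographics,
    PatientRecord,
    Setting,
    SpecialtyVocabulary,
)
from . import defaults


@dataclass(frozen=True)
class WindowSpec:
    """Year windows before a per-patient anchor date."""

    anchor: date
    n_years: int = 3
    year_days: int = 365

    def window_of(self, event_date: date) -> Optional[str]:
        """Label Y1..Yn for an event date, or None outside the span (the
        anchor day itself maps to None)."""
        days_before = (self.anchor - event_date).days
        if days_before <= 0 or days_before > self.n_years * self.year_days:
            return None
        # days_before in (0, year_days] -> Y1, etc.
        k = (days_before + self.year_days - 1) // self.year_days
        return f"Y{k}"

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"Y{k}" for k in range(1, self.n_years + 1))

    def lower_bound(self, label: str) -> date:
        k = int(label[1:])
        return self.anchor - timedelta(days=k * self.year_days)


def window_of(event_date: date, spec: WindowSpec) -> Optional[str]:
    return spec.window_of(event_date)


@dataclass(frozen=True)
class HcruSummary:
    """Per (window x setting x specialty) totals and cohort means.

    ``table`` is long-format with columns window, setting, specialty, total,
    mean (all-cohort arithmetic mean: patients with zero events in a window
    contribute zeros), n_observed and mean_observed (complete-case mean over
    patients whose observation start precedes the window).
    """

    n_patients: int
    table: pd.DataFrame
    window_mean_total: dict[str, float]
    mean_total_span: float
    mean_distinct_providers: float
    mean_distinct_specialties: float
    cardio_thoracic_share: float
    n_events_span: int

    def setting_window_mean(self, window: str, setting: Setting | str) -> float:
        setting = Setting(setting).value
        sub = self.table[(self.table.window == window) & (self.table.setting == setting)]
        return float(sub["mean"].sum())

    def setting_span_mean(self, setting: Setting | str) -> float:
        setting = Setting(setting).value
        return float(self.table[self.table.setting == setting]["mean"].sum())


def summarize(
    records: Mapping[str, PatientRecord] | Sequence[PatientRecord],
    anchors: Mapping[str, date],
    n_years: int = 3,
    vocabulary: SpecialtyVocabulary = defaults.SPECIALTY_VOCABULARY,
    observation_start: Optional[Mapping[str, date]] = None,
) -> HcruSummary:
    """Windowed utilization summary for an anchored cohort.

    Every patient in ``anchors`` must be present in ``records``; an empty
    cohort is an error.  ``observation_start`` (e.g. per-patient lookback
    dates) feeds the complete-case denominators; without it every patient
    counts as fully observed.
    """
    if not isinstance(records, Mapping):
        records = {r.patient_id: r for r in records}
    if not anchors:
        raise ValueError("empty cohort")
    missing = [pid for pid in anchors if pid not in records]
    if missing:
        raise ValueError(f"anchored patients missing from records: {missing[:5]}")

    n = len(anchors)
    labels = tuple(f"Y{k}" for k in range(1, n_years + 1))
    counts: dict[tuple[str, str, str], int] = {}
    window_patient_totals: dict[str, list[int]] = {w: [] for w in labels}
    observed_n: dict[str, int] = {w: 0 for w in labels}
    observed_totals: dict[str, int] = {w: 0 for w in labels}
    distinct_providers: list[int] = []
    distinct_specialties: list[int] = []
    cardio_events = 0
    total_events = 0

    for pid, anchor in anchors.items():
        spec = WindowSpec(anchor=anchor, n_years=n_years)
        per_window = dict.fromkeys(labels, 0)
        providers: set[str] = set()
        specialties: set[str] = set()
        for ev in records[pid].events:
            w = spec.window_of(ev.event_date)
            if w is None:
                continue
            canon = vocabulary.canonical(ev.treatment_specialty)
            counts[(w, ev.setting.value, canon)] = counts.get((w, ev.setting.value, canon), 0) + 1
            per_window[w] += 1
            providers.add(ev.provider)
            specialties.add(canon)
            total_events += 1
            if canon in CARDIO_THORACIC:
                cardio_events += 1
        obs = observation_start.get(pid) if observation_start else None
        for w in labels:
            window_patient_totals[w].append(per_window[w])
            if obs is None or obs <= spec.lower_bound(w):
                observed_n[w] += 1
                observed_totals[w] += per_window[w]
        distinct_providers.append(len(providers))
        distinct_specialties.append(len(specialties))

    rows = []
    for w in labels:
        for s in (Setting.AE, Setting.INPATIENT, Setting.OUTPATIENT):
            for spc in CANONICAL_SPECIALTIES:
                total = counts.get((w, s.value, spc), 0)
                if total == 0:
                    continue
                rows.append(
                    {
                        "window": w,
                        "setting": s.value,
                        "specialty": spc,
                        "total": total,
                        "mean": total / n,
                        "n_observed": observed_n[w],
                        "mean_observed": total / observed_n[w] if observed_n[w] else float("nan"),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["window", "setting", "specialty", "total", "mean", "n_observed", "mean_observed"],
    )
    window_mean_total = {w: sum(v) / n for w, v in window_patient_totals.items()}
    return HcruSummary(
        n_patients=n,
        table=table,
        window_mean_total=window_mean_total,
        mean_total_span=sum(window_mean_total.values()),
        mean_distinct_providers=sum(distinct_providers) / n,
        mean_distinct_specialties=sum(distinct_specialties) / n,
        cardio_thoracic_share=(cardio_events / total_events) if total_events else 0.0,
        n_events_span=total_events,
    )


def age_stratified_summary(
    records: Mapping[str, PatientRecord] | Sequence[PatientRecord],
    anchors: Mapping[str, date],
    demographics: Mapping[str, PatientDemographics] | Iterable[PatientDemographics],
    boundary: float = 50.0,
    **kwargs,
) -> dict[str, Optional[HcruSummary]]:
    """Separate summaries for patients aged < boundary and >= boundary at
    their anchor date.  An empty band is reported as None, not an error."""
    if not isinstance(records, Mapping):
        records = {r.patient_id: r for r in records}
    if not isinstance(demographics, Mapping):
        demographics = {d.patient_id: d for d in demographics}
    young = {p: a for p, a in anchors.items() if demographics[p].age_at(a) < boundary}
    old = {p: a for p, a in anchors.items() if demographics[p].age_at(a) >= boundary}
    lo_label = f"<{boundary:g}"
    hi_label = f">={boundary:g}"
    return {
        lo_label: summarize(records, young, **kwargs) if young else None,
        hi_label: summarize(records, old, **kwargs) if old else None,
    }


def brute_force_window_counts(
    record: PatientRecord, anchor: date, n_years: int = 3
) -> dict[tuple[str, str], int]:
    """Direct per-(window, setting) count for one patient — the oracle the
    summary tables are checked against."""
    out: dict[tuple[str, str], int] = {}
    for ev in record.events:
        days_before = (anchor - ev.event_date).days
        for k in range(1, n_years + 1):
            if (k - 1) * 365 < days_before <= k * 365:
                key = (f"Y{k}", ev.setting.value)
                out[key] = out.get(key, 0) + 1
    return out
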