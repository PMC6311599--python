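"""Per-patient temporal anchors for the confirmed-iPAH validation cohort.

For each patient linked to a confirmed diagnosis, three anchors frame the
pre-diagnosis observation window:

* **index date** — the last relevant specialist event (cardiology,
  respiratory medicine or neurology) strictly before the patient's first
  visit to the specialist unit; the pre-diagnosis window is anchored here
  rather than at the first specialist-unit visit itself.
* **lookback date** — the start of observation: the patient's first recorded
  event, or five years before the index date, whichever is later.
* **first symptom** — the earliest event between lookback and index whose
  primary diagnosis (ICD-10) or any procedure (OPCS) matches the
  symptom/procedure code list.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .codes import CodeList, any_code_matches, code_matches
from .records import SETTING_ORDER, PatientRecord, SpecialtyVocabulary
from . import defaults


class ValidationExclusion(str, Enum):
    NONE = "NONE"
    NOT_LINKED = "NOT_LINKED"
    HCRU_CAP = "HCRU_CAP"
    INSUFFICIENT_PRE_INDEX = "INSUFFICIENT_PRE_INDEX"
    NO_INDEX_EVENT = "NO_INDEX_EVENT"


@dataclass(frozen=True)
class AnchorConfig:
    relevant_specialties: frozenset[str] = frozenset({"CARDIOLOGY", "RESPIRATORY", "NEUROLOGY"})
    symptom_codes_icd10: CodeList = defaults.SYMPTOM_CODES_ICD10
    symptom_codes_opcs: Optional[CodeList] = defaults.SYMPTOM_CODES_OPCS
    lookback_horizon_days: int = 5 * 365
    min_pre_index_days: int = 3 * 365
    hcru_cap: int = 250
    specialty_vocabulary: SpecialtyVocabulary = defaults.SPECIALTY_VOCABULARY

    def __post_init__(self) -> None:
        if self.lookback_horizon_days <= 0 or self.min_pre_index_days <= 0:
            raise ValueError("durations must be positive")
        if not self.relevant_specialties:
            raise ValueError("relevant_specialties must be non-empty")


@dataclass(frozen=True)
class PatientAnchors:
    patient_id: str
    index_date: date
    lookback_date: date
    first_symptom_date: Optional[date]
    first_symptom_specialty: Optional[str]
    first_center_visit: date

    def __post_init__(self) -> None:
        if not (self.lookback_date <= self.index_date <= self.first_center_visit):
            raise ValueError(
                f"{self.patient_id}: anchors out of order "
                f"({self.lookback_date} / {self.index_date} / {self.first_center_visit})"
            )
        if self.first_symptom_date is not None and not (
            self.lookback_date <= self.first_symptom_date <= self.index_date
        ):
            raise ValueError(f"{self.patient_id}: first symptom outside lookback window")


def derive_index_date(
    record: PatientRecord, first_center_visit: date, cfg: AnchorConfig
) -> Optional[date]:
    """Latest relevant-specialty event strictly before the first center
    visit; None when the patient has no such event."""
    vocab = cfg.specialty_vocabulary
    best: Optional[date] = None
    for ev in record.events:
        if ev.event_date >= first_center_visit:
            break  # events are date-sorted
        if vocab.canonical(ev.treatment_specialty) in cfg.relevant_specialties:
            best = ev.event_date
    return best


def derive_lookback_date(record: PatientRecord, index_date: date, cfg: AnchorConfig) -> date:
    first = record.first_event_date()
    if first is None:
        raise ValueError(f"{record.patient_id}: empty record has no lookback date")
    return max(first, index_date - timedelta(days=cfg.lookback_horizon_days))


def derive_first_symptom(
    record: PatientRecord, lookback_date: date, index_date: date, cfg: AnchorConfig
) -> Optional[tuple[date, str]]:
    """Earliest event in [lookback, index] whose primary diagnosis matches
    the ICD-10 symptom list or whose procedures match the OPCS list.

    Diagnosis matching is restricted to the primary field (symptom codes in
    secondary positions do not qualify); procedures have no primary field so
    any position counts.  Same-day ties are broken by setting
    (AE < INPATIENT < OUTPATIENT), then by file order.
    """
    candidates = []
    for pos, ev in enumerate(record.events):
        if not lookback_date <= ev.event_date <= index_date:
            continue
        hit = ev.primary_diagnosis is not None and code_matches(
            ev.primary_diagnosis, cfg.symptom_codes_icd10
        )
        if not hit and cfg.symptom_codes_opcs is not None:
            hit = any_code_matches(ev.procedures, cfg.symptom_codes_opcs)
        if hit:
            candidates.append((ev.event_date, SETTING_ORDER[ev.setting], pos, ev))
    if not candidates:
        return None
    _, _, _, ev = min(candidates)
    return ev.event_date, cfg.specialty_vocabulary.canonical(ev.treatment_specialty)


def derive_anchors(
    record: PatientRecord, first_center_visit: date, cfg: AnchorConfig
) -> Optional[PatientAnchors]:
    """All anchors for one patient; None when no index event exists."""
    index = derive_index_date(record, first_center_visit, cfg)
    if index is None:
        return None
    lookback = derive_lookback_date(record, index, cfg)
    symptom = derive_first_symptom(record, lookback, index, cfg)
    return PatientAnchors(
        patient_id=record.patient_id,
        index_date=index,
        lookback_date=lookback,
        first_symptom_date=symptom[0] if symptom else None,
        first_symptom_specialty=symptom[1] if symptom else None,
        first_center_visit=first_center_visit,
    )


def validation_eligibility(
    records: Mapping[str, PatientRecord],
    first_center_visits: Mapping[str, date],
    linked_ids: Iterable[str],
    cfg: AnchorConfig,
) -> tuple[dict[str, PatientAnchors], list[tuple[str, int]]]:
    """Validation-cohort filter over linked confirmed-iPAH patients.

    ``first_center_visits`` maps every candidate patient (linked or not) to
    their first specialist-unit visit; ``linked_ids`` is the subset that
    linked cleanly.  Patients are excluded, first failing rule counted, if:
    (1) they did not link; (2) they have >= cap total events; (3) they have
    less than the minimum span of data before the index event (measured
    from the earliest recorded event, not the capped lookback date); or
    they have no derivable index event.  Returns anchors for the eligible
    cohort and the ordered attrition rows.
    """
    linked = set(linked_ids)
    candidates = list(first_center_visits)
    counts = {
        ValidationExclusion.NOT_LINKED: 0,
        ValidationExclusion.HCRU_CAP: 0,
        ValidationExclusion.INSUFFICIENT_PRE_INDEX: 0,
        ValidationExclusion.NO_INDEX_EVENT: 0,
    }
    eligible: dict[str, PatientAnchors] = {}
    for pid in candidates:
        if pid not in linked:
            counts[ValidationExclusion.NOT_LINKED] += 1
            continue
        record = records[pid]
        if len(record.events) >= cfg.hcru_cap:
            counts[ValidationExclusion.HCRU_CAP] += 1
            continue
        anchors = derive_anchors(record, first_center_visits[pid], cfg)
        if anchors is None:
            counts[ValidationExclusion.NO_INDEX_EVENT] += 1
            continue
        first = record.first_event_date()
        if (anchors.index_date - first).days < cfg.min_pre_index_days:
            counts[ValidationExclusion.INSUFFICIENT_PRE_INDEX] += 1
            continue
        eligible[pid] = anchors
    rows: list[tuple[str, int]] = [("CANDIDATES", len(candidates))]
    remaining = len(candidates)
    for rule in (
        ValidationExclusion.NOT_LINKED,
        ValidationExclusion.HCRU_CAP,
        ValidationExclusion.NO_INDEX_EVENT,
        ValidationExclusion.INSUFFICIENT_PRE_INDEX,
    ):
        remaining -= counts[rule]
        rows.append((rule.value, remaining))
    return eligible, rows


def first_symptom_specialty_distribution(
    anchors: Iterable[PatientAnchors],
) -> tuple[dict[str, float], int]:
    """Percentage of patients per first-symptom specialty, over patients WITH
    a first symptom, plus the count of patients without one."""
    anchors = list(anchors)
    if not anchors:
        raise ValueError("empty cohort")
    with_symptom = [a for a in anchors if a.first_symptom_specialty is not None]
    absent = len(anchors) - len(with_symptom)
    if not with_symptom:
        return {}, absent
    counts: dict[str, int] = {}
    for a in with_symptom:
        counts[a.first_symptom_specialty] = counts.get(a.first_symptom_specialty, 0) + 1
    total = len(with_symptom)
    return {k: 100.0 * v / total for k, v in sorted(counts.items())}, absent
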