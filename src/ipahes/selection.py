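"""Probable-iPAH selection cascade over hospital-episode histories.

Starting from every patient carrying a pulmonary-hypertension ICD-10 code,
patients are excluded — in a fixed order, recording the FIRST failing rule —
if they (after research-opt-out removal): (1) never underwent right heart
catheterization (RHC); (2) never had their RHC at an adult specialist PH
center; (3) carry a non-iPAH diagnosis code; (4) were aged under 18 at
diagnosis or attended the pediatric specialist center; (5) have less than
the minimum pre-diagnosis lookback (or were diagnosed before the earliest
inclusion date); (6) reside outside England; (7) have ≥ cap total episodes
(atypically heavy utilizers whose histories would dominate cohort means).
The diagnosis date is the earliest RHC at an adult specialist center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .codes import CodeList, any_code_matches
from .records import CenterRegistry, Gender, PatientDemographics, PatientRecord
from . import defaults


class ExclusionRule(str, Enum):
    NONE = "NONE"
    OPT_OUT = "OPT_OUT"
    NO_PH_CODE = "NO_PH_CODE"
    NO_RHC = "NO_RHC"
    NO_SPECIALIST_CENTER = "NO_SPECIALIST_CENTER"
    NON_IPAH_CODE = "NON_IPAH_CODE"
    PEDIATRIC = "PEDIATRIC"
    INSUFFICIENT_LOOKBACK = "INSUFFICIENT_LOOKBACK"
    NON_ENGLAND = "NON_ENGLAND"
    HCRU_CAP = "HCRU_CAP"


#: Cascade order; the recorded exclusion reason is the first failing rule.
CASCADE_ORDER = (
    ExclusionRule.OPT_OUT,
    ExclusionRule.NO_PH_CODE,
    ExclusionRule.NO_RHC,
    ExclusionRule.NO_SPECIALIST_CENTER,
    ExclusionRule.NON_IPAH_CODE,
    ExclusionRule.PEDIATRIC,
    ExclusionRule.INSUFFICIENT_LOOKBACK,
    ExclusionRule.NON_ENGLAND,
    ExclusionRule.HCRU_CAP,
)

#: Rules applied after the probable-iPAH cohort is formed (the analysis
#: subset restrictions); used to report incidence on the probable cohort.
POST_PROBABLE_RULES = frozenset(
    {
        ExclusionRule.INSUFFICIENT_LOOKBACK,
        ExclusionRule.NON_ENGLAND,
        ExclusionRule.HCRU_CAP,
    }
)


@dataclass(frozen=True)
class SelectionConfig:
    ph_codes: CodeList = defaults.PH_CODES
    non_ipah_exclusion_codes: CodeList = defaults.NON_IPAH_CODES
    rhc_procedure_codes: CodeList = defaults.RHC_CODES
    centers: CenterRegistry = defaults.CENTERS
    adult_age_threshold: float = 18.0
    min_lookback_days: int = 3 * 365
    hcru_cap: int = 250
    required_residence: str = "ENGLAND"
    earliest_diagnosis_for_inclusion: Optional[date] = None
    #: search primary + all secondary positions for PH codes ("all"), or the
    #: primary field only ("primary")
    ph_code_scope: str = "all"

    def __post_init__(self) -> None:
        if self.adult_age_threshold <= 0 or self.min_lookback_days <= 0 or self.hcru_cap <= 0:
            raise ValueError("selection thresholds must be positive")
        if self.ph_code_scope not in {"all", "primary"}:
            raise ValueError(f"ph_code_scope must be 'all' or 'primary', got {self.ph_code_scope!r}")


@dataclass(frozen=True)
class SelectionOutcome:
    patient_id: str
    included: bool
    exclusion_rule: ExclusionRule
    diagnosis_date: Optional[date]

    def __post_init__(self) -> None:
        if self.included != (self.exclusion_rule is ExclusionRule.NONE):
            raise ValueError("included must hold exactly when exclusion_rule is NONE")


@dataclass(frozen=True)
class AttritionTable:
    """Ordered (rule label, n remaining after the rule) counts, first row
    being the input cohort size — the patient-flow diagram as a table."""

    rows: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = [n for _, n in self.rows]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("attrition counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "n_remaining"])


def _has_ph_code(record: PatientRecord, cfg: SelectionConfig) -> bool:
    for ev in record.events:
        codes = ev.all_diagnoses() if cfg.ph_code_scope == "all" else (
            (ev.primary_diagnosis,) if ev.primary_diagnosis else ()
        )
        if any_code_matches(codes, cfg.ph_codes):
            return True
    return False


def assign_diagnosis_date(record: PatientRecord, cfg: SelectionConfig) -> Optional[date]:
    """Date of the earliest RHC performed at an adult specialist PH center,
    or None if the patient has no such procedure."""
    for ev in record.events:  # events are date-sorted
        if ev.provider in cfg.centers.adult_specialist_providers and any_code_matches(
            ev.procedures, cfg.rhc_procedure_codes
        ):
            return ev.event_date
    return None


def _first_failing_rule(
    record: PatientRecord, cfg: SelectionConfig
) -> tuple[ExclusionRule, Optional[date]]:
    demo = record.demographics
    has_rhc = any(
        any_code_matches(ev.procedures, cfg.rhc_procedure_codes) for ev in record.events
    )
    diagnosis = assign_diagnosis_date(record, cfg) if has_rhc else None

    if demo.research_opt_out:
        return ExclusionRule.OPT_OUT, diagnosis
    if not _has_ph_code(record, cfg):
        return ExclusionRule.NO_PH_CODE, diagnosis
    if not has_rhc:
        return ExclusionRule.NO_RHC, diagnosis
    if diagnosis is None:
        return ExclusionRule.NO_SPECIALIST_CENTER, diagnosis
    if any(
        any_code_matches(ev.all_diagnoses(), cfg.non_ipah_exclusion_codes)
        for ev in record.events
    ):
        return ExclusionRule.NON_IPAH_CODE, diagnosis
    pediatric_provider = any(
        ev.provider in cfg.centers.pediatric_providers for ev in record.events
    )
    if demo.age_at(diagnosis) < cfg.adult_age_threshold or pediatric_provider:
        return ExclusionRule.PEDIATRIC, diagnosis
    first = record.first_event_date()
    short_lookback = (diagnosis - first).days < cfg.min_lookback_days
    too_early = (
        cfg.earliest_diagnosis_for_inclusion is not None
        and diagnosis < cfg.earliest_diagnosis_for_inclusion
    )
    if short_lookback or too_early:
        return ExclusionRule.INSUFFICIENT_LOOKBACK, diagnosis
    if demo.residence_region.strip().upper() != cfg.required_residence:
        return ExclusionRule.NON_ENGLAND, diagnosis
    if len(record.events) >= cfg.hcru_cap:
        return ExclusionRule.HCRU_CAP, diagnosis
    return ExclusionRule.NONE, diagnosis


def evaluate_patient(record: PatientRecord, cfg: SelectionConfig) -> SelectionOutcome:
    rule, diagnosis = _first_failing_rule(record, cfg)
    return SelectionOutcome(
        patient_id=record.patient_id,
        included=rule is ExclusionRule.NONE,
        exclusion_rule=rule,
        diagnosis_date=diagnosis,
    )


def select(
    records: Sequence[PatientRecord], cfg: SelectionConfig
) -> tuple[list[SelectionOutcome], AttritionTable]:
    """Run the full cascade; returns per-patient outcomes and the ordered
    attrition table (first row = input size, then n remaining after each
    rule in cascade order)."""
    outcomes = [evaluate_patient(r, cfg) for r in records]
    excluded_at = {rule: 0 for rule in CASCADE_ORDER}
    for o in outcomes:
        if o.exclusion_rule is not ExclusionRule.NONE:
            excluded_at[o.exclusion_rule] += 1
    rows: list[tuple[str, int]] = [("INPUT", len(outcomes))]
    remaining = len(outcomes)
    for rule in CASCADE_ORDER:
        remaining -= excluded_at[rule]
        rows.append((rule.value, remaining))
    return outcomes, AttritionTable(rows=tuple(rows))


def incidence(
    outcomes: Iterable[SelectionOutcome],
    years: Sequence[int],
    population_denominator: float,
    stage: str = "analysis",
) -> dict[int, float]:
    """Annual incidence of new diagnoses per million population.

    ``stage="analysis"`` counts fully included patients; ``stage="probable"``
    counts the probable-iPAH cohort (patients surviving the diagnostic rules,
    before the analysis-subset restrictions on lookback, residence and
    utilization), which is the cohort whose incidence is compared with
    registry literature — the later restrictions would otherwise zero out
    early calendar years by construction.
    """
    if population_denominator <= 0:
        raise ValueError("population_denominator must be positive")
    if stage not in {"analysis", "probable"}:
        raise ValueError(f"unknown stage {stage!r}")
    keep = {ExclusionRule.NONE} if stage == "analysis" else (
        {ExclusionRule.NONE} | POST_PROBABLE_RULES
    )
    out = {y: 0 for y in years}
    for o in outcomes:
        if o.exclusion_rule in keep and o.diagnosis_date is not None:
            y = o.diagnosis_date.year
            if y in out:
                out[y] += 1
    return {y: n * 1e6 / population_denominator for y, n in out.items()}


def demographics_profile(
    outcomes: Iterable[SelectionOutcome],
    demographics: Mapping[str, PatientDemographics] | Iterable[PatientDemographics],
    age_bands: Sequence[float] = (50.0,),
) -> tuple[Optional[float], dict[str, float]]:
    """Gender and age profile of the included cohort.

    Returns (fraction female, fraction per age band).  Bands are defined by
    the given boundaries with "> boundary" strict: with the default (50,),
    the bands are "<=50" and ">50" and an exact age of 50 falls in the lower
    band.  Ages are computed at the diagnosis date.  An empty included set
    returns (None, {}).
    """
    if not isinstance(demographics, Mapping):
        demographics = {d.patient_id: d for d in demographics}
    included = [o for o in outcomes if o.included]
    if not included:
        return None, {}
    missing = [o.patient_id for o in included if o.patient_id not in demographics]
    if missing:
        raise ValueError(f"included patients missing demographics: {missing[:5]}")
    n = len(included)
    n_female = sum(
        1 for o in included if demographics[o.patient_id].gender is Gender.F
    )
    bounds = sorted(age_bands)
    labels = [f"<={bounds[0]:g}"] + [f">{b:g}" for b in bounds]
    counts = dict.fromkeys(labels, 0)
    for o in included:
        age = demographics[o.patient_id].age_at(o.diagnosis_date)
        label = labels[0]
        for i, b in enumerate(bounds):
            if age > b:
                label = labels[i + 1]
        counts[label] += 1
    return n_female / n, {k: v / n for k, v in counts.items()}


def brute_force_outcome(record: PatientRecord, cfg: SelectionConfig) -> SelectionOutcome:
    """Independent re-evaluation of every rule for one patient, written as a
    flat list of predicates rather than a cascade; used as a cross-check."""
    demo = record.demographics
    diagnosis = None
    for ev in sorted(record.events, key=lambda e: e.event_date):
        if any_code_matches(ev.procedures, cfg.rhc_procedure_codes) and (
            ev.provider in cfg.centers.adult_specialist_providers
        ):
            diagnosis = ev.event_date
            break
    checks: list[tuple[ExclusionRule, bool]] = []
    checks.append((ExclusionRule.OPT_OUT, demo.research_opt_out))
    checks.append((ExclusionRule.NO_PH_CODE, not _has_ph_code(record, cfg)))
    checks.append(
        (
            ExclusionRule.NO_RHC,
            not any(
                any_code_matches(ev.procedures, cfg.rhc_procedure_codes)
                for ev in record.events
            ),
        )
    )
    checks.append((ExclusionRule.NO_SPECIALIST_CENTER, diagnosis is None))
    checks.append(
        (
            ExclusionRule.NON_IPAH_CODE,
            any(
                any_code_matches(ev.all_diagnoses(), cfg.non_ipah_exclusion_codes)
                for ev in record.events
            ),
        )
    )
    if diagnosis is not None:
        checks.append(
            (
                ExclusionRule.PEDIATRIC,
                demo.age_at(diagnosis) < cfg.adult_age_threshold
                or any(ev.provider in cfg.centers.pediatric_providers for ev in record.events),
            )
        )
        checks.append(
            (
                ExclusionRule.INSUFFICIENT_LOOKBACK,
                (diagnosis - record.first_event_date()).days < cfg.min_lookback_days
                or (
                    cfg.earliest_diagnosis_for_inclusion is not None
                    and diagnosis < cfg.earliest_diagnosis_for_inclusion
                ),
            )
        )
    checks.append(
        (ExclusionRule.NON_ENGLAND, demo.residence_region.strip().upper() != cfg.required_residence)
    )
    checks.append((ExclusionRule.HCRU_CAP, len(record.events) >= cfg.hcru_cap))
    order = {rule: i for i, rule in enumerate(CASCADE_ORDER)}
    failing = sorted((rule for rule, failed in checks if failed), key=order.__getitem__)
    rule = failing[0] if failing else ExclusionRule.NONE
    return SelectionOutcome(
        patient_id=record.patient_id,
        included=rule is ExclusionRule.NONE,
        exclusion_rule=rule,
        diagnosis_date=diagnosis,
    )
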