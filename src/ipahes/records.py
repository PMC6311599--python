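"""Domain types for episode, demographic and registry data.

The atom of every computation is an :class:`EpisodeEvent` — a single hospital
interaction (A&E attendance, inpatient episode, or outpatient appointment)
with its calendar date, coded diagnoses and procedures, treatment specialty
and provider.  A :class:`PatientRecord` is a patient's demographics plus the
date-ordered event history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from typing import Mapping, Optional, Sequence

from .codes import ClinicalCode


class Setting(str, Enum):
    AE = "AE"
    INPATIENT = "INPATIENT"
    OUTPATIENT = "OUTPATIENT"


# Same-day tie-breaks throughout the package use this fixed setting order.
SETTING_ORDER = {Setting.AE: 0, Setting.INPATIENT: 1, Setting.OUTPATIENT: 2}


class Gender(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"


class RegistrySource(str, Enum):
    ASPIRE = "ASPIRE"
    INFOFLEX = "INFOFLEX"
    ARQ = "ARQ"


class FinalDiagnosis(str, Enum):
    IPAH = "IPAH"
    OTHER_PH = "OTHER_PH"
    NO_PH = "NO_PH"
    UNASSIGNED = "UNASSIGNED"


#: Canonical treatment-specialty vocabulary used for all reporting.
CANONICAL_SPECIALTIES = (
    "CARDIOLOGY",
    "RESPIRATORY",
    "NEUROLOGY",
    "GENERAL_MEDICINE",
    "GERIATRIC_MEDICINE",
    "AE",
    "GENERAL_SURGERY",
    "OTHER",
)

#: Specialties counted as "cardiology or thoracic" in utilization shares.
CARDIO_THORACIC = frozenset({"CARDIOLOGY", "RESPIRATORY"})


@dataclass(frozen=True)
class SpecialtyVocabulary:
    """Maps raw treatment-specialty codes to the canonical vocabulary.

    Raw codes in English hospital extracts are numeric treatment-function
    codes ("320" = cardiology); canonical names are accepted as-is.  Unmapped
    codes fall back to OTHER.
    """

    mapping: Mapping[str, str]

    def canonical(self, raw: str) -> str:
        raw = (raw or "").strip().upper()
        if raw in CANONICAL_SPECIALTIES:
            return raw
        return self.mapping.get(raw, "OTHER")


@dataclass(frozen=True)
class EpisodeEvent:
    patient_id: str
    setting: Setting
    event_date: date
    primary_diagnosis: Optional[ClinicalCode] = None
    secondary_diagnoses: tuple[ClinicalCode, ...] = ()
    procedures: tuple[ClinicalCode, ...] = ()
    treatment_specialty: str = "OTHER"
    provider: str = ""

    def all_diagnoses(self) -> tuple[ClinicalCode, ...]:
        if self.primary_diagnosis is None:
            return self.secondary_diagnoses
        return (self.primary_diagnosis,) + self.secondary_diagnoses


@dataclass(frozen=True)
class PatientDemographics:
    patient_id: str
    gender: Gender
    birth_year: int
    birth_month: int
    gp_postcode: str = ""
    residence_region: str = "ENGLAND"
    research_opt_out: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.birth_month <= 12:
            raise ValueError(
                f"patient {self.patient_id}: birth_month {self.birth_month} not in 1..12"
            )

    def age_at(self, on: date) -> float:
        """Age in years at a calendar date.

        Episode data carries month and year of birth only; the day of birth
        is taken as the 15th, which halves the maximum dating error.
        """
        birth = date(self.birth_year, self.birth_month, 15)
        return (on - birth).days / 365.25


@dataclass(frozen=True)
class PatientRecord:
    demographics: PatientDemographics
    events: tuple[EpisodeEvent, ...]

    def __post_init__(self) -> None:
        pid = self.demographics.patient_id
        for ev in self.events:
            if ev.patient_id != pid:
                raise ValueError(
                    f"event patient_id {ev.patient_id!r} does not match record {pid!r}"
                )
        # enforce ascending date order on construction, stable within a day
        object.__setattr__(
            self,
            "events",
            tuple(sorted(self.events, key=lambda e: e.event_date)),
        )

    @property
    def patient_id(self) -> str:
        return self.demographics.patient_id

    def first_event_date(self) -> Optional[date]:
        return self.events[0].event_date if self.events else None


@dataclass(frozen=True)
class RegistryRecord:
    """One clinical-registry row (diagnostic registry, operational clinical
    database, or biobank) carrying the clinician-confirmed final diagnosis."""

    registry_source: RegistrySource
    nhs_identifier: Optional[str]
    gender: Gender
    birth_year: int
    birth_month: int
    gp_postcode: str
    final_diagnosis: FinalDiagnosis
    first_visit_date: date
    demographic_conflict: bool = False


@dataclass(frozen=True)
class CenterRegistry:
    """Provider codes of the adult specialist PH centers and the pediatric
    specialist center; diagnosis is anchored at the adult centers and any
    attendance at the pediatric center marks a pediatric patient."""

    adult_specialist_providers: frozenset[str]
    pediatric_providers: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.adult_specialist_providers & self.pediatric_providers
        if overlap:
            raise ValueError(f"providers in both adult and pediatric sets: {sorted(overlap)}")
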