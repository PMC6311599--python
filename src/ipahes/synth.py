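"""Seeded generator of linked episode / demographics / registry datasets.

The generator emulates the structure of a national hospital-episode extract
joined to a specialist-center clinical registry: per-patient event streams
across A&E, inpatient and outpatient settings whose intensity escalates in
the years approaching diagnosis, a diagnosis encounter (right-heart-
catheterization at a specialist center carrying a PH ICD-10 code), and a
registry mirror with matchable demographics.  Each contrast subpopulation
is constructed to violate exactly one selection rule, so the selection
cascade, the linkage step and every windowed summary can be validated
against known ground truth.

Event counts are Poisson per patient x setting x pre-anchor year (the
minimal count model consistent with reporting means), with event dates
uniform within the year.  All randomness flows from one seed, split
hierarchically by (subpopulation, patient index) so that adding patients or
subpopulations does not perturb earlier patients' draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import CodeSystem, normalize_code
from .io import events_to_frame, write_events, write_registry
from .records import (
    EpisodeEvent,
    FinalDiagnosis,
    Gender,
    PatientDemographics,
    PatientRecord,
    RegistryRecord,
    RegistrySource,
    Setting,
)
from . import defaults


class SubpopLabel(str, Enum):
    IPAH_CASE = "IPAH_CASE"
    OTHER_PH = "OTHER_PH"
    NO_PH_CONTROL = "NO_PH_CONTROL"
    PEDIATRIC = "PEDIATRIC"
    NON_ENGLAND = "NON_ENGLAND"
    HIGH_UTILIZER = "HIGH_UTILIZER"
    NO_RHC = "NO_RHC"
    NON_SPECIALIST_ONLY = "NON_SPECIALIST_ONLY"


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent generator configuration."""


_SETTINGS = (Setting.AE, Setting.INPATIENT, Setting.OUTPATIENT)


@dataclass(frozen=True)
class SubpopulationSpec:
    """One generated subpopulation with its utilization and coding profile.

    ``base_rates`` are mean annual event counts per setting in the quiet
    years; ``escalation`` maps (setting, pre-anchor year 1..3) to a
    multiplicative ramp (year 1 = the year immediately before the anchor).
    ``gap_days`` > 0 plants an explicit index encounter (a relevant-specialty
    event) that many days before the diagnosis / first-center-visit date,
    giving validation-style data with a known true index date; 0 gives
    pilot-style data anchored directly on the diagnosis date.
    """

    label: SubpopLabel
    n: int
    base_rates: Mapping[Setting, float]
    escalation: Mapping[Setting, Mapping[int, float]] = field(default_factory=dict)
    specialty_mix: Mapping[str, float] = field(default_factory=lambda: {"OTHER": 1.0})
    symptom_specialty_mix: Optional[Mapping[str, float]] = None
    ph_code_prob: float = 1.0
    rhc_code_prob: float = 1.0
    history_years: int = 5
    gap_days: int = 0
    female_rate: float = 0.6
    p_age_over_50: float = 0.64
    age_range: Optional[tuple[int, int]] = None
    diagnosis_window: Optional[tuple[date, date]] = None
    min_total_events: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError(f"{self.label.value}: n must be >= 0")
        for s, r in self.base_rates.items():
            if r < 0:
                raise ConfigError(f"{self.label.value}: negative rate for {s}")
        for mix in (self.specialty_mix, self.symptom_specialty_mix):
            if mix is not None and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{self.label.value}: specialty mix must sum to 1")
        for p in (self.ph_code_prob, self.rhc_code_prob, self.female_rate, self.p_age_over_50):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{self.label.value}: probability {p} outside [0, 1]")
        if self.history_years < 1:
            raise ConfigError(f"{self.label.value}: history_years must be >= 1")
        if self.label is SubpopLabel.PEDIATRIC:
            rng = self.age_range or (5, 17)
            if rng[0] >= 18:
                raise ConfigError("PEDIATRIC subpopulation with adult age range")

    def rate(self, setting: Setting, year: int) -> float:
        base = self.base_rates.get(setting, 0.0)
        return base * self.escalation.get(setting, {}).get(year, 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    subpopulations: Sequence[SubpopulationSpec]
    study_window: tuple[date, date] = (date(2009, 4, 1), date(2014, 10, 31))
    population_denominator: float = 53_000_000
    registry_discrepancy_rate: float = 0.014
    multi_source_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.study_window[0] >= self.study_window[1]:
            raise ConfigError("study_window start must precede end")
        for p in (self.registry_discrepancy_rate, self.multi_source_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for sp in self.subpopulations:
            win = sp.diagnosis_window
            if win is not None and not (
                self.study_window[0] <= win[0] <= win[1] <= self.study_window[1]
            ):
                raise ConfigError(
                    f"{sp.label.value}: diagnosis_window outside study_window"
                )


GROUND_TRUTH_COLUMNS = [
    "patient_id",
    "label",
    "diagnosis_date",
    "index_date",
    "first_center_visit",
    "first_symptom_date",
    "first_symptom_specialty",
    "total_events",
    "registry_discrepant",
] + [f"y{k}_{s.value.lower()}" for k in (1, 2, 3) for s in _SETTINGS]


@dataclass
class GeneratedDataset:
    episodes: list[EpisodeEvent]
    demographics: list[PatientDemographics]
    registry: list[RegistryRecord]
    ground_truth: pd.DataFrame

    def records(self) -> list[PatientRecord]:
        by_pid: dict[str, list[EpisodeEvent]] = {}
        for ev in self.episodes:
            by_pid.setdefault(ev.patient_id, []).append(ev)
        return [
            PatientRecord(demographics=d, events=tuple(by_pid.get(d.patient_id, ())))
            for d in self.demographics
        ]

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "episodes": out_dir / "episodes.csv",
            "demographics": out_dir / "demographics.csv",
            "registry": out_dir / "registry.csv",
            "ground_truth": out_dir / "ground_truth.csv",
        }
        write_events(self.records(), paths["episodes"], paths["demographics"])
        write_registry(self.registry, paths["registry"])
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def _choice(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    p = np.asarray([mix[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=p / p.sum()))


_IPAH_LIKE = {
    SubpopLabel.IPAH_CASE,
    SubpopLabel.NO_RHC,
    SubpopLabel.NON_SPECIALIST_ONLY,
    SubpopLabel.HIGH_UTILIZER,
    SubpopLabel.PEDIATRIC,
    SubpopLabel.NON_ENGLAND,
}


def _final_diagnosis(label: SubpopLabel) -> FinalDiagnosis:
    if label in _IPAH_LIKE:
        return FinalDiagnosis.IPAH
    if label is SubpopLabel.OTHER_PH:
        return FinalDiagnosis.OTHER_PH
    return FinalDiagnosis.NO_PH


def _gen_patient(
    rng: np.random.Generator,
    pid: str,
    sp: SubpopulationSpec,
    cfg: GeneratorConfig,
) -> tuple[list[EpisodeEvent], PatientDemographics, list[RegistryRecord], dict]:
    icd = lambda c: normalize_code(c, CodeSystem.ICD10)
    opcs = lambda c: normalize_code(c, CodeSystem.OPCS)

    win = sp.diagnosis_window or cfg.study_window
    span = (win[1] - win[0]).days
    diagnosis = win[0] + timedelta(days=int(rng.integers(0, span + 1)))
    anchor = diagnosis - timedelta(days=sp.gap_days)

    # --- demographics -----------------------------------------------------
    gender = Gender.F if rng.random() < sp.female_rate else Gender.M
    if sp.age_range is not None:
        age = float(rng.integers(sp.age_range[0], sp.age_range[1] + 1))
    elif sp.label is SubpopLabel.PEDIATRIC:
        age = float(rng.integers(5, 18))
    elif rng.random() < sp.p_age_over_50:
        age = float(rng.integers(51, 86))
    else:
        age = float(rng.integers(20, 50))
    birth = diagnosis - timedelta(days=int(age * 365.25) + int(rng.integers(0, 300)))
    postcode = f"S{int(rng.integers(1, 99)):02d} {int(rng.integers(1, 9))}AB"
    region = "WALES" if sp.label is SubpopLabel.NON_ENGLAND else "ENGLAND"
    demo = PatientDemographics(
        patient_id=pid,
        gender=gender,
        birth_year=birth.year,
        birth_month=birth.month,
        gp_postcode=postcode,
        residence_region=region,
        research_opt_out=False,
    )

    # --- providers --------------------------------------------------------
    generals = defaults.GENERAL_PROVIDERS
    home, second = [generals[int(i)] for i in rng.choice(len(generals), size=2, replace=False)]

    def background_provider() -> str:
        u = rng.random()
        if u < 0.78:
            return home
        if u < 0.98:
            return second
        return generals[int(rng.integers(0, len(generals)))]

    # --- background pre-anchor events ------------------------------------
    events: list[EpisodeEvent] = []
    for year in range(1, sp.history_years + 1):
        for setting in _SETTINGS:
            rate = sp.rate(setting, year)
            if rate <= 0:
                continue
            for _ in range(int(rng.poisson(rate))):
                days_before = int(rng.integers((year - 1) * 365 + 1, year * 365 + 1))
                primary = None
                if setting is not Setting.AE or rng.random() < 0.5:
                    primary = icd(defaults.FILLER_ICD10[int(rng.integers(0, len(defaults.FILLER_ICD10)))])
                secondary = ()
                if rng.random() < 0.2:
                    secondary = (icd(defaults.FILLER_ICD10[int(rng.integers(0, len(defaults.FILLER_ICD10)))]),)
                events.append(
                    EpisodeEvent(
                        patient_id=pid,
                        setting=setting,
                        event_date=anchor - timedelta(days=days_before),
                        primary_diagnosis=primary,
                        secondary_diagnoses=secondary,
                        procedures=(),
                        treatment_specialty=_choice(rng, sp.specialty_mix),
                        provider=background_provider(),
                    )
                )

    # registration marker: guarantees the record spans the full history
    events.append(
        EpisodeEvent(
            patient_id=pid,
            setting=Setting.OUTPATIENT,
            event_date=anchor - timedelta(days=sp.history_years * 365),
            primary_diagnosis=icd("Z038"),
            treatment_specialty="OTHER",
            provider=home,
        )
    )

    # --- first-symptom tagging (re-labels an existing event) --------------
    symptom_date: Optional[date] = None
    symptom_specialty: Optional[str] = None
    horizon = min(2 * 365, sp.history_years * 365)
    eligible = [
        i
        for i, ev in enumerate(events[:-1])
        if 0 < (anchor - ev.event_date).days <= horizon
    ] or [
        i
        for i, ev in enumerate(events[:-1])
        if 0 < (anchor - ev.event_date).days <= 3 * 365
    ]
    if eligible:
        i = max(eligible, key=lambda j: (anchor - events[j].event_date).days)
        sym_codes = sorted(defaults.SYMPTOM_CODES_ICD10.entries)
        mix = sp.symptom_specialty_mix or sp.specialty_mix
        tagged = dataclasses.replace(
            events[i],
            primary_diagnosis=icd(sym_codes[int(rng.integers(0, len(sym_codes)))]),
            treatment_specialty=_choice(rng, mix),
        )
        events[i] = tagged
        symptom_date = tagged.event_date
        symptom_specialty = tagged.treatment_specialty

    # --- planted index encounter (validation-style data) ------------------
    index_date: Optional[date] = None
    if sp.gap_days > 0:
        index_date = anchor
        events.append(
            EpisodeEvent(
                patient_id=pid,
                setting=Setting.OUTPATIENT,
                event_date=anchor,
                primary_diagnosis=icd("Z038"),
                treatment_specialty=str(
                    rng.choice(["CARDIOLOGY", "RESPIRATORY", "NEUROLOGY"], p=[0.5, 0.4, 0.1])
                ),
                provider=home,
            )
        )

    # --- diagnosis encounter ----------------------------------------------
    if sp.label is SubpopLabel.NON_SPECIALIST_ONLY:
        dx_provider = home
    else:
        adult = sorted(defaults.ADULT_SPECIALIST_PROVIDERS)
        dx_provider = adult[int(rng.integers(0, len(adult)))]
    emits_ph = sp.label is not SubpopLabel.NO_PH_CONTROL and rng.random() < sp.ph_code_prob
    ph_code = str(rng.choice(["I270", "I272", "I279"], p=[0.7, 0.15, 0.15]))
    primary_dx = icd(ph_code) if emits_ph else icd("Z038")
    secondary_dx = ()
    if sp.label is SubpopLabel.OTHER_PH:
        secondary_dx = (icd("I509"),)
    emits_rhc = sp.label is not SubpopLabel.NO_RHC and rng.random() < sp.rhc_code_prob
    events.append(
        EpisodeEvent(
            patient_id=pid,
            setting=Setting.INPATIENT,
            event_date=diagnosis,
            primary_diagnosis=primary_dx,
            secondary_diagnoses=secondary_dx,
            procedures=(opcs("K652"),) if emits_rhc else (),
            treatment_specialty="CARDIOLOGY",
            provider=dx_provider,
        )
    )

    # --- heavy-utilizer top-up --------------------------------------------
    if sp.min_total_events is not None:
        while len(events) < sp.min_total_events:
            days_before = int(rng.integers(1, sp.history_years * 365 + 1))
            events.append(
                EpisodeEvent(
                    patient_id=pid,
                    setting=Setting.OUTPATIENT,
                    event_date=anchor - timedelta(days=days_before),
                    primary_diagnosis=icd("Z038"),
                    treatment_specialty=_choice(rng, sp.specialty_mix),
                    provider=home,
                )
            )

    events.sort(key=lambda e: e.event_date)

    # --- registry mirror ---------------------------------------------------
    source = RegistrySource(str(rng.choice([s.value for s in RegistrySource])))
    mirror_kwargs = dict(
        nhs_identifier=pid,
        gender=gender,
        birth_year=demo.birth_year,
        birth_month=demo.birth_month,
        gp_postcode=postcode,
    )
    discrepant = rng.random() < cfg.registry_discrepancy_rate
    if discrepant:
        kind = int(rng.integers(0, 4))
        if kind == 0:
            mirror_kwargs["nhs_identifier"] = None
        elif kind == 1:
            mirror_kwargs["gender"] = Gender.M if gender is Gender.F else Gender.F
        elif kind == 2:
            mirror_kwargs["birth_year"] = demo.birth_year - 1
        else:
            mirror_kwargs["gp_postcode"] = "S99 9ZZ"
    registry_rows = [
        RegistryRecord(
            registry_source=source,
            final_diagnosis=_final_diagnosis(sp.label),
            first_visit_date=diagnosis,
            **mirror_kwargs,
        )
    ]
    if rng.random() < cfg.multi_source_rate:
        others = [s for s in RegistrySource if s is not source]
        registry_rows.append(
            RegistryRecord(
                registry_source=others[int(rng.integers(0, len(others)))],
                nhs_identifier=pid,
                gender=gender,
                birth_year=demo.birth_year,
                birth_month=demo.birth_month,
                gp_postcode=postcode,
                final_diagnosis=FinalDiagnosis.UNASSIGNED,
                first_visit_date=diagnosis + timedelta(days=30),
            )
        )

    # --- ground truth -------------------------------------------------------
    gt = {
        "patient_id": pid,
        "label": sp.label.value,
        "diagnosis_date": diagnosis.isoformat(),
        "index_date": index_date.isoformat() if index_date else "",
        "first_center_visit": diagnosis.isoformat(),
        "first_symptom_date": symptom_date.isoformat() if symptom_date else "",
        "first_symptom_specialty": symptom_specialty or "",
        "total_events": len(events),
        "registry_discrepant": discrepant,
    }
    for k in (1, 2, 3):
        for setting in _SETTINGS:
            gt[f"y{k}_{setting.value.lower()}"] = 0
    for ev in events:
        days_before = (anchor - ev.event_date).days
        if 0 < days_before <= 3 * 365:
            k = (days_before + 364) // 365
            gt[f"y{k}_{ev.setting.value.lower()}"] += 1
    return events, demo, registry_rows, gt


def generate(config: GeneratorConfig) -> GeneratedDataset:
    """Generate the full linked dataset; fully reproducible for a fixed
    seed (outputs are byte-identical run to run)."""
    episodes: list[EpisodeEvent] = []
    demographics: list[PatientDemographics] = []
    registry: list[RegistryRecord] = []
    gt_rows: list[dict] = []
    for sub_i, sp in enumerate(config.subpopulations):
        for pat_i in range(sp.n):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, sub_i, pat_i])
            )
            pid = f"P{sub_i:02d}-{pat_i:05d}"
            evs, demo, reg, gt = _gen_patient(rng, pid, sp, config)
            episodes.extend(evs)
            demographics.append(demo)
            registry.extend(reg)
            gt_rows.append(gt)
    ground_truth = pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)
    return GeneratedDataset(episodes, demographics, registry, ground_truth)


def ground_truth_counts(
    ground_truth: pd.DataFrame, patient_id: str, window: str
) -> dict[str, int]:
    """Per-setting true event counts for one patient in window 'Y1'..'Y3'."""
    rows = ground_truth[ground_truth.patient_id == patient_id]
    if rows.empty:
        raise KeyError(f"unknown patient {patient_id!r}")
    k = int(window[1:])
    row = rows.iloc[0]
    return {s.value: int(row[f"y{k}_{s.value.lower()}"]) for s in _SETTINGS}


# ---------------------------------------------------------------------------
# Calibrated presets: the study conditions the package is exercised under.
# ---------------------------------------------------------------------------

#: Pilot-style clean cases: per-year (Y3, Y2, Y1) means — outpatient
#: (4.9, 5.9, 9.4) summing to 20.2, inpatient (0.7, 0.8, 1.8), A&E
#: (0.3, 0.4, 0.8); three-year total 25.0 with 12.0 in Y1, and half of all
#: events under cardiology/respiratory specialties.
PHASE1_BASE_RATES = {Setting.OUTPATIENT: 4.9, Setting.INPATIENT: 0.7, Setting.AE: 0.3}
PHASE1_ESCALATION = {
    Setting.OUTPATIENT: {1: 9.4 / 4.9, 2: 5.9 / 4.9},
    Setting.INPATIENT: {1: 1.8 / 0.7, 2: 0.8 / 0.7},
    Setting.AE: {1: 0.8 / 0.3, 2: 0.4 / 0.3},
}
PHASE1_SPECIALTY_MIX = {
    "CARDIOLOGY": 0.28,
    "RESPIRATORY": 0.22,
    "GENERAL_MEDICINE": 0.20,
    "NEUROLOGY": 0.03,
    "GERIATRIC_MEDICINE": 0.05,
    "AE": 0.07,
    "GENERAL_SURGERY": 0.05,
    "OTHER": 0.10,
}

#: Validation-style cases: outpatient (4.4, 5.3, 8.4) summing to 18.1,
#: inpatient (0.8, 0.9, 1.7), A&E (0.3, 0.4, 0.8); total 23.0; 32% of events
#: cardiology/thoracic; first-symptom specialty shares matching the
#: confirmed-cohort distribution.
PHASE2_BASE_RATES = {Setting.OUTPATIENT: 4.4, Setting.INPATIENT: 0.8, Setting.AE: 0.3}
PHASE2_ESCALATION = {
    Setting.OUTPATIENT: {1: 8.4 / 4.4, 2: 5.3 / 4.4},
    Setting.INPATIENT: {1: 1.7 / 0.8, 2: 0.9 / 0.8},
    Setting.AE: {1: 0.8 / 0.3, 2: 0.4 / 0.3},
}
PHASE2_SPECIALTY_MIX = {
    "CARDIOLOGY": 0.13,
    "RESPIRATORY": 0.19,
    "GENERAL_MEDICINE": 0.30,
    "NEUROLOGY": 0.03,
    "GERIATRIC_MEDICINE": 0.05,
    "AE": 0.05,
    "GENERAL_SURGERY": 0.05,
    "OTHER": 0.20,
}
PHASE2_SYMPTOM_SPECIALTY_MIX = {
    "GENERAL_MEDICINE": 0.360,
    "RESPIRATORY": 0.328,
    "CARDIOLOGY": 0.133,
    "GERIATRIC_MEDICINE": 0.031,
    "AE": 0.029,
    "GENERAL_SURGERY": 0.011,
    "OTHER": 0.108,
}


def phase1_case_spec(n: int, label: SubpopLabel = SubpopLabel.IPAH_CASE, **overrides) -> SubpopulationSpec:
    kwargs = dict(
        label=label,
        n=n,
        base_rates=PHASE1_BASE_RATES,
        escalation=PHASE1_ESCALATION,
        specialty_mix=PHASE1_SPECIALTY_MIX,
        history_years=5,
        gap_days=0,
        diagnosis_window=(date(2012, 4, 1), date(2014, 9, 30)),
    )
    kwargs.update(overrides)
    return SubpopulationSpec(**kwargs)


def phase2_case_spec(n: int, **overrides) -> SubpopulationSpec:
    kwargs = dict(
        label=SubpopLabel.IPAH_CASE,
        n=n,
        base_rates=PHASE2_BASE_RATES,
        escalation=PHASE2_ESCALATION,
        specialty_mix=PHASE2_SPECIALTY_MIX,
        symptom_specialty_mix=PHASE2_SYMPTOM_SPECIALTY_MIX,
        history_years=5,
        gap_days=76,
        diagnosis_window=(date(2012, 4, 1), date(2014, 9, 30)),
    )
    kwargs.update(overrides)
    return SubpopulationSpec(**kwargs)


def violator_spec(label: SubpopLabel, n: int, **overrides) -> SubpopulationSpec:
    """A pilot-style subpopulation violating exactly one selection rule."""
    if label is SubpopLabel.HIGH_UTILIZER:
        overrides.setdefault("min_total_events", 260)
    return phase1_case_spec(n, label=label, **overrides)


def default_phase1_config(
    seed: int, n_cases: int = 200, n_per_violator: int = 40
) -> GeneratorConfig:
    """Pilot-style study conditions: clean cases plus one subpopulation per
    targeted exclusion rule."""
    violators = [
        SubpopLabel.NO_PH_CONTROL,
        SubpopLabel.NO_RHC,
        SubpopLabel.NON_SPECIALIST_ONLY,
        SubpopLabel.OTHER_PH,
        SubpopLabel.PEDIATRIC,
        SubpopLabel.NON_ENGLAND,
        SubpopLabel.HIGH_UTILIZER,
    ]
    subpops = [phase1_case_spec(n_cases)] + [
        violator_spec(lbl, n_per_violator) for lbl in violators
    ]
    return GeneratorConfig(seed=seed, subpopulations=subpops)
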