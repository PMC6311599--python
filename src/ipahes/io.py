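"""Readers and writers for the package's tabular dialects.

All tables are plain CSV with documented headers and ISO-8601 dates:

* episodes: ``patient_id, setting, event_date, primary_diagnosis,
  secondary_diagnoses, procedures, treatment_specialty, provider`` —
  multi-valued code fields are semicolon-joined.
* demographics: ``patient_id, gender, birth_year, birth_month, gp_postcode,
  residence_region, research_opt_out``.
* registry: ``registry_source, nhs_identifier, gender, birth_year,
  birth_month, gp_postcode, final_diagnosis, first_visit_date``.

Code-list files are YAML mappings (``name``, ``system``, ``match_mode``,
``entries``) or CSV with one entry per row.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .codes import ClinicalCode, CodeList, CodeSystem, MatchMode, normalize_code
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

EPISODE_COLUMNS = [
    "patient_id",
    "setting",
    "event_date",
    "primary_diagnosis",
    "secondary_diagnoses",
    "procedures",
    "treatment_specialty",
    "provider",
]
DEMOGRAPHICS_COLUMNS = [
    "patient_id",
    "gender",
    "birth_year",
    "birth_month",
    "gp_postcode",
    "residence_region",
    "research_opt_out",
]
REGISTRY_COLUMNS = [
    "registry_source",
    "nhs_identifier",
    "gender",
    "birth_year",
    "birth_month",
    "gp_postcode",
    "final_diagnosis",
    "first_visit_date",
]


class TableFormatError(ValueError):
    """Raised for malformed input tables (missing columns, bad dates...)."""


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _parse_date(value: str, path: str | Path, row: int, column: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value.strip())
    except ValueError as exc:
        raise TableFormatError(
            f"{path}: row {row}: unparseable {column} {value!r}: {exc}"
        ) from None


def _split_codes(cell: str, system: CodeSystem) -> tuple[ClinicalCode, ...]:
    cell = (cell or "").strip()
    if not cell:
        return ()
    return tuple(normalize_code(part, system) for part in cell.split(";") if part.strip())


def read_episode_events(path: str | Path) -> list[EpisodeEvent]:
    df = _read_csv(path, EPISODE_COLUMNS)
    events: list[EpisodeEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        primary = (row.primary_diagnosis or "").strip()
        events.append(
            EpisodeEvent(
                patient_id=row.patient_id,
                setting=Setting(row.setting),
                event_date=_parse_date(row.event_date, path, i, "event_date"),
                primary_diagnosis=(
                    normalize_code(primary, CodeSystem.ICD10) if primary else None
                ),
                secondary_diagnoses=_split_codes(row.secondary_diagnoses, CodeSystem.ICD10),
                procedures=_split_codes(row.procedures, CodeSystem.OPCS),
                treatment_specialty=row.treatment_specialty,
                provider=row.provider,
            )
        )
    return events


def read_demographics(path: str | Path) -> list[PatientDemographics]:
    df = _read_csv(path, DEMOGRAPHICS_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        out.append(
            PatientDemographics(
                patient_id=row.patient_id,
                gender=Gender(row.gender),
                birth_year=int(row.birth_year),
                birth_month=int(row.birth_month),
                gp_postcode=row.gp_postcode,
                residence_region=row.residence_region,
                research_opt_out=row.research_opt_out.strip().lower()
                in {"1", "true", "yes"},
            )
        )
    return out


def assemble_records(
    events: Iterable[EpisodeEvent], demographics: Iterable[PatientDemographics]
) -> list[PatientRecord]:
    """Join events onto demographics by patient_id (patients without events
    get an empty history; events without demographics are a hard error)."""
    by_patient: dict[str, list[EpisodeEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    demo_list = list(demographics)
    known = {d.patient_id for d in demo_list}
    orphans = sorted(set(by_patient) - known)
    if orphans:
        raise TableFormatError(f"events for patients with no demographics: {orphans[:5]}")
    return [
        PatientRecord(demographics=d, events=tuple(by_patient.get(d.patient_id, ())))
        for d in demo_list
    ]


def read_events(episodes_path: str | Path, demographics_path: str | Path) -> list[PatientRecord]:
    return assemble_records(
        read_episode_events(episodes_path), read_demographics(demographics_path)
    )


def _join_codes(codes: Sequence[ClinicalCode]) -> str:
    return ";".join(c.normalized for c in codes)


def events_to_frame(events: Iterable[EpisodeEvent]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": ev.patient_id,
            "setting": ev.setting.value,
            "event_date": ev.event_date.isoformat(),
            "primary_diagnosis": ev.primary_diagnosis.normalized if ev.primary_diagnosis else "",
            "secondary_diagnoses": _join_codes(ev.secondary_diagnoses),
            "procedures": _join_codes(ev.procedures),
            "treatment_specialty": ev.treatment_specialty,
            "provider": ev.provider,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def write_events(records: Iterable[PatientRecord], episodes_path, demographics_path) -> None:
    records = list(records)
    all_events = [ev for r in records for ev in r.events]
    events_to_frame(all_events).to_csv(episodes_path, index=False)
    demo_rows = [
        {
            "patient_id": r.demographics.patient_id,
            "gender": r.demographics.gender.value,
            "birth_year": r.demographics.birth_year,
            "birth_month": r.demographics.birth_month,
            "gp_postcode": r.demographics.gp_postcode,
            "residence_region": r.demographics.residence_region,
            "research_opt_out": str(r.demographics.research_opt_out).lower(),
        }
        for r in records
    ]
    pd.DataFrame(demo_rows, columns=DEMOGRAPHICS_COLUMNS).to_csv(demographics_path, index=False)


def read_registry(path: str | Path) -> list[RegistryRecord]:
    df = _read_csv(path, REGISTRY_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        nhs = (row.nhs_identifier or "").strip()
        out.append(
            RegistryRecord(
                registry_source=RegistrySource(row.registry_source),
                nhs_identifier=nhs or None,
                gender=Gender(row.gender),
                birth_year=int(row.birth_year),
                birth_month=int(row.birth_month),
                gp_postcode=row.gp_postcode,
                final_diagnosis=FinalDiagnosis(row.final_diagnosis),
                first_visit_date=_parse_date(row.first_visit_date, path, i, "first_visit_date"),
            )
        )
    return out


def write_registry(rows: Iterable[RegistryRecord], path: str | Path) -> None:
    out = [
        {
            "registry_source": r.registry_source.value,
            "nhs_identifier": r.nhs_identifier or "",
            "gender": r.gender.value,
            "birth_year": r.birth_year,
            "birth_month": r.birth_month,
            "gp_postcode": r.gp_postcode,
            "final_diagnosis": r.final_diagnosis.value,
            "first_visit_date": r.first_visit_date.isoformat(),
        }
        for r in rows
    ]
    pd.DataFrame(out, columns=REGISTRY_COLUMNS).to_csv(path, index=False)


def load_code_list(path: str | Path) -> CodeList:
    """Load a code list from YAML (mapping) or CSV (one entry per row).

    Entries may be dotted or undotted; they are normalized on load.
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise TableFormatError(f"{path}: expected a YAML mapping")
        try:
            return CodeList.from_raw(
                name=data["name"],
                system=data["system"],
                entries=data["entries"],
                match_mode=data.get("match_mode", "EXACT"),
            )
        except KeyError as exc:
            raise TableFormatError(f"{path}: missing key {exc}") from None
    df = _read_csv(path, ["name", "system", "match_mode", "entry"])
    if df.empty:
        raise TableFormatError(f"{path}: code-list CSV has no rows")
    return CodeList.from_raw(
        name=df["name"].iloc[0],
        system=df["system"].iloc[0],
        entries=df["entry"].tolist(),
        match_mode=df["match_mode"].iloc[0],
    )


def write_attrition(rows: Sequence[tuple[str, int]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["rule", "n_remaining"]).to_csv(path, index=False)
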