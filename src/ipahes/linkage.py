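"""Registry merge and deterministic episode-data linkage.

Three clinical data sources (a diagnostic registry, an operational clinical
database and a biobank) are merged into one row per patient identifier, then
linked to the episode demographics table by exact identifier match.  Linkage
is deterministic: demographics (gender, month/year of birth, GP postcode)
are used only as a consistency check, never for probabilistic matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional, Sequence

from .records import (
    FinalDiagnosis,
    PatientDemographics,
    RegistryRecord,
    RegistrySource,
)

#: Precedence for the confirmed final diagnosis when sources conflict: the
#: diagnostic registry outranks the clinical database, which outranks the
#: biobank.  An UNASSIGNED diagnosis never overrides an assigned one.
SOURCE_PRECEDENCE = {
    RegistrySource.ASPIRE: 0,
    RegistrySource.INFOFLEX: 1,
    RegistrySource.ARQ: 2,
}


class LinkStatus(str, Enum):
    LINKED = "LINKED"
    NO_IDENTIFIER = "NO_IDENTIFIER"
    IDENTIFIER_NOT_FOUND = "IDENTIFIER_NOT_FOUND"
    DEMOGRAPHIC_MISMATCH = "DEMOGRAPHIC_MISMATCH"


class LinkPolicy(str, Enum):
    #: any demographic mismatch demotes the pair to DEMOGRAPHIC_MISMATCH
    STRICT = "STRICT"
    #: a postcode-only mismatch is tolerated (postcodes churn with GP moves)
    LENIENT = "LENIENT"


@dataclass(frozen=True)
class LinkageResult:
    registry_record: RegistryRecord
    linked_patient_id: Optional[str]
    status: LinkStatus
    mismatched_fields: frozenset[str] = frozenset()


def merge_registries(rows: Iterable[RegistryRecord]) -> list[RegistryRecord]:
    """Collapse to one record per identifier.

    Records without an identifier pass through unmerged.  For merged groups
    the final diagnosis comes from the highest-precedence source that
    assigned one; the first-visit date is the minimum across sources.
    Conflicting gender or birth fields within a group flag the merged record
    (``demographic_conflict=True``) rather than silently merging.
    """
    groups: dict[str, list[RegistryRecord]] = {}
    passthrough: list[RegistryRecord] = []
    order: list[str] = []
    for r in rows:
        if r.nhs_identifier is None:
            passthrough.append(r)
        else:
            if r.nhs_identifier not in groups:
                order.append(r.nhs_identifier)
            groups.setdefault(r.nhs_identifier, []).append(r)
    merged: list[RegistryRecord] = []
    for ident in order:
        group = sorted(groups[ident], key=lambda r: SOURCE_PRECEDENCE[r.registry_source])
        assigned = [r for r in group if r.final_diagnosis is not FinalDiagnosis.UNASSIGNED]
        diagnosis = assigned[0].final_diagnosis if assigned else FinalDiagnosis.UNASSIGNED
        base = group[0]
        conflict = any(
            (r.gender, r.birth_year, r.birth_month)
            != (base.gender, base.birth_year, base.birth_month)
            for r in group[1:]
        )
        merged.append(
            RegistryRecord(
                registry_source=base.registry_source,
                nhs_identifier=ident,
                gender=base.gender,
                birth_year=base.birth_year,
                birth_month=base.birth_month,
                gp_postcode=base.gp_postcode,
                final_diagnosis=diagnosis,
                first_visit_date=min(r.first_visit_date for r in group),
                demographic_conflict=conflict,
            )
        )
    return merged + passthrough


def diagnosis_partition(rows: Sequence[RegistryRecord]) -> dict[str, int]:
    """Counts per final-diagnosis category; values always sum to len(rows)."""
    counts = {d.value: 0 for d in FinalDiagnosis}
    for r in rows:
        counts[r.final_diagnosis.value] += 1
    return counts


def _normalize_postcode(pc: str) -> str:
    return "".join((pc or "").split()).upper()


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.65 -> 2.7), matching how percentages are
    conventionally reported; Python's round() is half-even."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def link(
    registry: Sequence[RegistryRecord],
    demographics: Iterable[PatientDemographics],
    policy: LinkPolicy = LinkPolicy.STRICT,
) -> tuple[list[LinkageResult], float]:
    """Exact-identifier join with demographic consistency checks.

    Returns per-record results plus the linkage rate: 100 x LINKED / total
    registry records, half-up rounded to 1 decimal place.
    """
    demo_by_id: dict[str, PatientDemographics] = {}
    for d in demographics:
        if d.patient_id in demo_by_id:
            raise ValueError(f"duplicate patient_id in demographics: {d.patient_id!r}")
        demo_by_id[d.patient_id] = d

    results: list[LinkageResult] = []
    for r in registry:
        if r.nhs_identifier is None:
            results.append(LinkageResult(r, None, LinkStatus.NO_IDENTIFIER))
            continue
        d = demo_by_id.get(r.nhs_identifier)
        if d is None:
            results.append(LinkageResult(r, None, LinkStatus.IDENTIFIER_NOT_FOUND))
            continue
        mismatched = set()
        if r.gender is not d.gender:
            mismatched.add("gender")
        if (r.birth_year, r.birth_month) != (d.birth_year, d.birth_month):
            mismatched.add("birth_month_year")
        if _normalize_postcode(r.gp_postcode) != _normalize_postcode(d.gp_postcode):
            mismatched.add("gp_postcode")
        hard = mismatched if policy is LinkPolicy.STRICT else mismatched - {"gp_postcode"}
        if hard:
            results.append(
                LinkageResult(r, None, LinkStatus.DEMOGRAPHIC_MISMATCH, frozenset(mismatched))
            )
        else:
            results.append(
                LinkageResult(r, d.patient_id, LinkStatus.LINKED, frozenset(mismatched))
            )
    n = len(results)
    n_linked = sum(1 for x in results if x.status is LinkStatus.LINKED)
    rate = round_half_up(100.0 * n_linked / n, 1) if n else 0.0
    return results, rate
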