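"""Clinical code normalization and code-list matching.

Hospital episode extracts store ICD-10 and OPCS codes undotted ("I270"),
while code lists in the literature are printed dotted ("I27.0").  Everything
in this package compares codes on a single normalized form: upper-case,
dot-free, whitespace-stripped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable


class CodeSystem(str, Enum):
    ICD10 = "ICD10"
    OPCS = "OPCS"


class MatchMode(str, Enum):
    EXACT = "EXACT"
    PREFIX = "PREFIX"


_ICD10_RE = re.compile(r"^[A-Z]\d{2}[A-Z0-9]{0,2}$")


class CodeValidationError(ValueError):
    """Raised when a raw code or code list cannot be interpreted."""


def _normalize(raw: str) -> str:
    return raw.strip().replace(".", "").replace(" ", "").upper()


@dataclass(frozen=True)
class ClinicalCode:
    """A single diagnosis or procedure code.

    ``raw`` preserves the source spelling; ``normalized`` is the canonical
    comparison form (upper-case, no dots, no whitespace).
    """

    raw: str
    normalized: str
    system: CodeSystem

    def __post_init__(self) -> None:
        if "." in self.normalized or any(c.isspace() for c in self.normalized):
            raise CodeValidationError(
                f"normalized code {self.normalized!r} contains '.' or whitespace"
            )


def normalize_code(raw: str, system: CodeSystem | str) -> ClinicalCode:
    """Build a :class:`ClinicalCode` from a raw source string.

    Raises :class:`CodeValidationError` on empty input or, for ICD-10, on
    strings that cannot be an ICD-10 code shape (letter + 2 digits +
    up to 2 alphanumerics).
    """
    system = CodeSystem(system)
    if raw is None:
        raise CodeValidationError("code is None")
    normalized = _normalize(raw)
    if not normalized:
        raise CodeValidationError(f"empty clinical code from input {raw!r}")
    if system is CodeSystem.ICD10 and not _ICD10_RE.match(normalized):
        raise CodeValidationError(
            f"{raw!r} (normalized {normalized!r}) is not a valid ICD-10 code shape"
        )
    return ClinicalCode(raw=raw, normalized=normalized, system=system)


@dataclass(frozen=True)
class CodeList:
    """A named set of normalized code entries with exact or prefix matching.

    In PREFIX mode a code matches when any entry is a prefix of the
    normalized code, which is the usual way chapter/category-level entries
    (e.g. "I27") are applied to fully specified codes ("I279").
    """

    name: str
    system: CodeSystem
    entries: frozenset[str]
    match_mode: MatchMode = MatchMode.EXACT

    def __post_init__(self) -> None:
        if not self.entries:
            raise CodeValidationError(f"code list {self.name!r} has no entries")
        for e in self.entries:
            if e != _normalize(e) or not e:
                raise CodeValidationError(
                    f"code list {self.name!r} entry {e!r} is not normalized"
                )

    @classmethod
    def from_raw(
        cls,
        name: str,
        system: CodeSystem | str,
        entries: Iterable[str],
        match_mode: MatchMode | str = MatchMode.EXACT,
    ) -> "CodeList":
        """Normalize arbitrary (possibly dotted) entries on construction."""
        system = CodeSystem(system)
        normalized = frozenset(_normalize(e) for e in entries if _normalize(e))
        return cls(
            name=name,
            system=system,
            entries=normalized,
            match_mode=MatchMode(match_mode),
        )

    def __contains__(self, code: ClinicalCode) -> bool:
        return code_matches(code, self)


def code_matches(code: ClinicalCode, code_list: CodeList) -> bool:
    """True when ``code`` is matched by ``code_list``.

    A system mismatch is a hard error, never a silent False: matching an
    OPCS procedure against an ICD-10 diagnosis list is a pipeline bug.
    """
    if code.system is not code_list.system:
        raise CodeValidationError(
            f"system mismatch: code {code.normalized!r} is {code.system.value}, "
            f"list {code_list.name!r} is {code_list.system.value}"
        )
    if code_list.match_mode is MatchMode.EXACT:
        return code.normalized in code_list.entries
    return any(code.normalized.startswith(e) for e in code_list.entries)


def any_code_matches(codes: Iterable[ClinicalCode], code_list: CodeList) -> bool:
    return any(code_matches(c, code_list) for c in codes)
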