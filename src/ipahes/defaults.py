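"""Documented default configuration values.

The study design depends on several inputs that are site-specific and not
publicly enumerated: the right-heart-catheterization (RHC) OPCS procedure
codes, the provider codes of the six adult specialist PH centers and of the
pediatric specialist center, the non-iPAH exclusion diagnosis list, and the
first-symptom code list.  The defaults below are synthetic stand-ins with the
right structure (documented here and overridable everywhere they are used);
analyses of real extracts must supply the locally governed lists.
"""

from __future__ import annotations

from .codes import CodeList, CodeSystem, MatchMode
from .records import CenterRegistry, SpecialtyVocabulary

#: ICD-10 codes used to identify pulmonary hypertension:
#: I27.0 primary pulmonary hypertension, I27.2 other secondary pulmonary
#: hypertension, I27.9 pulmonary heart disease unspecified.
PH_CODES = CodeList.from_raw(
    "ph_icd10", CodeSystem.ICD10, ["I27.0", "I27.2", "I27.9"], MatchMode.EXACT
)

#: Synthetic stand-in for the non-iPAH exclusion list: category-level ICD-10
#: codes for conditions that explain PH as secondary (left heart disease,
#: chronic lung disease, thromboembolic disease, connective-tissue disease,
#: congenital heart disease).  PREFIX matching applies category entries to
#: fully specified codes.
NON_IPAH_CODES = CodeList.from_raw(
    "non_ipah_icd10",
    CodeSystem.ICD10,
    ["I26", "I50", "J44", "M32", "Q21"],
    MatchMode.PREFIX,
)

#: Synthetic stand-in OPCS codes for right heart catheterization.
RHC_CODES = CodeList.from_raw(
    "rhc_opcs", CodeSystem.OPCS, ["K652", "K633"], MatchMode.EXACT
)

#: Synthetic stand-in for the first-symptom code list: ICD-10 symptom codes
#: typical of presenting PH (breathlessness, chest pain, syncope, fatigue,
#: edema) plus an OPCS echocardiography stand-in.
SYMPTOM_CODES_ICD10 = CodeList.from_raw(
    "symptom_icd10",
    CodeSystem.ICD10,
    ["R06.0", "R06.2", "R07.4", "R55", "R53", "R60.0"],
    MatchMode.EXACT,
)
SYMPTOM_CODES_OPCS = CodeList.from_raw(
    "symptom_opcs", CodeSystem.OPCS, ["U202"], MatchMode.EXACT
)

#: Innocuous filler diagnosis codes for synthetic background events; disjoint
#: from the PH, non-iPAH and symptom lists above.
FILLER_ICD10 = ("Z038", "I10", "E119", "K219", "M545", "J069")

#: Synthetic provider codes: six adult specialist PH centers, one pediatric
#: specialist center, and a pool of general hospital trusts.
ADULT_SPECIALIST_PROVIDERS = frozenset(f"PHC0{i}" for i in range(1, 7))
PEDIATRIC_PROVIDERS = frozenset({"PED01"})
GENERAL_PROVIDERS = tuple(f"GEN{i:02d}" for i in range(1, 21))

CENTERS = CenterRegistry(
    adult_specialist_providers=ADULT_SPECIALIST_PROVIDERS,
    pediatric_providers=PEDIATRIC_PROVIDERS,
)

#: Raw treatment-function codes -> canonical specialty (English secondary
#: care treatment-function coding).
SPECIALTY_VOCABULARY = SpecialtyVocabulary(
    mapping={
        "320": "CARDIOLOGY",
        "340": "RESPIRATORY",
        "341": "RESPIRATORY",  # thoracic medicine variants
        "400": "NEUROLOGY",
        "300": "GENERAL_MEDICINE",
        "430": "GERIATRIC_MEDICINE",
        "180": "AE",
        "100": "GENERAL_SURGERY",
    }
)
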