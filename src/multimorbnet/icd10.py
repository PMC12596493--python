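"""ICD-10 category handling: 3-character truncation and chapter assignment.

Diseases are identified by their 3-character ICD-10 category code (a letter
followed by two digits, e.g. ``I10`` for essential hypertension).  Chapter
membership is derived from the standard letter/number ranges of ICD-10
(A00–B99 = Chapter 1 ... U00–U99 = Chapter 22).  Analyses restrict to
Chapters 1–14, the somatic-disease chapters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "DiseaseCategory",
    "CodeError",
    "normalize_code",
    "chapter_of",
    "CHAPTER_LABELS",
    "IN_SCOPE_CHAPTERS",
]

_CODE3_RE = re.compile(r"^([A-Z])([0-9]{2})")

#: Chapters retained by the analysis (infectious through genitourinary).
IN_SCOPE_CHAPTERS = frozenset(range(1, 15))

CHAPTER_LABELS = {
    1: "Infectious and parasitic diseases",
    2: "Neoplasms",
    3: "Blood and immune disorders",
    4: "Endocrine, nutritional and metabolic diseases",
    5: "Mental and behavioural disorders",
    6: "Nervous system diseases",
    7: "Eye and adnexa diseases",
    8: "Ear and mastoid diseases",
    9: "Circulatory system diseases",
    10: "Respiratory system diseases",
    11: "Digestive system diseases",
    12: "Skin and subcutaneous tissue diseases",
    13: "Musculoskeletal and connective tissue diseases",
    14: "Genitourinary system diseases",
    15: "Pregnancy, childbirth and the puerperium",
    16: "Perinatal conditions",
    17: "Congenital malformations and chromosomal abnormalities",
    18: "Symptoms, signs and abnormal findings",
    19: "Injury, poisoning and external causes",
    20: "External causes of morbidity and mortality",
    21: "Factors influencing health status",
    22: "Codes for special purposes",
}

# (letter, two-digit-number) ranges -> chapter, in lookup order.  D and H
# split mid-letter; S/T and V..Y span several letters.
_RANGES = [
    ("A", 0, "B", 99, 1),
    ("C", 0, "D", 48, 2),
    ("D", 50, "D", 89, 3),
    ("E", 0, "E", 90, 4),
    ("F", 0, "F", 99, 5),
    ("G", 0, "G", 99, 6),
    ("H", 0, "H", 59, 7),
    ("H", 60, "H", 95, 8),
    ("I", 0, "I", 99, 9),
    ("J", 0, "J", 99, 10),
    ("K", 0, "K", 93, 11),
    ("L", 0, "L", 99, 12),
    ("M", 0, "M", 99, 13),
    ("N", 0, "N", 99, 14),
    ("O", 0, "O", 99, 15),
    ("P", 0, "P", 96, 16),
    ("Q", 0, "Q", 99, 17),
    ("R", 0, "R", 99, 18),
    ("S", 0, "T", 98, 19),
    ("V", 1, "Y", 98, 20),
    ("Z", 0, "Z", 99, 21),
    ("U", 0, "U", 99, 22),
]


class CodeError(ValueError):
    """Raised for strings that do not start with an ICD-10 category pattern."""


@dataclass(frozen=True, slots=True)
class DiseaseCategory:
    """A 3-character ICD-10 disease category with its chapter."""

    code3: str
    chapter: int

    @property
    def chapter_label(self) -> str:
        return CHAPTER_LABELS[self.chapter]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code3


def chapter_of(code3: str) -> int:
    """Chapter number (1–22) for a 3-character category code."""
    letter, num = code3[0], int(code3[1:3])
    for lo_l, lo_n, hi_l, hi_n, chap in _RANGES:
        if (lo_l, lo_n) <= (letter, num) <= (hi_l, hi_n):
            return chap
    raise CodeError(f"no ICD-10 chapter for code {code3!r}")


def normalize_code(raw: str) -> DiseaseCategory:
    """Truncate an ICD-10 code of any precision to its 3-character category.

    ``"E11.9"`` and ``"E119"`` both normalize to category ``E11``
    (Chapter 4).  Normalization is a projection: applying it to an already
    3-character code returns the same category.
    """
    m = _CODE3_RE.match(raw.strip().upper())
    if m is None:
        raise CodeError(f"not an ICD-10 category: {raw!r}")
    code3 = m.group(1) + m.group(2)
    return DiseaseCategory(code3=code3, chapter=chapter_of(code3))
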