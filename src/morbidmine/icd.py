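"""ICD-10-CM category normalization and chapter-level eligibility.

Diagnosis codes arrive as free-text strings in several dialects
(``"E11.65"``, ``"E1165"``, ``"e11"``).  For multimorbidity analysis every
sub-classification is rolled up to its 3-character *parental category*
(letter + two digits, e.g. ``E11`` for type 2 diabetes), and only
categories inside a configurable set of clinical chapters count as
chronic-capable conditions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Icd10Code",
    "ChapterFilter",
    "InvalidCodeError",
    "normalize_code",
    "try_normalize",
    "is_eligible",
    "default_filter",
    "DEFAULT_INCLUDED_RANGES",
    "DEFAULT_EXCLUDED_CATEGORIES",
]

_CATEGORY_RE = re.compile(r"^[A-Z][0-9][0-9]$")
_RANGE_RE = re.compile(r"^([A-Z])([0-9]{2})\s*-\s*([A-Z])([0-9]{2})$")

#: Clinical chapters eligible by default: blood/blood-forming organs,
#: endocrine/nutritional/metabolic, mental/behavioral, nervous system,
#: circulatory, respiratory, digestive, musculoskeletal, genitourinary.
DEFAULT_INCLUDED_RANGES: tuple[str, ...] = (
    "D50-D89",
    "E00-E89",
    "F01-F99",
    "G00-G99",
    "I00-I99",
    "J00-J99",
    "K00-K95",
    "M00-M99",
    "N00-N99",
)

#: E66 (obesity) is excluded by default: BMI already stratifies the
#: analysis, so obesity is not allowed to reappear as an outcome.
DEFAULT_EXCLUDED_CATEGORIES: tuple[str, ...] = ("E66",)


class InvalidCodeError(ValueError):
    """Raised when a raw string cannot be normalized to a 3-character category."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"not a recognizable ICD-10-CM code: {raw!r}")


@dataclass(frozen=True)
class Icd10Code:
    """A diagnosis code reduced to its 3-character parental category."""

    raw: str
    category: str

    @property
    def chapter_letter(self) -> str:
        return self.category[0]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.category


def normalize_code(raw: str) -> Icd10Code:
    """Normalize a raw ICD-10-CM string to its parental category.

    Whitespace is stripped, the dot and everything after it are dropped,
    letters are upper-cased and the result is truncated to 3 characters,
    which must match letter-digit-digit.

    Raises
    ------
    InvalidCodeError
        If the input is empty or the leading 3 characters do not form a
        valid category.
    """
    if raw is None:
        raise InvalidCodeError("")
    text = str(raw).strip().upper()
    text = text.split(".", 1)[0]
    text = re.sub(r"\s+", "", text)
    category = text[:3]
    if not _CATEGORY_RE.match(category):
        raise InvalidCodeError(str(raw))
    return Icd10Code(raw=str(raw), category=category)


def try_normalize(raw: str) -> Icd10Code | None:
    """Like :func:`normalize_code` but returns ``None`` on malformed input."""
    try:
        return normalize_code(raw)
    except InvalidCodeError:
        return None


def _parse_range(text: str) -> tuple[str, int, int]:
    m = _RANGE_RE.match(text.strip().upper())
    if not m:
        raise ValueError(f"bad category range {text!r}; expected e.g. 'E00-E89'")
    lo_letter, lo, hi_letter, hi = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    if lo_letter != hi_letter:
        raise ValueError(f"range {text!r} spans two chapter letters")
    if lo > hi:
        raise ValueError(f"range {text!r} has low > high")
    return lo_letter, lo, hi


@dataclass(frozen=True)
class ChapterFilter:
    """Inclusive category ranges plus an explicit category blocklist.

    ``included_ranges`` holds ``(letter, low, high)`` triples; a category
    ``L##`` is eligible iff ``low <= ## <= high`` for some range with
    letter ``L`` and the category is not in ``excluded_categories``.
    """

    included_ranges: tuple[tuple[str, int, int], ...]
    excluded_categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        by_letter: dict[str, list[tuple[int, int]]] = {}
        for letter, lo, hi in self.included_ranges:
            if lo > hi:
                raise ValueError(f"range {letter}{lo:02d}-{letter}{hi:02d} has low > high")
            for olo, ohi in by_letter.setdefault(letter, []):
                if lo <= ohi and olo <= hi:
                    raise ValueError(f"overlapping ranges within chapter {letter}")
            by_letter[letter].append((lo, hi))

    @classmethod
    def from_strings(
        cls, ranges: Iterable[str], exclude: Iterable[str] = ()
    ) -> "ChapterFilter":
        parsed = tuple(_parse_range(r) for r in ranges)
        excl = frozenset(normalize_code(c).category for c in exclude)
        return cls(included_ranges=parsed, excluded_categories=excl)

    def to_strings(self) -> dict[str, list[str]]:
        """Serializable form used in run configs."""
        return {
            "include": [f"{L}{lo:02d}-{L}{hi:02d}" for L, lo, hi in self.included_ranges],
            "exclude": sorted(self.excluded_categories),
        }

    def __contains__(self, category: str) -> bool:
        if category in self.excluded_categories:
            return False
        letter, number = category[0], int(category[1:3])
        return any(
            letter == L and lo <= number <= hi for L, lo, hi in self.included_ranges
        )


def default_filter() -> ChapterFilter:
    """The default chronic-condition chapter filter (obesity excluded)."""
    return ChapterFilter.from_strings(
        DEFAULT_INCLUDED_RANGES, exclude=DEFAULT_EXCLUDED_CATEGORIES
    )


def is_eligible(code: Icd10Code | str, chapter_filter: ChapterFilter) -> bool:
    """True iff the code's parental category passes the chapter filter."""
    category = code.category if isinstance(code, Icd10Code) else normalize_code(code).category
    return category in chapter_filter


def eligible_categories(
    codes: Sequence[str], chapter_filter: ChapterFilter
) -> tuple[set[str], list[str]]:
    """Normalize a batch of raw codes and keep eligible categories.

    Returns ``(categories, malformed)`` where ``malformed`` lists the raw
    strings that failed normalization (callers log them; nothing is
    silently dropped).
    """
    kept: set[str] = set()
    malformed: list[str] = []
    for raw in codes:
        code = try_normalize(raw)
        if code is None:
            malformed.append(str(raw))
        elif code.category in chapter_filter:
            kept.add(code.category)
    return kept, malformed
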