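"""ICD-10 code normalization and multi-level collapsing.

ICD-10(-GM) codes are prefix-structured strings: a letter, two digits,
and an optional extension after a dot (``A15.1``). A trailing ``.-``
marks a wildcard category covering every extension (``B15.-`` means all
of ``B15.*``). Diagnosis matching can be evaluated at four granularity
levels, from the full code down to a configured medical specialty.
No external code-system file is needed: only positional truncation and
prefix matching are used.
"""

from __future__ import annotations

import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ValidationError

__all__ = [
    "GranularityLevel",
    "DEFAULT_SPECIALTY_MAP",
    "normalize_code",
    "truncate_code",
    "codes_match",
    "match_codes",
    "validate_specialty_map",
    "read_specialty_map",
    "write_specialty_map",
]


class GranularityLevel(str, Enum):
    """Truncation depth at which two diagnosis codes count as a match."""

    FULL = "full"
    CATEGORY3 = "category3"
    CHAPTER = "chapter"
    SPECIALTY = "specialty"


#: Specialty assignment of the default diagnosis catalog. Prefixes are
#: matched longest-first, so ``E83.0`` wins over any shorter ``E`` rule.
DEFAULT_SPECIALTY_MAP: dict[str, str] = {
    "B15": "Gastroenterological",
    "B16": "Gastroenterological",
    "B17": "Gastroenterological",
    "B18": "Gastroenterological",
    "E83.0": "Gastroenterological",
    "E83.1": "Gastroenterological",
    "E88.0": "Gastroenterological",
    "C34": "Pneumological",
    "A15": "Pneumological",
    "D86": "Pneumological",
    "J11": "Pneumological",
    "E05": "Endocrinological",
    "E06.1": "Endocrinological",
}

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")


def normalize_code(code: str) -> str:
    """Normalize an ICD-10 code string.

    Uppercases, strips whitespace, and reduces a trailing wildcard
    (``B15.-`` or a bare trailing dot) to the three-character category
    prefix. Raises :class:`ValidationError` for strings that do not look
    like an ICD-10 code.
    """
    if not code or not code.strip():
        raise ValidationError("empty ICD-10 code")
    c = re.sub(r"\s+", "", code).upper()
    if c.endswith(".-"):
        c = c[:-2]
    elif c.endswith("-"):
        c = c[:-1]
    if c.endswith("."):
        c = c[:-1]
    if not _CODE_RE.match(c):
        raise ValidationError(f"not an ICD-10 code: {code!r}")
    return c


def truncate_code(
    code: str,
    level: GranularityLevel | str,
    specialty_map: Optional[Mapping[str, str]] = None,
) -> str:
    """Collapse a normalized code to the requested granularity level.

    ``full`` leaves the code unchanged, ``category3`` keeps the first
    three characters, ``chapter`` the initial letter, and ``specialty``
    looks up the longest matching prefix in *specialty_map*.
    """
    level = GranularityLevel(level)
    if level is GranularityLevel.FULL:
        return code
    if level is GranularityLevel.CATEGORY3:
        return code[:3]
    if level is GranularityLevel.CHAPTER:
        return code[0]
    # specialty
    if specialty_map is None:
        specialty_map = DEFAULT_SPECIALTY_MAP
    for prefix in sorted(specialty_map, key=len, reverse=True):
        if code == prefix or code.startswith(prefix):
            return specialty_map[prefix]
    raise ValidationError(f"unmapped code for specialty level: {code!r}")


def codes_match(
    a: str,
    b: str,
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
) -> bool:
    """Whether two normalized codes match at *level*.

    At the full level a three-character category code acts as a
    wildcard: ``B15`` matches ``B15.9`` (and vice versa), reflecting
    catalog entries given as ``B15.-``.
    """
    level = GranularityLevel(level)
    if level is GranularityLevel.FULL:
        if a == b:
            return True
        if len(a) == 3 and b.startswith(a):
            return True
        if len(b) == 3 and a.startswith(b):
            return True
        return False
    return truncate_code(a, level, specialty_map) == truncate_code(b, level, specialty_map)


def match_codes(
    a: Iterable[str],
    b: Iterable[str],
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
) -> bool:
    """Whether any code of set *a* matches any code of set *b* at *level*."""
    a = [normalize_code(c) for c in a]
    b = [normalize_code(c) for c in b]
    if not a or not b:
        raise ValidationError("match_codes requires non-empty code sets")
    return any(codes_match(x, y, level, specialty_map) for x in a for y in b)


def validate_specialty_map(specialty_map: Mapping[str, str]) -> None:
    """Reject maps whose prefixes overlap after normalization.

    Overlapping prefixes (one a prefix of another) would make the
    longest-match lookup order-dependent in spirit; they are refused so
    a code's specialty is unambiguous.
    """
    prefixes = sorted(specialty_map)
    for i, p in enumerate(prefixes):
        for q in prefixes[i + 1 :]:
            if q.startswith(p) or p.startswith(q):
                raise ValidationError(f"overlapping specialty prefixes: {p!r}, {q!r}")


def read_specialty_map(path: str | Path) -> dict[str, str]:
    """Read a (prefix, specialty) CSV into a validated specialty map."""
    df = pd.read_csv(path, dtype=str)
    if not {"prefix", "specialty"}.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns prefix,specialty")
    mapping = {str(r.prefix).strip().upper(): str(r.specialty).strip() for r in df.itertuples()}
    validate_specialty_map(mapping)
    return mapping


def write_specialty_map(specialty_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(specialty_map.items()), columns=["prefix", "specialty"]
    ).to_csv(path, index=False)
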