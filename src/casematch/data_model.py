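"""Domain types, concept tokenization, and case-base preparation.

A patient record is a multiset of *concept tokens* — coded clinical
facts written as ``VOCAB|ID`` with an optional reference-range relation
appended for laboratory results (``LOINC|1742-6|above``) — plus a set
of primary ICD-10-GM diagnosis codes that serve as the retrieval ground
truth. Record preparation removes the primary diagnoses themselves and
any explicitly listed "directly indicative" concepts from the concept
multiset, and drops records left with fewer than two concept mentions.

Case bases are read from / written to a small OMOP-subset CSV schema
(persons, diagnoses, concepts, exclusions); see :func:`read_case_base`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from . import granularity
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceRelation",
    "Gender",
    "ConceptToken",
    "PatientRecord",
    "CaseBase",
    "build_concept_token",
    "classify_reference_relation",
    "split_token",
    "base_token",
    "prepare_record",
    "prepare_case_base",
    "filter_min_concepts",
    "read_case_base",
    "write_case_base",
]

SEP = "|"


class ReferenceRelation(str, Enum):
    """Position of a laboratory result relative to its reference range."""

    BELOW = "below"
    WITHIN = "within"
    ABOVE = "above"


class Gender(str, Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ConceptToken:
    """A vocabulary-qualified concept mention.

    The canonical serialization is ``vocabulary|concept_id`` with
    ``|relation`` appended iff a reference-range relation is set.
    ``concept_name`` is carried for semantic normalization but does not
    participate in identity.
    """

    vocabulary: str
    concept_id: str
    reference_relation: Optional[ReferenceRelation] = None
    concept_name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for part, label in ((self.vocabulary, "vocabulary"), (self.concept_id, "concept_id")):
            if not part:
                raise ValidationError(f"{label} must be non-empty")
            if SEP in part:
                raise ValidationError(f"{label} must not contain {SEP!r}: {part!r}")

    @property
    def canonical(self) -> str:
        s = f"{self.vocabulary}{SEP}{self.concept_id}"
        if self.reference_relation is not None:
            s += SEP + self.reference_relation.value
        return s

    @property
    def base(self) -> str:
        """Canonical form without the relation suffix."""
        return f"{self.vocabulary}{SEP}{self.concept_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical

    @classmethod
    def parse(cls, token: str, concept_name: str = "") -> "ConceptToken":
        parts = token.split(SEP)
        if len(parts) == 2:
            return cls(parts[0], parts[1], None, concept_name)
        if len(parts) == 3:
            try:
                rel = ReferenceRelation(parts[2])
            except ValueError as exc:
                raise ValidationError(f"unknown reference relation in {token!r}") from exc
            return cls(parts[0], parts[1], rel, concept_name)
        raise ValidationError(f"malformed concept token: {token!r}")


def build_concept_token(
    vocabulary: str,
    concept_id: str,
    reference_relation: Optional[ReferenceRelation | str] = None,
    concept_name: str = "",
) -> ConceptToken:
    """Construct a validated :class:`ConceptToken`."""
    rel = ReferenceRelation(reference_relation) if reference_relation is not None else None
    return ConceptToken(vocabulary, concept_id, rel, concept_name)


def split_token(token: str) -> tuple[str, Optional[str]]:
    """Split a canonical token into (base, relation-or-None)."""
    parts = token.split(SEP)
    if len(parts) == 3:
        return SEP.join(parts[:2]), parts[2]
    if len(parts) == 2:
        return token, None
    raise ValidationError(f"malformed concept token: {token!r}")


def base_token(token: str) -> str:
    return split_token(token)[0]


def classify_reference_relation(
    value: Optional[float],
    range_low: Optional[float],
    range_high: Optional[float],
) -> Optional[ReferenceRelation]:
    """Classify a numeric result against its reference range.

    Returns ``None`` when the value or either bound is missing.
    Boundary values count as *within*: flagged laboratory results are
    those strictly outside the range.
    """
    if range_low is not None and range_high is not None and range_low > range_high:
        raise ValidationError(f"range_low {range_low} > range_high {range_high}")
    if value is None or range_low is None or range_high is None:
        return None
    if value < range_low:
        return ReferenceRelation.BELOW
    if value > range_high:
        return ReferenceRelation.ABOVE
    return ReferenceRelation.WITHIN


@dataclass
class PatientRecord:
    """One patient: a concept multiset plus primary-diagnosis codes.

    All concept mentions across visits are collapsed into the single
    record; no temporal ordering is retained.
    """

    person_id: str
    concepts: dict[str, int] = field(default_factory=dict)
    primary_diagnoses: frozenset[str] = field(default_factory=frozenset)
    gender: Optional[Gender] = None
    specialty: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.person_id:
            raise ValidationError("person_id must be non-empty")
        for token, count in self.concepts.items():
            split_token(token)  # validates shape
            if count < 1:
                raise ValidationError(f"count for {token!r} must be >= 1, got {count}")
        self.primary_diagnoses = frozenset(self.primary_diagnoses)

    @property
    def total_mentions(self) -> int:
        return sum(self.concepts.values())

    @property
    def distinct_concepts(self) -> int:
        return len(self.concepts)


@dataclass
class CaseBase:
    """A collection of patient records with shared concept metadata.

    ``concept_names`` maps base tokens (``VOCAB|ID``) to human-readable
    concept names; ``indicative_exclusions`` holds base tokens of
    directly indicative concepts to strip during preparation.
    """

    records: list[PatientRecord] = field(default_factory=list)
    concept_names: dict[str, str] = field(default_factory=dict)
    indicative_exclusions: frozenset[str] = field(default_factory=frozenset)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.person_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate person_ids: {dupes[:5]}")
        self.indicative_exclusions = frozenset(self.indicative_exclusions)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, person_id: str) -> PatientRecord:
        for r in self.records:
            if r.person_id == person_id:
                return r
        raise KeyError(person_id)

    def name_of(self, token: str) -> str:
        return self.concept_names.get(base_token(token), "")


def _diagnosis_matches_token(token: str, diagnoses: Iterable[str]) -> bool:
    """Whether an ICD-10 concept token codes one of the primary diagnoses.

    Matching uses full-level wildcard semantics: a ``B15.-`` diagnosis
    (normalized ``B15``) excludes ``ICD10GM|B15.0`` and so on.
    """
    base, _ = split_token(token)
    vocab, code = base.split(SEP)
    if not vocab.upper().replace("-", "").startswith("ICD10"):
        return False
    try:
        norm = granularity.normalize_code(code)
    except ValidationError:
        return False
    return any(granularity.codes_match(norm, d, granularity.GranularityLevel.FULL) for d in diagnoses)


def prepare_record(
    record: PatientRecord,
    indicative_exclusions: Iterable[str] = (),
) -> PatientRecord:
    """Remove diagnosis-revealing tokens from a record.

    Drops (a) any token in *indicative_exclusions* — matched on the base
    token, so a listed ``LOINC|91071-1`` also removes
    ``LOINC|91071-1|above`` — and (b) any ICD-10 token coding one of the
    record's own primary diagnoses at any wildcard granularity. Counts
    of surviving tokens are preserved. Idempotent.
    """
    exclusions = {base_token(t) for t in indicative_exclusions}
    diagnoses = [granularity.normalize_code(d) for d in record.primary_diagnoses]
    kept: dict[str, int] = {}
    for token, count in record.concepts.items():
        base, _ = split_token(token)
        if base in exclusions:
            continue
        if diagnoses and _diagnosis_matches_token(token, diagnoses):
            continue
        kept[token] = count
    return replace(record, concepts=kept)


def prepare_case_base(case_base: CaseBase) -> CaseBase:
    """Apply :func:`prepare_record` to every record, using the case
    base's indicative-exclusion list."""
    records = [prepare_record(r, case_base.indicative_exclusions) for r in case_base.records]
    return replace(case_base, records=records)


def filter_min_concepts(case_base: CaseBase, min_mentions: int = 2) -> tuple[CaseBase, int]:
    """Keep records with at least *min_mentions* total concept mentions.

    Returns the filtered case base and the number of records removed.
    """
    if min_mentions < 1:
        raise ValidationError(f"min_mentions must be >= 1, got {min_mentions}")
    kept = [r for r in case_base.records if r.total_mentions >= min_mentions]
    removed = len(case_base.records) - len(kept)
    return replace(case_base, records=kept), removed


# ---------------------------------------------------------------------------
# CSV ingestion / serialization (OMOP-subset schema)
# ---------------------------------------------------------------------------

def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, str) and not v.strip()) or pd.isna(v):
        return None
    return float(v)


def read_case_base(
    persons_csv: str | Path,
    diagnoses_csv: str | Path,
    concepts_csv: str | Path,
    exclusions_csv: Optional[str | Path] = None,
    provenance: str = "",
) -> CaseBase:
    """Read a case base from the four-table CSV schema.

    ``concepts.csv`` holds one row per concept mention; rows for the
    same person and canonical token accumulate into the mention count.
    Measurement rows with a numeric value and both range bounds get a
    reference relation via :func:`classify_reference_relation`, unless
    an explicit ``reference_relation`` column value overrides it.
    """
    persons = pd.read_csv(persons_csv, dtype=str).fillna("")
    diagnoses = pd.read_csv(diagnoses_csv, dtype=str).fillna("")
    concepts = pd.read_csv(
        concepts_csv,
        dtype={
            "person_id": str,
            "vocabulary": str,
            "concept_id": str,
            "concept_name": str,
            "reference_relation": str,
        },
    )

    def cell(row, key) -> str:
        v = row.get(key, "")
        return "" if v is None or pd.isna(v) else str(v).strip()

    genders: dict[str, Optional[Gender]] = {}
    for i, row in persons.iterrows():
        pid = str(row.get("person_id", "")).strip()
        if not pid:
            raise ValidationError(f"{persons_csv}: row {i + 2}: missing person_id")
        g = str(row.get("gender", "")).strip().lower()
        genders[pid] = Gender(g) if g else None

    dx: dict[str, set[str]] = {pid: set() for pid in genders}
    for i, row in diagnoses.iterrows():
        pid = str(row.get("person_id", "")).strip()
        code = str(row.get("icd10gm_code", "")).strip()
        if not pid or not code:
            raise ValidationError(f"{diagnoses_csv}: row {i + 2}: missing person_id or code")
        granularity.normalize_code(code)  # validate early, keep verbatim
        dx.setdefault(pid, set()).add(code)

    counts: dict[str, dict[str, int]] = {pid: {} for pid in genders}
    names: dict[str, str] = {}
    for i, row in concepts.iterrows():
        pid = cell(row, "person_id")
        vocab = cell(row, "vocabulary")
        cid = cell(row, "concept_id")
        if not pid or not vocab or not cid:
            raise ValidationError(f"{concepts_csv}: row {i + 2}: missing person_id/vocabulary/concept_id")
        name = cell(row, "concept_name")
        rel_raw = cell(row, "reference_relation").lower()
        try:
            if rel_raw:
                rel: Optional[ReferenceRelation] = ReferenceRelation(rel_raw)
            else:
                rel = classify_reference_relation(
                    _opt_float(row.get("value_number")),
                    _opt_float(row.get("range_low")),
                    _opt_float(row.get("range_high")),
                )
            token = build_concept_token(vocab, cid, rel, name)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{concepts_csv}: row {i + 2}: {exc}") from exc
        per = counts.setdefault(pid, {})
        per[token.canonical] = per.get(token.canonical, 0) + 1
        if name:
            names[token.base] = name

    exclusions: set[str] = set()
    if exclusions_csv is not None:
        excl = pd.read_csv(exclusions_csv, dtype=str).fillna("")
        for i, row in excl.iterrows():
            vocab = str(row.get("vocabulary", "")).strip()
            cid = str(row.get("concept_id", "")).strip()
            if not vocab or not cid:
                raise ValidationError(f"{exclusions_csv}: row {i + 2}: missing vocabulary/concept_id")
            exclusions.add(build_concept_token(vocab, cid).canonical)

    all_pids = sorted(set(genders) | set(dx) | set(counts))
    records = [
        PatientRecord(
            person_id=pid,
            concepts=counts.get(pid, {}),
            primary_diagnoses=frozenset(dx.get(pid, set())),
            gender=genders.get(pid),
        )
        for pid in all_pids
    ]
    return CaseBase(
        records=records,
        concept_names=names,
        indicative_exclusions=frozenset(exclusions),
        provenance=provenance,
    )


def write_case_base(case_base: CaseBase, out_dir: str | Path) -> dict[str, Path]:
    """Write a case base back to the four-table CSV schema.

    Mention counts expand to repeated rows so that
    ``read_case_base(write_case_base(cb))`` round-trips token multisets
    and diagnosis sets exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in ("persons", "diagnoses", "concepts", "exclusions")}

    pd.DataFrame(
        [(r.person_id, r.gender.value if r.gender else "") for r in case_base.records],
        columns=["person_id", "gender"],
    ).to_csv(paths["persons"], index=False)

    dx_rows = [
        (r.person_id, code)
        for r in case_base.records
        for code in sorted(r.primary_diagnoses)
    ]
    pd.DataFrame(dx_rows, columns=["person_id", "icd10gm_code"]).to_csv(paths["diagnoses"], index=False)

    c_rows = []
    for r in case_base.records:
        for token in sorted(r.concepts):
            base, rel = split_token(token)
            vocab, cid = base.split(SEP)
            name = case_base.concept_names.get(base, "")
            for _ in range(r.concepts[token]):
                c_rows.append((r.person_id, vocab, cid, name, "", "", "", rel or ""))
    pd.DataFrame(
        c_rows,
        columns=[
            "person_id", "vocabulary", "concept_id", "concept_name",
            "value_number", "range_low", "range_high", "reference_relation",
        ],
    ).to_csv(paths["concepts"], index=False)

    e_rows = [tuple(t.split(SEP)[:2]) for t in sorted(case_base.indicative_exclusions)]
    pd.DataFrame(e_rows, columns=["vocabulary", "concept_id"]).to_csv(paths["exclusions"], index=False)
    return paths
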