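"""Seeded generator of synthetic case bases with planted diagnostic signal.

Real multi-specialty hospital cohorts cannot be redistributed, so every
pipeline stage is exercised on synthetic case bases that emulate the
structure of such a cohort:

* a 13-diagnosis catalog spanning gastroenterology, pneumology and
  endocrinology, with bronchial carcinoma (C34.-) at 48.83% of
  diagnosis draws and a 77/19/3/1% distribution of records carrying
  1/2/3/4 primary diagnoses;
* a heavy-tailed per-record concept-count distribution (log-normal,
  capped at 127 total and 109 distinct mentions) whose parameters are
  set so that about 17.7% of raw records carry fewer than two concepts
  after preparation and the mean matches the corpus-wide 22.4 mentions
  per record;
* a vocabulary mix proportional to the corpus totals (LOINC and SNOMED
  dominate), with 72% of laboratory mentions carrying a
  reference-range relation.

On top of that structure the generator plants a *diagnostic signal*:
each catalog diagnosis owns a signature set of concept tokens, drawn
disjointly from the background pool, and a record carrying the
diagnosis includes each signature token with probability ``s``
(``signal_strength``). At ``s = 1`` the first signature token is
always present, so any two records sharing a diagnosis share at least
one rare, high-idf concept — nearest-neighbor recovery is guaranteed by
construction. At ``s = 0`` concepts are independent of the diagnoses
and retrieval precision falls to the random-match base rate. Ground
truth (planted diagnoses, signatures, and the synonym partition used
for mock embeddings) is returned alongside the case base.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .data_model import (
    SEP,
    CaseBase,
    Gender,
    PatientRecord,
    ReferenceRelation,
    build_concept_token,
)
from .errors import ValidationError
from .semantic_map import EmbeddingSet

__all__ = [
    "DiagnosisSpec",
    "DEFAULT_CATALOG",
    "VOCABULARY_TOTALS",
    "VOCABULARY_DISTINCT",
    "GeneratorConfig",
    "GroundTruth",
    "generate_case_base",
    "generate_mock_embeddings",
    "MockEmbeddingBackend",
    "expanded_catalog",
    "case_base_from_diagnosis_counts",
]


@dataclass(frozen=True)
class DiagnosisSpec:
    """One catalog entry: ICD-10-GM code (possibly a ``.-`` wildcard
    category), sampling weight, and medical specialty."""

    code: str
    weight: float
    specialty: str


#: The default catalog: 13 diagnoses from 3 specialties with their
#: dataset frequencies (summing to 5292 diagnosis draws).
DEFAULT_CATALOG: tuple[DiagnosisSpec, ...] = (
    DiagnosisSpec("B15.-", 28, "Gastroenterological"),
    DiagnosisSpec("B16.-", 39, "Gastroenterological"),
    DiagnosisSpec("B17.-", 76, "Gastroenterological"),
    DiagnosisSpec("B18.-", 130, "Gastroenterological"),
    DiagnosisSpec("E83.0", 7, "Gastroenterological"),
    DiagnosisSpec("E83.1", 24, "Gastroenterological"),
    DiagnosisSpec("E88.0", 4, "Gastroenterological"),
    DiagnosisSpec("C34.-", 2584, "Pneumological"),
    DiagnosisSpec("A15.-", 221, "Pneumological"),
    DiagnosisSpec("D86.-", 345, "Pneumological"),
    DiagnosisSpec("J11.-", 74, "Pneumological"),
    DiagnosisSpec("E05.-", 1749, "Endocrinological"),
    DiagnosisSpec("E06.1", 11, "Endocrinological"),
)

#: Corpus-wide mention totals per vocabulary (mix weights).
VOCABULARY_TOTALS: dict[str, int] = {
    "CancerModifier": 1364,
    "HPO": 12190,
    "ICD10CM": 223,
    "ICD10GM": 3823,
    "LOINC": 48399,
    "OMOPExtension": 1943,
    "SNOMEDCT": 28369,
}

#: Distinct-concept counts per vocabulary (pool-size proportions).
VOCABULARY_DISTINCT: dict[str, int] = {
    "CancerModifier": 15,
    "HPO": 66,
    "ICD10CM": 48,
    "ICD10GM": 324,
    "LOINC": 40,
    "OMOPExtension": 4,
    "SNOMEDCT": 1557,
}

_BACKGROUND_ICD_CHAPTERS = "KMNRZ"  # far from the catalog's chapters


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Defaults reproduce the emulated cohort structure: 4295 records, the
    13-diagnosis catalog, log-normal concept counts with mean-log 1.868
    and sd-log 1.576 (about 17.7% of raw records below two mentions,
    mean about 22 mentions), caps of 127 total / 109 distinct mentions,
    the 77/19/3/1% multi-diagnosis split, and 72% laboratory
    reference-range coverage. ``signal_strength`` (default 0.8, a
    strong but imperfect diagnostic signal) and the signature geometry
    are generator-specific and carry no real-data counterpart.
    """

    n_records: int = 4295
    catalog: tuple[DiagnosisSpec, ...] = DEFAULT_CATALOG
    multi_dx_probs: tuple[float, ...] = (0.77, 0.19, 0.03, 0.01)
    concept_mean_log: float = 1.868
    concept_sd_log: float = 1.576
    max_total: int = 127
    max_distinct: int = 109
    vocabulary_mix: dict[str, int] = field(default_factory=lambda: dict(VOCABULARY_TOTALS))
    pool_size: int = 2054
    zipf_exponent: float = 0.7
    lab_relation_coverage: float = 0.72
    signature_size: int = 5
    signature_fraction: float = 0.6
    signal_strength: float = 0.8
    disjoint_signatures: bool = True
    expand_wildcards: bool = True
    wildcard_extensions: tuple[str, ...] = ("0", "1", "8", "9")
    include_diagnosis_tokens: bool = True
    indicative_rate: float = 0.05
    n_synonym_groups: int = 10
    synonym_group_size: int = 3

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")
        if not self.catalog:
            raise ValidationError("catalog must be non-empty")
        probs = np.asarray(self.multi_dx_probs, dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValidationError("multi_dx_probs must be non-negative, not all zero")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValidationError("signal_strength must be in [0, 1]")
        if not (0.0 <= self.lab_relation_coverage <= 1.0):
            raise ValidationError("lab_relation_coverage must be in [0, 1]")
        if self.max_total < 2 or self.max_distinct < 2:
            raise ValidationError("mention caps must be >= 2")
        if self.signature_size < 1:
            raise ValidationError("signature_size must be positive")
        if not (0.0 < self.signature_fraction < 1.0):
            raise ValidationError("signature_fraction must be in (0, 1)")
        if self.pool_size < len(self.vocabulary_mix):
            raise ValidationError("pool_size must cover every vocabulary")
        if self.signature_size * len(self.catalog) > 10 * self.pool_size:
            raise ValidationError("signature demand exceeds a plausible concept pool")
        if len(self.multi_dx_probs) > len(self.catalog):
            raise ValidationError("more simultaneous diagnoses than catalog entries")
        if self.n_synonym_groups * self.synonym_group_size > self.pool_size:
            raise ValidationError("synonym groups exceed the background pool")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["catalog"] = [asdict(spec) for spec in self.catalog]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["catalog"] = tuple(DiagnosisSpec(**spec) for spec in data.get("catalog", []))
        for key in ("multi_dx_probs", "wildcard_extensions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery testing."""

    diagnoses: dict[str, list[str]]
    signatures: dict[str, list[str]]
    synonym_partition: list[list[str]]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class _PoolConcept:
    token: str  # base token VOCAB|ID
    name: str
    weight: float
    vocabulary: str


def _build_pool(config: GeneratorConfig, rng: np.random.Generator) -> list[_PoolConcept]:
    """Background concept pool: sizes proportional to the per-vocabulary
    distinct counts, mention weights proportional to the vocabulary mix
    with a Zipf profile inside each vocabulary."""
    distinct_total = sum(VOCABULARY_DISTINCT[v] for v in config.vocabulary_mix)
    sizes = {
        v: max(1, round(config.pool_size * VOCABULARY_DISTINCT[v] / distinct_total))
        for v in config.vocabulary_mix
    }
    pool: list[_PoolConcept] = []
    for vocab in sorted(config.vocabulary_mix):
        n_v = sizes[vocab]
        zipf = np.array([1.0 / (r + 1) ** config.zipf_exponent for r in range(n_v)])
        zipf /= zipf.sum()
        for i in range(n_v):
            if vocab == "SNOMEDCT":
                cid = str(100000 + i)
            elif vocab == "LOINC":
                cid = f"{1000 + i}-{i % 10}"
            elif vocab == "HPO":
                cid = f"HP:{7000000 + i}"
            elif vocab in ("ICD10GM", "ICD10CM"):
                letter = _BACKGROUND_ICD_CHAPTERS[i % len(_BACKGROUND_ICD_CHAPTERS)]
                cid = f"{letter}{10 + i % 80:02d}.{i % 10}"
            else:
                cid = f"{vocab[:2].upper()}{i:04d}"
            pool.append(
                _PoolConcept(
                    token=f"{vocab}{SEP}{cid}",
                    name=f"{vocab.lower()} finding {i}",
                    weight=config.vocabulary_mix[vocab] * zipf[i],
                    vocabulary=vocab,
                )
            )
    return pool


def _plant_synonyms(
    pool: list[_PoolConcept], config: GeneratorConfig, rng: np.random.Generator
) -> list[list[str]]:
    """Rename designated background concepts into synonym groups.

    Members of a group get names like ``term 3 variant 1``; the mock
    embedding backend later gives these near-identical vectors.
    """
    n_members = config.n_synonym_groups * config.synonym_group_size
    if n_members == 0:
        return []
    chosen = rng.choice(len(pool), size=n_members, replace=False)
    partition = []
    for g in range(config.n_synonym_groups):
        group_names = []
        for v in range(config.synonym_group_size):
            idx = chosen[g * config.synonym_group_size + v]
            name = f"term {g} variant {v}"
            pool[idx] = _PoolConcept(pool[idx].token, name, pool[idx].weight, pool[idx].vocabulary)
            group_names.append(name)
        partition.append(sorted(group_names))
    return partition


def _build_signatures(
    config: GeneratorConfig, rng: np.random.Generator, pool: list[_PoolConcept]
) -> dict[str, list[str]]:
    """One signature token list per catalog diagnosis.

    With ``disjoint_signatures`` the tokens live outside the background
    pool, so signature overlap between records implies a shared
    diagnosis; otherwise signatures are sampled from the pool and may
    collide across diagnoses. Laboratory signature tokens carry a fixed
    relation (a consistently abnormal characteristic result).
    """
    vocabs = sorted(config.vocabulary_mix)
    mix = np.array([config.vocabulary_mix[v] for v in vocabs], dtype=float)
    mix /= mix.sum()
    signatures: dict[str, list[str]] = {}
    for spec in config.catalog:
        category = spec.code.rstrip("-").rstrip(".")
        tokens = []
        if config.disjoint_signatures:
            for j in range(config.signature_size):
                vocab = vocabs[rng.choice(len(vocabs), p=mix)]
                rel = None
                if vocab == "LOINC":
                    rel = ReferenceRelation(["below", "above"][int(rng.integers(2))])
                token = build_concept_token(vocab, f"SIG-{category}-{j}", rel,
                                            f"signature {category} {j}")
                tokens.append(token.canonical)
        else:
            picks = rng.choice(len(pool), size=config.signature_size, replace=False)
            tokens = [pool[int(p)].token for p in picks]
        signatures[category] = tokens
    return signatures


def generate_case_base(
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
) -> tuple[CaseBase, GroundTruth]:
    """Generate a reproducible synthetic case base with ground truth.

    The returned case base is *raw*: records still contain their own
    diagnosis tokens and possibly the indicative laboratory concept, so
    the standard preparation pipeline (exclusion, minimum-concept
    filtering) applies exactly as it would to real data.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    pool = _build_pool(config, rng)
    partition = _plant_synonyms(pool, config, rng)
    signatures = _build_signatures(config, rng, pool)
    pool_weights = np.array([c.weight for c in pool])
    pool_weights /= pool_weights.sum()

    catalog_weights = np.array([s.weight for s in config.catalog], dtype=float)
    catalog_weights /= catalog_weights.sum()
    dx_probs = np.asarray(config.multi_dx_probs, dtype=float)
    dx_probs /= dx_probs.sum()

    indicative_token = build_concept_token(
        "LOINC", "91071-1", None, "hepatitis e virus rna stool"
    )

    concept_names: dict[str, str] = {c.token: c.name for c in pool}
    for tokens in signatures.values():
        for t in tokens:
            base = SEP.join(t.split(SEP)[:2])
            concept_names.setdefault(base, f"signature {base.split(SEP)[1]}")
    concept_names[indicative_token.base] = indicative_token.concept_name

    records: list[PatientRecord] = []
    truth_dx: dict[str, list[str]] = {}
    width = len(str(config.n_records))
    for i in range(config.n_records):
        pid = f"P{i + 1:0{width}d}"
        n_dx = 1 + int(rng.choice(len(dx_probs), p=dx_probs))
        drawn = rng.choice(len(config.catalog), size=n_dx, replace=False, p=catalog_weights)
        codes = []
        categories = []
        for d in drawn:
            spec = config.catalog[int(d)]
            category = spec.code.rstrip("-").rstrip(".")
            categories.append(category)
            if spec.code.endswith(".-") and config.expand_wildcards:
                ext = config.wildcard_extensions[int(rng.integers(len(config.wildcard_extensions)))]
                codes.append(f"{category}.{ext}")
            else:
                codes.append(category if spec.code.endswith(".-") else spec.code)
        specialty = config.catalog[int(drawn[0])].specialty

        budget = int(np.clip(round(rng.lognormal(config.concept_mean_log, config.concept_sd_log)),
                             0, config.max_total))
        concepts: dict[str, int] = {}

        # Planted signal: signature tokens interleaved across the record's
        # diagnoses in fixed order (each diagnosis's first token first),
        # each kept with probability s. Included tokens split a fixed
        # fraction of the mention budget, so the signature's share of a
        # record's mass does not shrink for heavily documented patients —
        # at s = 1 any two records sharing a diagnosis share its first
        # signature token and most of their weighted mass.
        included: list[str] = []
        for rank in range(config.signature_size):
            for category in categories:
                if rng.random() < config.signal_strength:
                    included.append(signatures[category][rank])
        spent = 0
        if included and budget > 0:
            # Floor of one mention per included token: lightly documented
            # records are essentially pure signature, heavier ones keep
            # the configured signature share of their mass.
            sig_budget = min(
                budget,
                max(len(included), round(config.signature_fraction * budget)),
            )
            base_count, extra = divmod(sig_budget, len(included))
            for idx, token in enumerate(included):
                count = base_count + (1 if idx < extra else 0)
                if count > 0:
                    concepts[token] = concepts.get(token, 0) + count
                    spent += count
        remaining = budget - spent

        # Background fill up to the budget, honoring the distinct cap.
        if remaining > 0:
            draws = rng.choice(len(pool), size=remaining, p=pool_weights, replace=True)
            relations: dict[str, Optional[str]] = {}
            for d in draws:
                concept = pool[int(d)]
                token = concept.token
                if concept.vocabulary == "LOINC":
                    if token not in relations:
                        if rng.random() < config.lab_relation_coverage:
                            relations[token] = ["below", "within", "above"][
                                int(rng.choice(3, p=[0.25, 0.5, 0.25]))
                            ]
                        else:
                            relations[token] = None
                    rel = relations[token]
                    full = token + (SEP + rel if rel else "")
                else:
                    full = token
                if full not in concepts and len(concepts) >= config.max_distinct:
                    full = min(concepts)  # cap reached: fold into an existing concept
                concepts[full] = concepts.get(full, 0) + 1

        # Diagnosis tokens and the indicative concept sit on top of the
        # budget; preparation removes them again.
        if config.include_diagnosis_tokens:
            for code in codes:
                concepts[f"ICD10GM{SEP}{code}"] = concepts.get(f"ICD10GM{SEP}{code}", 0) + 1
        if config.indicative_rate > 0 and rng.random() < config.indicative_rate:
            concepts[indicative_token.canonical] = 1

        records.append(
            PatientRecord(
                person_id=pid,
                concepts=concepts,
                primary_diagnoses=frozenset(codes),
                gender=Gender.FEMALE if rng.random() < 0.5 else Gender.MALE,
                specialty=specialty,
            )
        )
        truth_dx[pid] = sorted(codes)

    case_base = CaseBase(
        records=records,
        concept_names=concept_names,
        indicative_exclusions=frozenset(
            {indicative_token.canonical} if config.indicative_rate > 0 else set()
        ),
        provenance=f"casematch synthetic cohort (seed={seed}, n={config.n_records})",
    )
    truth = GroundTruth(
        diagnoses=truth_dx,
        signatures=signatures,
        synonym_partition=partition,
    )
    return case_base, truth


def sample_diagnoses(
    config: GeneratorConfig = GeneratorConfig(),
    n: int = 5292,
    seed: int = 0,
) -> list[str]:
    """Independent single draws from the diagnosis catalog weights.

    Returns *n* catalog codes (wildcards kept as category codes). The
    empirical share of each code converges to its catalog weight; note
    that within generated *records* the shares of dominant codes are
    slightly diluted, because the extra diagnoses of multi-diagnosis
    records are drawn without replacement.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    weights = np.array([s.weight for s in config.catalog], dtype=float)
    weights /= weights.sum()
    draws = rng.choice(len(config.catalog), size=n, p=weights)
    return [config.catalog[int(d)].code.rstrip("-").rstrip(".") for d in draws]


# ---------------------------------------------------------------------------
# Mock embeddings
# ---------------------------------------------------------------------------

class MockEmbeddingBackend:
    """Deterministic hash-to-vector embedding backend with planted synonyms.

    Names belonging to one group of the synonym partition receive
    near-identical vectors (pairwise cosine >= 0.99); unrelated names
    receive independent random directions whose cosines stay far below
    0.5 in high dimension. Vectors depend only on (name/group, seed),
    so repeated calls are bitwise reproducible.
    """

    name = "mock"

    def __init__(self, synonym_partition: Sequence[Sequence[str]] = (), d: int = 768, seed: int = 0):
        self.d = d
        self.seed = seed
        self.group_of = {
            name: f"group:{i}" for i, group in enumerate(synonym_partition) for name in group
        }
        self._noise_scale = 0.002

    def _direction(self, key: str) -> np.ndarray:
        sub = np.random.default_rng((zlib.crc32(key.encode()) + self.seed) % (2**31))
        v = sub.standard_normal(self.d)
        return v / np.linalg.norm(v)

    def __call__(self, names: Sequence[str]) -> np.ndarray:
        out = np.empty((len(names), self.d))
        for i, name in enumerate(names):
            group = self.group_of.get(name)
            if group is None:
                out[i] = self._direction(f"name:{name}")
            else:
                base = self._direction(group)
                v = base + self._noise_scale * self._direction(f"member:{name}")
                out[i] = v / np.linalg.norm(v)
        return out


def generate_mock_embeddings(
    ground_truth: GroundTruth | Sequence[Sequence[str]],
    names: Sequence[str],
    d: int = 768,
    seed: int = 0,
) -> EmbeddingSet:
    """Embed *names* with the deterministic mock backend, planting the
    ground truth's synonym partition."""
    partition = (
        ground_truth.synonym_partition
        if isinstance(ground_truth, GroundTruth)
        else list(ground_truth)
    )
    backend = MockEmbeddingBackend(partition, d=d, seed=seed)
    unique = sorted(set(names))
    return EmbeddingSet(names=unique, vectors=backend(unique), backend=backend.name)


# ---------------------------------------------------------------------------
# Deterministic strata fixtures
# ---------------------------------------------------------------------------

def expanded_catalog(
    n_prevalent: int = 30,
    n_infrequent: int = 12,
    n_singleton: int = 6,
) -> list[tuple[str, int]]:
    """A 48-code diagnosis catalog with prescribed occurrence classes.

    Expands the catalog categories into subcodes and assigns exact
    occurrence counts: the first ``n_prevalent`` codes occur in more
    than 10 records, the next ``n_infrequent`` in 2-10, and the rest
    exactly once — handing :func:`case_base_from_diagnosis_counts` a
    cohort whose prevalence classes are known by construction.
    """
    categories = ["C34", "E05", "D86", "A15", "B18", "B17", "J11", "B16", "B15", "E83", "E88", "E06"]
    codes = []
    for ext in ("0", "1", "2", "3"):
        for cat in categories:
            codes.append(f"{cat}.{ext}")
    codes = codes[: n_prevalent + n_infrequent + n_singleton]
    counts = []
    for i, code in enumerate(codes):
        if i < n_prevalent:
            counts.append((code, 11 + (i % 20)))
        elif i < n_prevalent + n_infrequent:
            counts.append((code, 2 + (i % 9)))
        else:
            counts.append((code, 1))
    return counts


def case_base_from_diagnosis_counts(
    counts: Sequence[tuple[str, int]],
    mentions_per_record: int = 3,
) -> CaseBase:
    """Minimal deterministic case base realizing exact diagnosis counts.

    Every record carries one diagnosis and a few filler concepts, so
    the case base is analysis-ready (>= 2 mentions each) and
    ``stratify`` sees precisely the requested occurrence profile.
    """
    records = []
    i = 0
    for code, n in counts:
        for _ in range(n):
            i += 1
            concepts = {
                f"SNOMEDCT{SEP}{900000 + (i + j) % 50}": 1 for j in range(mentions_per_record)
            }
            records.append(
                PatientRecord(
                    person_id=f"S{i:05d}",
                    concepts=concepts,
                    primary_diagnoses=frozenset({code}),
                )
            )
    return CaseBase(records=records, provenance="deterministic strata fixture")
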