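"""Leave-one-out evaluation of diagnosis prediction by retrieval.

Every record serves once as the index patient: it is removed, the
vectorizer is refit on the remaining N-1 records (strict
cross-validation; a global-fit fast path exists), all records are
vectorized, and the neighbors are ranked by cosine similarity. A
retrieved neighbor is a true positive when it shares at least one
primary diagnosis with the index at the chosen ICD-10 granularity
level.

Reported metrics per prevalence stratum and cutoff k:

* precision@k — mean fraction of true positives among the top k,
* success rate SR@k — fraction of index patients with at least one
  true positive among the top k,

each with its empirical (population) standard deviation. Diagnoses are
stratified by dataset occurrence: prevalent (>10 records), infrequent
(2-10), singleton (1). Singleton-only records cannot have a true
positive and are excluded from evaluation; infrequent records are
evaluated at k=1 only. A uniform-random neighbor draw provides the
baseline, and a grid search over the vectorizer and threshold
parameters selects the configuration maximizing top-1 precision.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import CaseBase, PatientRecord
from .errors import ValidationError
from .granularity import GranularityLevel, match_codes, normalize_code
from .semantic_map import (
    ConceptMap,
    EmbeddingSet,
    apply_concept_map,
    build_concept_map,
    similarity_matrix,
)
from .vectorizer import Mode, VectorizerParams

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID",
    "FoldOutcome",
    "PrevalenceStrata",
    "MetricRow",
    "EvaluationReport",
    "is_true_positive",
    "precision_at_k",
    "success_rate_at_k",
    "stratify",
    "loocv",
    "random_baseline",
    "enumerate_grid",
    "grid_search",
    "random_match_base_rate",
]

#: The default hyperparameter grid. ``theta`` applies only to the
#: semantically normalized method.
DEFAULT_GRID: dict[str, list] = {
    "binary": [True, False],
    "max_df": [1.0, 0.9, 0.8, 0.6, 0.4],
    "min_df": [1, 2, 5, 8, 10],
    "theta": [0.8, 0.85, 0.9, 0.95],
}

PREVALENT = "prevalent"
INFREQUENT = "infrequent"
SINGLETON = "singleton"
ALL = "all"


@dataclass
class FoldOutcome:
    """True-positive indicators for one index record, ranks 1..k_max."""

    index_id: str
    indicators: np.ndarray
    stratum: str
    skipped: bool = False

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=int)
        if not np.isin(self.indicators, (0, 1)).all():
            raise ValidationError("indicators must be 0/1")


@dataclass
class PrevalenceStrata:
    """Occurrence-based diagnosis classes and per-record labels."""

    counts: dict[str, int]
    prevalent: frozenset[str]
    infrequent: frozenset[str]
    singleton: frozenset[str]
    record_labels: dict[str, str]

    def class_sizes(self) -> tuple[int, int, int]:
        return len(self.prevalent), len(self.infrequent), len(self.singleton)


@dataclass
class MetricRow:
    stratum: str
    k: int
    n: int
    precision: float
    precision_sd: float
    success_rate: float
    success_rate_sd: float


@dataclass
class EvaluationReport:
    """Precision/SR table for one method configuration."""

    method: str
    level: str
    params: dict
    rows: list[MetricRow]
    n_skipped: int = 0
    outcomes: list[FoldOutcome] = field(default_factory=list, repr=False)

    def get(self, stratum: str, k: int) -> MetricRow:
        for row in self.rows:
            if row.stratum == stratum and row.k == k:
                return row
        raise KeyError((stratum, k))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.rows])
        df.insert(0, "method", self.method)
        df.insert(1, "level", self.level)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "level": self.level,
            "params": self.params,
            "n_skipped": self.n_skipped,
            "rows": [asdict(r) for r in self.rows],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def is_true_positive(
    index: PatientRecord,
    neighbor: PatientRecord,
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
) -> bool:
    """Whether a neighbor shares at least one primary diagnosis with
    the index at the given granularity level."""
    if not index.primary_diagnoses or not neighbor.primary_diagnoses:
        raise ValidationError("both records need at least one primary diagnosis")
    a = [normalize_code(c) for c in index.primary_diagnoses]
    b = [normalize_code(c) for c in neighbor.primary_diagnoses]
    return match_codes(a, b, level, specialty_map)


def _check_outcomes(outcomes: Sequence[FoldOutcome], k: int) -> None:
    if not outcomes:
        raise ValidationError("no fold outcomes to aggregate")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    for o in outcomes:
        if len(o.indicators) < k:
            raise ValidationError(f"outcome for {o.index_id!r} has fewer than {k} indicators")


def precision_at_k(outcomes: Sequence[FoldOutcome], k: int) -> tuple[float, float]:
    """Mean per-record precision in the top k, with its population SD."""
    _check_outcomes(outcomes, k)
    per_record = np.array([o.indicators[:k].sum() / k for o in outcomes])
    return float(per_record.mean()), float(per_record.std(ddof=0))


def success_rate_at_k(outcomes: Sequence[FoldOutcome], k: int) -> tuple[float, float]:
    """Fraction of records with >= 1 true positive in the top k, with
    the population SD of the binary outcome."""
    _check_outcomes(outcomes, k)
    hits = np.array([1 if o.indicators[:k].any() else 0 for o in outcomes])
    return float(hits.mean()), float(hits.std(ddof=0))


def stratify(case_base: CaseBase) -> PrevalenceStrata:
    """Classify diagnoses and records by dataset occurrence.

    A diagnosis is prevalent when it occurs in more than 10 records,
    infrequent in 2-10, singleton in exactly 1. A record is labeled
    prevalent if any of its diagnoses is prevalent, else infrequent if
    any is infrequent, else singleton.
    """
    counts: dict[str, int] = {}
    record_codes: dict[str, list[str]] = {}
    for r in case_base.records:
        codes = sorted({normalize_code(c) for c in r.primary_diagnoses})
        record_codes[r.person_id] = codes
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
    prevalent = frozenset(c for c, n in counts.items() if n > 10)
    infrequent = frozenset(c for c, n in counts.items() if 2 <= n <= 10)
    singleton = frozenset(c for c, n in counts.items() if n == 1)
    labels: dict[str, str] = {}
    for pid, codes in record_codes.items():
        if any(c in prevalent for c in codes):
            labels[pid] = PREVALENT
        elif any(c in infrequent for c in codes):
            labels[pid] = INFREQUENT
        else:
            labels[pid] = SINGLETON
    return PrevalenceStrata(
        counts=counts,
        prevalent=prevalent,
        infrequent=infrequent,
        singleton=singleton,
        record_labels=labels,
    )


def _aggregate(
    outcomes: list[FoldOutcome],
    ks: Sequence[int],
) -> list[MetricRow]:
    """Stratified metric rows: prevalent at every k, infrequent and the
    combined pool at k=1 only (only the most similar patient is
    assessed for infrequent diagnoses)."""
    rows: list[MetricRow] = []
    prevalent = [o for o in outcomes if o.stratum == PREVALENT]
    infrequent = [o for o in outcomes if o.stratum == INFREQUENT]
    for k in ks:
        if prevalent:
            p, psd = precision_at_k(prevalent, k)
            s, ssd = success_rate_at_k(prevalent, k)
            rows.append(MetricRow(PREVALENT, k, len(prevalent), p, psd, s, ssd))
    if infrequent:
        p, psd = precision_at_k(infrequent, 1)
        s, ssd = success_rate_at_k(infrequent, 1)
        rows.append(MetricRow(INFREQUENT, 1, len(infrequent), p, psd, s, ssd))
    if outcomes:
        p, psd = precision_at_k(outcomes, 1)
        s, ssd = success_rate_at_k(outcomes, 1)
        rows.append(MetricRow(ALL, 1, len(outcomes), p, psd, s, ssd))
    return rows


@dataclass
class _DenseBase:
    """Count matrices and metadata shared across folds."""

    ids: list[str]
    counts: np.ndarray
    presence: np.ndarray
    df_all: np.ndarray
    dx: list[list[str]]


def _densify(case_base: CaseBase) -> _DenseBase:
    tokens = sorted({t for r in case_base.records for t in r.concepts})
    index = {t: j for j, t in enumerate(tokens)}
    n, m = len(case_base.records), len(tokens)
    counts = np.zeros((n, m))
    for i, r in enumerate(case_base.records):
        for t, c in r.concepts.items():
            counts[i, index[t]] = c
    presence = (counts > 0).astype(float)
    return _DenseBase(
        ids=[r.person_id for r in case_base.records],
        counts=counts,
        presence=presence,
        df_all=presence.sum(axis=0),
        dx=[sorted(normalize_code(c) for c in r.primary_diagnoses) for r in case_base.records],
    )


def _fold_weights(
    base: _DenseBase,
    i: int,
    params: VectorizerParams,
    refit_per_fold: bool,
) -> np.ndarray:
    """Per-concept column weight (idf x df-filter mask) for fold i."""
    n = len(base.ids)
    if refit_per_fold:
        df = base.df_all - base.presence[i]
        n_train = n - 1
    else:
        df = base.df_all
        n_train = n
    keep = (df >= params.min_df) & (df <= params.max_df * n_train + 1e-9)
    if params.mode is Mode.TFIDF:
        log = np.log if params.log_base == "e" else np.log10
        idf = log((1 + n_train) / (1 + df)) + 1.0
    else:
        idf = np.ones_like(df)
    return keep * idf


def loocv(
    case_base: CaseBase,
    params: VectorizerParams = VectorizerParams(),
    ks: Sequence[int] = (1, 3, 5, 10),
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
    concept_map: Optional[ConceptMap] = None,
    refit_per_fold: bool = True,
    method: Optional[str] = None,
) -> EvaluationReport:
    """Leave-one-out diagnosis-prediction evaluation.

    With ``refit_per_fold`` (default) document frequencies and idf are
    recomputed on each fold's N-1 training records, so the index never
    influences its own weighting; disabling it fits once globally — a
    faster but mildly leaky approximation. An index whose vector is
    zero under the fold's vocabulary cannot be queried; it is counted
    as an all-miss outcome and reported via ``n_skipped``.
    """
    ks = sorted(set(ks))
    level = GranularityLevel(level)
    if concept_map is not None:
        case_base, _ = apply_concept_map(case_base, concept_map)
    if len(case_base) < 3:
        raise ValidationError("leave-one-out evaluation needs at least 3 records")
    kmax = max(ks)
    if kmax > len(case_base) - 1:
        raise ValidationError(f"k_max={kmax} exceeds N-1={len(case_base) - 1}")

    strata = stratify(case_base)
    base = _densify(case_base)
    n = len(base.ids)
    tf = base.presence if params.binary else base.counts

    outcomes: list[FoldOutcome] = []
    n_skipped = 0
    for i in range(n):
        stratum = strata.record_labels[base.ids[i]]
        if stratum == SINGLETON:
            continue
        w = _fold_weights(base, i, params, refit_per_fold)
        v = tf * w
        x = v[i]
        nx = np.linalg.norm(x)
        if nx == 0:
            n_skipped += 1
            outcomes.append(
                FoldOutcome(base.ids[i], np.zeros(kmax, dtype=int), stratum, skipped=True)
            )
            continue
        norms = np.linalg.norm(v, axis=1)
        sims = v @ x
        # scores rounded to 12 decimals so mathematically tied cosines
        # tie-break by record id regardless of summation order
        order = sorted(
            (j for j in range(n) if j != i and norms[j] > 0),
            key=lambda j: (-round(sims[j] / (norms[j] * nx), 12), base.ids[j]),
        )
        indicators = np.zeros(kmax, dtype=int)
        for rank, j in enumerate(order[:kmax]):
            indicators[rank] = int(match_codes(base.dx[i], base.dx[j], level, specialty_map))
        outcomes.append(FoldOutcome(base.ids[i], indicators, stratum))

    report = EvaluationReport(
        method=method or ("tfidf_sem" if concept_map is not None else params.mode.value),
        level=level.value,
        params={
            "binary": params.binary,
            "max_df": params.max_df,
            "min_df": params.min_df,
            **({"theta": concept_map.theta} if concept_map is not None else {}),
        },
        rows=_aggregate(outcomes, ks),
        n_skipped=n_skipped,
        outcomes=outcomes,
    )
    return report


def random_baseline(
    case_base: CaseBase,
    ks: Sequence[int] = (1, 3, 5, 10),
    seed: int = 0,
    repetitions: int = 1,
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
) -> EvaluationReport:
    """Baseline drawing neighbors uniformly without replacement.

    Metrics are averaged over ``repetitions`` independent draws (one by
    default, the single-run convention); the seed makes draws
    reproducible.
    """
    ks = sorted(set(ks))
    level = GranularityLevel(level)
    if len(case_base) < 3:
        raise ValidationError("random baseline needs at least 3 records")
    kmax = max(ks)
    if kmax > len(case_base) - 1:
        raise ValidationError(f"k_max={kmax} exceeds N-1={len(case_base) - 1}")
    strata = stratify(case_base)
    base = _densify(case_base)
    n = len(base.ids)
    rng = np.random.default_rng(seed)

    per_rep_rows: list[list[MetricRow]] = []
    last_outcomes: list[FoldOutcome] = []
    for _ in range(repetitions):
        outcomes = []
        for i in range(n):
            stratum = strata.record_labels[base.ids[i]]
            if stratum == SINGLETON:
                continue
            others = [j for j in range(n) if j != i]
            picks = rng.choice(len(others), size=kmax, replace=False)
            indicators = np.array(
                [int(match_codes(base.dx[i], base.dx[others[p]], level, specialty_map)) for p in picks]
            )
            outcomes.append(FoldOutcome(base.ids[i], indicators, stratum))
        per_rep_rows.append(_aggregate(outcomes, ks))
        last_outcomes = outcomes

    rows = []
    for idx, template in enumerate(per_rep_rows[0]):
        rows.append(
            MetricRow(
                stratum=template.stratum,
                k=template.k,
                n=template.n,
                precision=float(np.mean([r[idx].precision for r in per_rep_rows])),
                precision_sd=float(np.mean([r[idx].precision_sd for r in per_rep_rows])),
                success_rate=float(np.mean([r[idx].success_rate for r in per_rep_rows])),
                success_rate_sd=float(np.mean([r[idx].success_rate_sd for r in per_rep_rows])),
            )
        )
    return EvaluationReport(
        method="random",
        level=level.value,
        params={"seed": seed, "repetitions": repetitions},
        rows=rows,
        outcomes=last_outcomes,
    )


def random_match_base_rate(
    case_base: CaseBase,
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
) -> float:
    """Expected top-1 precision of a uniformly random neighbor draw.

    Mean, over eligible (non-singleton) index records, of the fraction
    of other records sharing at least one diagnosis at *level*.
    """
    strata = stratify(case_base)
    base = _densify(case_base)
    n = len(base.ids)
    probs = []
    for i in range(n):
        if strata.record_labels[base.ids[i]] == SINGLETON:
            continue
        matches = sum(
            1 for j in range(n) if j != i and match_codes(base.dx[i], base.dx[j], level, specialty_map)
        )
        probs.append(matches / (n - 1))
    if not probs:
        raise ValidationError("no eligible records")
    return float(np.mean(probs))


def enumerate_grid(mode: str = "tfidf", grid: Optional[Mapping[str, list]] = None) -> list[dict]:
    """Expand the hyperparameter grid into parameter dictionaries.

    The plain TF / TF-IDF grid spans binary x max_df x min_df; the
    semantically normalized method additionally spans theta.
    """
    grid = dict(grid or DEFAULT_GRID)
    keys = ["binary", "max_df", "min_df"]
    if mode == "tfidf_sem":
        keys.append("theta")
    missing = [k for k in keys if k not in grid or not grid[k]]
    if missing:
        raise ValidationError(f"grid missing values for: {missing}")
    combos = []
    for values in itertools.product(*(grid[k] for k in keys)):
        combos.append(dict(zip(keys, values)))
    return combos


def grid_search(
    case_base: CaseBase,
    mode: str = "tfidf",
    grid: Optional[Mapping[str, list]] = None,
    ks: Sequence[int] = (1,),
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
    embeddings: Optional[EmbeddingSet] = None,
    refit_per_fold: bool = True,
) -> pd.DataFrame:
    """Evaluate every grid combination by LOOCV and rank the results.

    The objective is the average precision for the most similar patient
    (combined eligible pool, k=1); ties are broken by success rate,
    then by the parameters themselves, so the output ordering is
    deterministic regardless of execution order.
    """
    if mode not in ("tf", "tfidf", "tfidf_sem"):
        raise ValidationError(f"unknown method mode: {mode!r}")
    combos = enumerate_grid(mode, grid)
    concept_maps: dict[float, ConceptMap] = {}
    if mode == "tfidf_sem":
        if embeddings is None:
            raise ValidationError("tfidf_sem grid search requires an EmbeddingSet")
        sim = similarity_matrix(embeddings)
        name_freq: dict[str, int] = {}
        for r in case_base.records:
            for t, c in r.concepts.items():
                name = case_base.name_of(t)
                if name:
                    name_freq[name] = name_freq.get(name, 0) + c
        for theta in sorted({c["theta"] for c in combos}):
            concept_maps[theta] = build_concept_map(sim, theta, name_freq)

    results = []
    for combo in combos:
        params = VectorizerParams(
            mode=Mode.TF if mode == "tf" else Mode.TFIDF,
            binary=combo["binary"],
            max_df=combo["max_df"],
            min_df=combo["min_df"],
        )
        cmap = concept_maps.get(combo.get("theta")) if mode == "tfidf_sem" else None
        try:
            report = loocv(
                case_base,
                params,
                ks=ks,
                level=level,
                specialty_map=specialty_map,
                concept_map=cmap,
                refit_per_fold=refit_per_fold,
                method=mode,
            )
            top1 = report.get(ALL, 1)
            row = {**combo, "precision_top1": top1.precision, "sr_top1": top1.success_rate}
        except ValidationError as exc:
            logger.warning("grid point %s failed: %s", combo, exc)
            row = {**combo, "precision_top1": float("nan"), "sr_top1": float("nan")}
        results.append(row)
        logger.info("grid point %s -> %s", combo, row.get("precision_top1"))

    df = pd.DataFrame(results)
    sort_cols = ["precision_top1", "sr_top1"] + [c for c in ("binary", "max_df", "min_df", "theta") if c in df]
    df = df.sort_values(
        sort_cols,
        ascending=[False, False] + [True] * (len(sort_cols) - 2),
        kind="mergesort",
    ).reset_index(drop=True)
    return df
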