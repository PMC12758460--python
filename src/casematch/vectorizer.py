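"""Concept weighting: term frequency and smoothed TF-IDF.

Records are rows, concept tokens are columns, and each cell holds the
weight of concept *c_j* in record *p_i*. Term frequency is the raw
mention count (or a 0/1 presence indicator in binary mode); the inverse
document frequency uses the smoothed form

    idf(c_j) = log((1 + N) / (1 + df_j)) + 1

so concepts occurring in every training record keep a weight of 1
rather than vanishing. Document-frequency filters (``min_df`` absolute,
``max_df`` proportional) prune rare and ubiquitous concepts before
weighting. Vectors are deliberately not L2-normalized here: cosine
retrieval divides by the norms, making pre-normalization redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data_model import CaseBase, PatientRecord
from .errors import ValidationError

__all__ = [
    "Mode",
    "VectorizerParams",
    "FittedVocabulary",
    "WeightMatrix",
    "term_frequency",
    "inverse_document_frequency",
    "fit",
    "transform",
    "transform_record",
    "vectorize",
]


class Mode(str, Enum):
    TF = "tf"
    TFIDF = "tfidf"


@dataclass(frozen=True)
class VectorizerParams:
    """Weighting configuration.

    ``max_df`` is a proportion in (0, 1]: concepts present in more than
    that fraction of training records are dropped. ``min_df`` is an
    absolute document count. ``log_base`` selects the idf logarithm
    (natural by default; base 10 available for sensitivity analysis).
    """

    mode: Mode = Mode.TFIDF
    binary: bool = False
    max_df: float = 1.0
    min_df: int = 1
    log_base: str = "e"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_df <= 1.0):
            raise ValidationError(f"max_df must be in (0, 1], got {self.max_df}")
        if self.min_df < 1:
            raise ValidationError(f"min_df must be >= 1, got {self.min_df}")
        if self.log_base not in ("e", "10"):
            raise ValidationError(f"log_base must be 'e' or '10', got {self.log_base!r}")
        object.__setattr__(self, "mode", Mode(self.mode))


@dataclass
class FittedVocabulary:
    """Retained concept columns with their document statistics."""

    tokens: list[str]
    df: np.ndarray
    idf: np.ndarray
    n_train: int
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: j for j, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class WeightMatrix:
    """Sparse record-by-concept weight matrix with aligned labels."""

    row_ids: list[str]
    tokens: list[str]
    matrix: sp.csr_matrix

    def save(self, path_prefix: str | Path) -> dict[str, Path]:
        """Export as MatrixMarket plus row-id and token sidecar CSVs."""
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": prefix.with_suffix(".mtx"),
            "rows": Path(f"{prefix}.rows.csv"),
            "cols": Path(f"{prefix}.cols.csv"),
        }
        scipy.io.mmwrite(str(paths["matrix"]), self.matrix)
        pd.DataFrame({"person_id": self.row_ids}).to_csv(paths["rows"], index=False)
        pd.DataFrame({"token": self.tokens}).to_csv(paths["cols"], index=False)
        return paths


def term_frequency(token: str, record: PatientRecord, binary: bool = False) -> int:
    """Mention count of *token* in *record* (presence indicator if binary)."""
    count = record.concepts.get(token, 0)
    if binary:
        return 1 if count > 0 else 0
    return count


def inverse_document_frequency(df: int, n: int, log_base: str = "e") -> float:
    """Smoothed inverse document frequency of a concept.

    Strictly decreasing in *df* with minimum value 1.0 at ``df == n``.
    """
    if df < 0 or n < 0 or df > n:
        raise ValidationError(f"need 0 <= df <= N, got df={df}, N={n}")
    ratio = (1 + n) / (1 + df)
    return (math.log(ratio) if log_base == "e" else math.log10(ratio)) + 1.0


def _records(case_base: CaseBase | Sequence[PatientRecord]) -> list[PatientRecord]:
    if isinstance(case_base, CaseBase):
        return list(case_base.records)
    return list(case_base)


def fit(case_base: CaseBase | Sequence[PatientRecord], params: VectorizerParams) -> FittedVocabulary:
    """Learn the vocabulary and idf values from training records.

    Document frequency is the binary notion (number of records holding
    the token at least once) regardless of the binary TF flag. Retained
    columns are ordered lexicographically for run-to-run determinism.
    """
    records = _records(case_base)
    if not records:
        raise ValidationError("cannot fit on an empty case base")
    n = len(records)
    df_all: dict[str, int] = {}
    for r in records:
        for token in r.concepts:
            df_all[token] = df_all.get(token, 0) + 1
    max_count = params.max_df * n + 1e-9
    tokens = sorted(t for t, c in df_all.items() if c >= params.min_df and c <= max_count)
    if not tokens:
        raise ValidationError(
            f"vocabulary empty after df filtering (min_df={params.min_df}, "
            f"max_df={params.max_df}, N={n})"
        )
    df = np.array([df_all[t] for t in tokens], dtype=np.int64)
    idf = np.array([inverse_document_frequency(int(c), n, params.log_base) for c in df])
    return FittedVocabulary(tokens=tokens, df=df, idf=idf, n_train=n)


def transform_record(
    record: PatientRecord,
    vocabulary: FittedVocabulary,
    params: VectorizerParams,
) -> np.ndarray:
    """Weight vector of one record over the fitted vocabulary.

    Out-of-vocabulary tokens are dropped (debug-logged only); a record
    with no in-vocabulary concepts yields the zero vector.
    """
    vec = np.zeros(len(vocabulary))
    for token, count in record.concepts.items():
        j = vocabulary.index.get(token)
        if j is None:
            continue
        tf = 1 if (params.binary and count > 0) else count
        vec[j] = tf * (vocabulary.idf[j] if params.mode is Mode.TFIDF else 1.0)
    return vec


def transform(
    case_base: CaseBase | Sequence[PatientRecord],
    vocabulary: FittedVocabulary,
    params: VectorizerParams,
) -> WeightMatrix:
    """Weight matrix of a set of records over the fitted vocabulary."""
    records = _records(case_base)
    rows, cols, data = [], [], []
    for i, r in enumerate(records):
        for token, count in r.concepts.items():
            j = vocabulary.index.get(token)
            if j is None:
                continue
            tf = 1 if (params.binary and count > 0) else count
            w = tf * (vocabulary.idf[j] if params.mode is Mode.TFIDF else 1.0)
            if w != 0:
                rows.append(i)
                cols.append(j)
                data.append(w)
    matrix = sp.csr_matrix(
        (np.array(data, dtype=float), (rows, cols)),
        shape=(len(records), len(vocabulary)),
    )
    return WeightMatrix(
        row_ids=[r.person_id for r in records],
        tokens=list(vocabulary.tokens),
        matrix=matrix,
    )


def vectorize(
    case_base: CaseBase | Sequence[PatientRecord],
    params: VectorizerParams,
) -> tuple[WeightMatrix, FittedVocabulary]:
    """Fit on *case_base* and transform it in one step."""
    vocab = fit(case_base, params)
    return transform(case_base, vocab, params), vocab
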