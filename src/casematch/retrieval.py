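"""Cosine-similarity nearest-neighbor retrieval over weight vectors.

Given an index patient's weight vector and the weight matrix of the
case base, the k most similar records are returned with their cosine
scores and the concept tokens shared with the index (the explanation
payload a decision-support front end would display). Ties are broken
by ascending record id for cross-platform reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .vectorizer import WeightMatrix

__all__ = ["Neighbor", "QueryResult", "cosine_similarity", "top_k"]


@dataclass(frozen=True)
class Neighbor:
    person_id: str
    score: float
    shared_concepts: tuple[str, ...]


@dataclass
class QueryResult:
    """Ranked neighbors of one index record."""

    index_id: str
    k: int
    neighbors: list[Neighbor]

    def to_json(self) -> str:
        return json.dumps(
            {
                "index_id": self.index_id,
                "k": self.k,
                "neighbors": [
                    {"id": n.person_id, "score": n.score, "shared_concepts": list(n.shared_concepts)}
                    for n in self.neighbors
                ],
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _dense(v) -> np.ndarray:
    if sp.issparse(v):
        return np.asarray(v.todense()).ravel()
    return np.asarray(v, dtype=float).ravel()


def cosine_similarity(v, w) -> float:
    """Cosine of the angle between two nonzero weight vectors.

    Dot product over the product of L2 norms; lies in [-1, 1], and in
    [0, 1] for the non-negative weights produced by the vectorizer.
    """
    v = _dense(v)
    w = _dense(w)
    nv = np.linalg.norm(v)
    nw = np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValidationError("cosine similarity is undefined for a zero vector")
    return float(np.clip(v @ w / (nv * nw), -1.0, 1.0))


def top_k(
    index_id: str,
    index_vector,
    weights: WeightMatrix,
    k: int,
    tokens: Optional[Sequence[str]] = None,
) -> QueryResult:
    """The k records most similar to the index vector.

    The index record itself (matched by ``index_id``) is never returned.
    Rows with zero norm cannot be scored and are excluded from the
    candidate set. Ranking is by descending cosine, then ascending
    record id. ``shared_concepts`` lists tokens with nonzero weight in
    both the index and the neighbor vector.
    """
    x = _dense(index_vector)
    nx = np.linalg.norm(x)
    if nx == 0:
        raise ValidationError(
            f"index record {index_id!r} has a zero weight vector and cannot be queried"
        )
    m = weights.matrix
    candidates = [i for i, rid in enumerate(weights.row_ids) if rid != index_id]
    n_candidates = len(candidates)
    if not (1 <= k <= n_candidates):
        raise ValidationError(f"k must be in [1, {n_candidates}], got {k}")

    norms = np.sqrt(np.asarray(m.multiply(m).sum(axis=1)).ravel())
    dots = np.asarray(m @ x).ravel()
    scored = [
        (i, float(np.clip(dots[i] / (norms[i] * nx), -1.0, 1.0)))
        for i in candidates
        if norms[i] > 0
    ]
    # round to 12 decimals so mathematically tied scores fall through to
    # the ascending-id tie-break regardless of float summation order
    scored.sort(key=lambda t: (-round(t[1], 12), weights.row_ids[t[0]]))

    token_list = list(tokens) if tokens is not None else list(weights.tokens)
    x_support = set(np.flatnonzero(x))
    neighbors = []
    for i, score in scored[:k]:
        row_support = set(m.getrow(i).indices)
        shared = tuple(sorted(token_list[j] for j in (x_support & row_support)))
        neighbors.append(Neighbor(person_id=weights.row_ids[i], score=score, shared_concepts=shared))
    return QueryResult(index_id=index_id, k=k, neighbors=neighbors)
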