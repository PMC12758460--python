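"""Embedding-based concept normalization.

Clinically coded datasets contain near-synonymous concept names
("cough" vs "coughing") that fragment term statistics. Each unique
concept name is embedded with a medical-terminology encoder, a pairwise
cosine-similarity matrix is built, and names whose similarity reaches a
threshold θ are merged: connected components of the thresholded
similarity graph collapse onto a single representative name (the most
frequent one in the corpus, ties broken lexicographically). Applying
the resulting concept map rewrites merged tokens and pools their
mention counts.

The default embedding backend in tests is a deterministic mock (see
:mod:`casematch.synthetic_data`); a pretrained multilingual medical
encoder can be loaded by name at runtime when the optional
``transformers`` stack is installed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .data_model import SEP, CaseBase, base_token, split_token
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingBackend",
    "EmbeddingSet",
    "SimilarityMatrix",
    "ConceptMap",
    "embed_concepts",
    "similarity_matrix",
    "build_concept_map",
    "apply_concept_map",
    "load_transformer_backend",
]


class EmbeddingBackend(Protocol):
    """Anything that maps concept names to fixed-dimension vectors."""

    name: str

    def __call__(self, names: Sequence[str]) -> np.ndarray: ...


@dataclass
class EmbeddingSet:
    """Embeddings of unique concept names, all of one dimension."""

    names: list[str]
    vectors: np.ndarray
    backend: str = "unknown"
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.names):
            raise ValidationError("vectors must be (len(names), d)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = [self.names[i] for i in np.flatnonzero(norms == 0)[:3]]
            raise ValidationError(f"zero embedding vectors for: {bad}")
        self.index = {n: i for i, n in enumerate(self.names)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def save(self, path_prefix: str | Path) -> None:
        """Cache to a .npy array with a JSON sidecar (names, d, backend)."""
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.save(f"{prefix}.npy", self.vectors)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"names": self.names, "d": self.dimension, "backend": self.backend}, fh)

    @classmethod
    def load(cls, path_prefix: str | Path) -> "EmbeddingSet":
        prefix = Path(path_prefix)
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        return cls(names=meta["names"], vectors=np.load(f"{prefix}.npy"), backend=meta["backend"])


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise cosine similarities with unit diagonal."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")


def embed_concepts(names: Sequence[str], backend: EmbeddingBackend) -> EmbeddingSet:
    """Embed unique concept names with the given backend."""
    if not names:
        raise ValidationError("no concept names to embed")
    if any(not n for n in names):
        raise ValidationError("empty concept name")
    unique = sorted(set(names))
    try:
        vectors = np.asarray(backend(unique), dtype=float)
    except Exception as exc:  # noqa: BLE001 - annotate backend failures
        raise ValidationError(
            f"embedding backend {getattr(backend, 'name', backend)!r} failed: {exc}"
        ) from exc
    return EmbeddingSet(names=unique, vectors=vectors, backend=getattr(backend, "name", "unknown"))


def similarity_matrix(embeddings: EmbeddingSet) -> SimilarityMatrix:
    """All pairwise cosine similarities between the embeddings."""
    v = embeddings.vectors
    unit = v / np.linalg.norm(v, axis=1, keepdims=True)
    s = np.clip(unit @ unit.T, -1.0, 1.0)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(names=list(embeddings.names), values=s)


@dataclass
class ConceptMap:
    """Idempotent mapping from concept names to their representatives."""

    theta: float
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValidationError(f"theta must be in (0, 1], got {self.theta}")
        for name, rep in self.mapping.items():
            if self.mapping.get(rep, rep) != rep:
                raise ValidationError(f"representative {rep!r} of {name!r} does not map to itself")

    def __call__(self, name: str) -> str:
        return self.mapping.get(name, name)

    @property
    def n_replaced(self) -> int:
        """Number of names mapped onto a different representative."""
        return sum(1 for k, v in self.mapping.items() if k != v)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["concept_name", "representative_name"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, theta: float) -> "ConceptMap":
        df = pd.read_csv(path, dtype=str)
        return cls(theta=theta, mapping=dict(zip(df.concept_name, df.representative_name)))


def build_concept_map(
    sim: SimilarityMatrix,
    theta: float,
    corpus_frequencies: Optional[Mapping[str, int]] = None,
) -> ConceptMap:
    """Merge names whose pairwise similarity reaches *theta*.

    Merging uses connected components of the thresholded similarity
    graph (single linkage): thresholded similarity is not transitive,
    but the equality constraint f(a) = f(b) is, so any chain of
    above-threshold pairs must share one representative. The component
    representative is the highest-corpus-frequency member, ties broken
    by lexicographic order; singletons map to themselves.
    """
    if not (0.0 < theta <= 1.0):
        raise ValidationError(f"theta must be in (0, 1], got {theta}")
    freq = corpus_frequencies or {}
    adj = sp.csr_matrix(sim.values >= theta)
    n_comp, labels = connected_components(adj, directed=False)
    mapping: dict[str, str] = {}
    for comp in range(n_comp):
        members = [sim.names[i] for i in np.flatnonzero(labels == comp)]
        rep = min(members, key=lambda nm: (-freq.get(nm, 1), nm))
        for nm in members:
            mapping[nm] = rep
    return ConceptMap(theta=theta, mapping=mapping)


def apply_concept_map(case_base: CaseBase, concept_map: ConceptMap) -> tuple[CaseBase, int]:
    """Rewrite merged concepts onto their representative tokens.

    Tokens are keyed by concept name: a token whose name maps to a
    different representative is rewritten to the representative's base
    token, preserving any reference-range relation, so relation-bearing
    tokens only ever merge with tokens carrying the same relation.
    Counts of tokens merging onto the same target are summed; total
    mention count is conserved. Returns the rewritten case base and the
    number of distinct tokens that were replaced.
    """
    # Representative name -> base token carrying that name (ties: lexicographic).
    name_to_base: dict[str, str] = {}
    for base, name in case_base.concept_names.items():
        if name and (name not in name_to_base or base < name_to_base[name]):
            name_to_base[name] = base

    replaced_tokens: set[str] = set()
    new_records = []
    for record in case_base.records:
        merged: dict[str, int] = {}
        for token, count in record.concepts.items():
            base, rel = split_token(token)
            name = case_base.concept_names.get(base, "")
            rep = concept_map(name) if name else name
            new_token = token
            if name and rep != name:
                rep_base = name_to_base.get(rep)
                if rep_base is not None and rep_base != base:
                    new_token = rep_base + (SEP + rel if rel else "")
                    replaced_tokens.add(token)
            merged[new_token] = merged.get(new_token, 0) + count
        new_records.append(replace(record, concepts=merged))

    new_names = dict(case_base.concept_names)
    for base, name in case_base.concept_names.items():
        rep = concept_map(name) if name else name
        if name and rep != name and name_to_base.get(rep, base) != base:
            new_names[base] = name  # unchanged; rewritten tokens use the rep's base
    return replace(case_base, records=new_records, concept_names=new_names), len(replaced_tokens)


def load_transformer_backend(model_name: str = "GanjinZero/coder_all") -> EmbeddingBackend:
    """Load a pretrained medical-term encoder as an embedding backend.

    Requires the optional ``transformers``/``torch`` stack; the test
    suite never needs it — the deterministic mock backend stands in.
    """
    try:
        import torch  # type: ignore
        from transformers import AutoModel, AutoTokenizer  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "transformers/torch are required for pretrained embedding backends; "
            "install them or use the deterministic mock backend"
        ) from exc

    tokenizer = AutoTokenizer.from_pretrained(model_name)  # pragma: no cover
    model = AutoModel.from_pretrained(model_name)  # pragma: no cover

    class _Backend:  # pragma: no cover - exercised only with the optional stack
        name = model_name

        def __call__(self, names: Sequence[str]) -> np.ndarray:
            with torch.no_grad():
                enc = tokenizer(list(names), padding=True, truncation=True, return_tensors="pt")
                out = model(**enc).last_hidden_state[:, 0, :]
            return out.numpy()

    return _Backend()  # pragma: no cover
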