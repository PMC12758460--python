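"""Per-diagnosis-group concept importance.

For clinical interpretation, records are grouped by their primary
diagnoses (at a configurable granularity level) and the TF-IDF weights
of each concept are summed over the group's members, ranking the
concepts that drive similarity within each disease group. The weights
are plain TF-IDF, without semantic normalization, so the ranked tokens
are the original coded concepts. Expert relevance ratings of the
top-ranked concepts (integers 1-5) are aggregated to a mean and a
population standard deviation per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .data_model import CaseBase
from .errors import ValidationError
from .granularity import GranularityLevel, normalize_code, truncate_code
from .vectorizer import WeightMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConceptScoreTable",
    "group_concept_scores",
    "top_n_concepts",
    "aggregate_ratings",
    "write_score_tables",
]


@dataclass
class ConceptScoreTable:
    """Ranked summed concept weights for one diagnosis group."""

    group: str
    table: pd.DataFrame  # columns: rank, token, concept_name, score


def group_concept_scores(
    case_base: CaseBase,
    weights: WeightMatrix,
    level: GranularityLevel | str = GranularityLevel.FULL,
    specialty_map: Optional[Mapping[str, str]] = None,
) -> dict[str, ConceptScoreTable]:
    """Sum per-record concept weights within each diagnosis group.

    Records with several primary diagnoses contribute fully to every
    matching group. Tokens are ranked by descending summed score, ties
    broken lexicographically. Groups whose members carry no nonzero
    weights are excluded with a warning.
    """
    level = GranularityLevel(level)
    row_index = {pid: i for i, pid in enumerate(weights.row_ids)}
    members: dict[str, list[int]] = {}
    for record in case_base.records:
        i = row_index.get(record.person_id)
        if i is None:
            continue
        groups = {
            truncate_code(normalize_code(c), level, specialty_map)
            for c in record.primary_diagnoses
        }
        for g in groups:
            members.setdefault(g, []).append(i)

    dense = np.asarray(weights.matrix.todense())
    tables: dict[str, ConceptScoreTable] = {}
    for group in sorted(members):
        scores = dense[members[group]].sum(axis=0)
        nonzero = np.flatnonzero(scores)
        if nonzero.size == 0:
            logger.warning("group %r has no weighted concepts; excluded", group)
            continue
        df = pd.DataFrame(
            {
                "token": [weights.tokens[j] for j in nonzero],
                "score": scores[nonzero],
            }
        )
        df["concept_name"] = [case_base.name_of(t) for t in df["token"]]
        df = df.sort_values(["score", "token"], ascending=[False, True], kind="mergesort")
        df.insert(0, "rank", range(1, len(df) + 1))
        tables[group] = ConceptScoreTable(group=group, table=df.reset_index(drop=True))
    return tables


def top_n_concepts(table: ConceptScoreTable, n: int = 5) -> list[str]:
    """The n highest-scoring tokens of a group (all of them if fewer)."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if table.table.empty:
        raise ValidationError(f"group {table.group!r} has an empty score table")
    return list(table.table["token"].head(n))


def aggregate_ratings(ratings: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Aggregate expert relevance ratings per group.

    Input columns: ``group``, ``token``, ``rater_id``, ``rating`` with
    ratings in 1..5. Returns one row per group with the mean and the
    population standard deviation, rounded to one decimal place.
    """
    if not isinstance(ratings, pd.DataFrame):
        ratings = pd.read_csv(ratings)
    required = {"group", "rating"}
    if not required.issubset(ratings.columns):
        raise ValidationError(f"ratings need columns {sorted(required)}")
    if ratings.empty:
        raise ValidationError("no ratings to aggregate")
    values = ratings["rating"]
    if not np.isin(values, [1, 2, 3, 4, 5]).all():
        bad = sorted(set(values) - {1, 2, 3, 4, 5})
        raise ValidationError(f"ratings must be integers 1-5; found {bad}")
    rows = []
    for group, sub in ratings.groupby("group", sort=True):
        arr = sub["rating"].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "n": len(arr),
                "mean": round(float(arr.mean()), 1),
                "sd": round(float(arr.std(ddof=0)), 1),
            }
        )
    return pd.DataFrame(rows)


def write_score_tables(
    tables: Mapping[str, ConceptScoreTable],
    path: str | Path,
    n: Optional[int] = None,
) -> None:
    """Write score tables to one CSV (group, rank, token, concept_name, score)."""
    frames = []
    for group in sorted(tables):
        df = tables[group].table.copy()
        if n is not None:
            df = df.head(n)
        df.insert(0, "group", group)
        frames.append(df)
    pd.concat(frames, ignore_index=True)[
        ["group", "rank", "token", "concept_name", "score"]
    ].to_csv(path, index=False)
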