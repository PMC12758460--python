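"""Shared fixtures: tiny hand-built case bases and random-base factories."""

from __future__ import annotations

import numpy as np
import pytest

from casematch.data_model import CaseBase, PatientRecord


def make_record(pid: str, concepts: dict[str, int], dx: set[str], **kw) -> PatientRecord:
    return PatientRecord(person_id=pid, concepts=dict(concepts), primary_diagnoses=frozenset(dx), **kw)


def random_case_base(
    rng: np.random.Generator,
    n_records: int = 8,
    n_tokens: int = 12,
    n_codes: int = 4,
) -> CaseBase:
    """A small random case base with valid ICD-ish diagnosis codes."""
    tokens = [f"SNOMEDCT|{100 + t}" for t in range(n_tokens)]
    codes = [f"{'ABCE'[c % 4]}{10 + c}.{c % 3}" for c in range(n_codes)]
    records = []
    for i in range(n_records):
        n_mention_types = min(int(rng.integers(1, 6)), n_tokens)
        picks = rng.choice(n_tokens, size=n_mention_types, replace=False)
        concepts = {tokens[p]: int(rng.integers(1, 4)) for p in picks}
        n_dx = 1 + int(rng.random() < 0.25)
        dx = {codes[int(c)] for c in rng.choice(n_codes, size=n_dx, replace=False)}
        records.append(make_record(f"R{i:03d}", concepts, dx))
    return CaseBase(records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_case_base() -> CaseBase:
    """Five records with hand-checkable overlap structure."""
    return CaseBase(
        records=[
            make_record("P1", {"SNOMEDCT|1": 2, "SNOMEDCT|2": 1}, {"B18.1"}),
            make_record("P2", {"SNOMEDCT|1": 2, "SNOMEDCT|2": 1}, {"B18.1"}),
            make_record("P3", {"SNOMEDCT|2": 1, "SNOMEDCT|3": 3}, {"C34.1"}),
            make_record("P4", {"SNOMEDCT|3": 1, "SNOMEDCT|4": 1}, {"C34.1", "E05.0"}),
            make_record("P5", {"SNOMEDCT|4": 2, "SNOMEDCT|5": 1}, {"E05.0"}),
        ],
        concept_names={
            "SNOMEDCT|1": "cough",
            "SNOMEDCT|2": "coughing",
            "SNOMEDCT|3": "fever",
            "SNOMEDCT|4": "fatigue",
            "SNOMEDCT|5": "weight loss",
        },
    )
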