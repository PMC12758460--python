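"""Independent brute-force re-implementation of the evaluation pipeline.

Deliberately written with plain dictionaries, ``math`` and exhaustive
loops — no numpy, no shared code with the package internals — so it can
serve as an oracle for the vectorization, ranking and metric formulas.
"""

from __future__ import annotations

import math


def bf_normalize(code: str) -> str:
    c = code.replace(" ", "").upper()
    while c.endswith("-") or c.endswith("."):
        c = c[:-1]
    return c


def bf_truncate(code: str, level: str, specialty_map=None) -> str:
    if level == "full":
        return code
    if level == "category3":
        return code[:3]
    if level == "chapter":
        return code[0]
    for prefix in sorted(specialty_map, key=len, reverse=True):
        if code.startswith(prefix):
            return specialty_map[prefix]
    raise KeyError(code)


def bf_match(dx_a, dx_b, level="full", specialty_map=None) -> bool:
    a = [bf_normalize(c) for c in dx_a]
    b = [bf_normalize(c) for c in dx_b]
    for x in a:
        for y in b:
            if level == "full":
                if x == y or (len(x) == 3 and y.startswith(x)) or (len(y) == 3 and x.startswith(y)):
                    return True
            elif bf_truncate(x, level, specialty_map) == bf_truncate(y, level, specialty_map):
                return True
    return False


def bf_strata(records) -> dict[str, str]:
    counts: dict[str, int] = {}
    for r in records:
        for c in {bf_normalize(d) for d in r.primary_diagnoses}:
            counts[c] = counts.get(c, 0) + 1
    labels = {}
    for r in records:
        codes = {bf_normalize(d) for d in r.primary_diagnoses}
        if any(counts[c] > 10 for c in codes):
            labels[r.person_id] = "prevalent"
        elif any(2 <= counts[c] <= 10 for c in codes):
            labels[r.person_id] = "infrequent"
        else:
            labels[r.person_id] = "singleton"
    return labels


def bf_loocv_outcomes(records, *, mode="tfidf", binary=False, max_df=1.0, min_df=1,
                      kmax=3, level="full", specialty_map=None):
    """Per-index TP indicator lists, skipped indices as all-zero rows."""
    n = len(records)
    labels = bf_strata(records)
    outcomes = []
    for i, index in enumerate(records):
        if labels[index.person_id] == "singleton":
            continue
        train = [r for j, r in enumerate(records) if j != i]
        df: dict[str, int] = {}
        for r in train:
            for t in r.concepts:
                df[t] = df.get(t, 0) + 1
        vocab = {
            t for t, c in df.items()
            if c >= min_df and c <= max_df * (n - 1) + 1e-9
        }

        def weight(rec):
            v = {}
            for t, c in rec.concepts.items():
                if t not in vocab:
                    continue
                tf = 1 if binary else c
                idf = math.log((1 + (n - 1)) / (1 + df.get(t, 0))) + 1 if mode == "tfidf" else 1.0
                v[t] = tf * idf
            return v

        x = weight(index)
        nx = math.sqrt(sum(w * w for w in x.values()))
        if nx == 0:
            outcomes.append((index.person_id, labels[index.person_id], [0] * kmax, True))
            continue
        scored = []
        for r in train:
            v = weight(r)
            nv = math.sqrt(sum(w * w for w in v.values()))
            if nv == 0:
                continue
            dot = sum(x[t] * v[t] for t in x if t in v)
            scored.append((r.person_id, dot / (nx * nv)))
        scored.sort(key=lambda t: (-round(t[1], 12), t[0]))
        by_id = {r.person_id: r for r in train}
        indicators = [0] * kmax
        for rank, (pid, _) in enumerate(scored[:kmax]):
            indicators[rank] = int(
                bf_match(index.primary_diagnoses, by_id[pid].primary_diagnoses, level, specialty_map)
            )
        outcomes.append((index.person_id, labels[index.person_id], indicators, False))
    return outcomes


def bf_precision(indicator_rows, k):
    vals = [sum(row[:k]) / k for row in indicator_rows]
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
    return mean, sd


def bf_success_rate(indicator_rows, k):
    vals = [1 if any(row[:k]) else 0 for row in indicator_rows]
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
    return mean, sd
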