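"""LOOCV metrics: hand-traced folds, strata, baseline, grid enumeration."""

import numpy as np
import pytest

from casematch.data_model import CaseBase
from casematch.errors import ValidationError
from casematch.evaluation import (
    ALL,
    FoldOutcome,
    DEFAULT_GRID,
    enumerate_grid,
    grid_search,
    is_true_positive,
    loocv,
    precision_at_k,
    random_baseline,
    random_match_base_rate,
    stratify,
    success_rate_at_k,
)
from casematch.vectorizer import VectorizerParams

from _bruteforce import bf_loocv_outcomes, bf_precision, bf_success_rate
from conftest import make_record, random_case_base


def outcome(pid, indicators, stratum="prevalent"):
    return FoldOutcome(pid, np.array(indicators), stratum)


class TestMetrics:
    def test_all_hits_and_all_misses(self):
        perfect = [outcome("a", [1, 1, 1]), outcome("b", [1, 1, 1])]
        assert precision_at_k(perfect, 3) == (1.0, 0.0)
        assert success_rate_at_k(perfect, 3) == (1.0, 0.0)
        empty = [outcome("a", [0, 0, 0])]
        assert precision_at_k(empty, 3) == (0.0, 0.0)
        assert success_rate_at_k(empty, 3) == (0.0, 0.0)

    def test_hand_evaluated_mixed_outcomes(self):
        rows = [outcome("a", [1, 1, 0]), outcome("b", [0, 0, 0])]
        p, psd = precision_at_k(rows, 3)
        assert p == pytest.approx(1 / 3)
        assert psd == pytest.approx(1 / 3)
        sr, srsd = success_rate_at_k([outcome("a", [1, 0, 0]), outcome("b", [0, 0, 0])], 3)
        assert sr == pytest.approx(0.5)
        assert srsd == pytest.approx(0.5)

    def test_late_hit_counts_for_success(self):
        sr, _ = success_rate_at_k([outcome("a", [0, 0, 1])], 3)
        assert sr == 1.0

    def test_precision1_equals_sr1_randomized(self, rng):
        for _ in range(50):
            rows = [
                outcome(f"r{i}", rng.integers(0, 2, size=5))
                for i in range(int(rng.integers(1, 12)))
            ]
            assert precision_at_k(rows, 1) == success_rate_at_k(rows, 1)

    def test_empty_or_short_outcomes_rejected(self):
        with pytest.raises(ValidationError):
            precision_at_k([], 1)
        with pytest.raises(ValidationError):
            success_rate_at_k([outcome("a", [1])], 2)


class TestTruePositive:
    def test_shared_and_unshared_codes(self):
        a = make_record("a", {"SNOMEDCT|1": 1}, {"E05.0"})
        b = make_record("b", {"SNOMEDCT|1": 1}, {"E05.0", "C34.1"})
        c = make_record("c", {"SNOMEDCT|1": 1}, {"C34.1"})
        assert is_true_positive(a, b, "full")
        assert not is_true_positive(a, c, "full")

    def test_granularity_changes_the_verdict(self):
        a = make_record("a", {"SNOMEDCT|1": 1}, {"A15.1"})
        b = make_record("b", {"SNOMEDCT|1": 1}, {"A15.0"})
        assert not is_true_positive(a, b, "full")
        assert is_true_positive(a, b, "category3")
        c = make_record("c", {"SNOMEDCT|1": 1}, {"C34.1"})
        d = make_record("d", {"SNOMEDCT|1": 1}, {"B18.1"})
        assert not is_true_positive(c, d, "chapter")

    def test_missing_diagnoses_rejected(self):
        a = make_record("a", {"SNOMEDCT|1": 1}, {"E05.0"})
        empty = make_record("b", {"SNOMEDCT|1": 1}, set())
        with pytest.raises(ValidationError):
            is_true_positive(a, empty)


class TestStratify:
    def test_occurrence_classes(self):
        records = []
        i = 0
        for code, count in [("C34.1", 11), ("B18.1", 2), ("E88.0", 1)]:
            for _ in range(count):
                i += 1
                records.append(make_record(f"P{i}", {"SNOMEDCT|1": 1}, {code}))
        strata = stratify(CaseBase(records=records))
        assert strata.prevalent == {"C34.1"}
        assert strata.infrequent == {"B18.1"}
        assert strata.singleton == {"E88.0"}
        assert strata.record_labels["P1"] == "prevalent"
        assert strata.record_labels["P12"] == "infrequent"
        assert strata.record_labels["P14"] == "singleton"

    def test_mixed_prevalence_record_goes_to_prevalent(self):
        records = [make_record(f"P{i}", {"SNOMEDCT|1": 1}, {"C34.1"}) for i in range(11)]
        records.append(make_record("MIX", {"SNOMEDCT|1": 1}, {"C34.1", "E88.0"}))
        strata = stratify(CaseBase(records=records))
        assert strata.record_labels["MIX"] == "prevalent"

    def test_class_sizes_30_12_6(self):
        from casematch.synthetic_data import case_base_from_diagnosis_counts, expanded_catalog

        cb = case_base_from_diagnosis_counts(expanded_catalog())
        strata = stratify(cb)
        assert strata.class_sizes() == (30, 12, 6)
        assert len(strata.counts) == 48


class TestLoocv:
    def test_hand_traced_three_record_base(self):
        """Records 1 and 2 are concept-identical and share a diagnosis;
        record 3 has disjoint concepts. Folds 1 and 2 retrieve each
        other (hit); record 3 is unqueryable after its fold's fit and
        counts as a miss, giving precision@1 = SR@1 = 2/3."""
        cb = CaseBase(records=[
            make_record("P1", {"SNOMEDCT|1": 1, "SNOMEDCT|2": 1}, {"B18.1"}),
            make_record("P2", {"SNOMEDCT|1": 1, "SNOMEDCT|2": 1}, {"B18.1"}),
            make_record("P3", {"SNOMEDCT|8": 1, "SNOMEDCT|9": 1}, {"B18.1"}),
        ])
        report = loocv(cb, VectorizerParams(), ks=[1])
        row = report.get(ALL, 1)
        assert row.precision == pytest.approx(2 / 3)
        assert row.success_rate == pytest.approx(2 / 3)
        assert report.n_skipped == 1

    def test_globally_shared_diagnosis_gives_perfect_scores(self, rng):
        records = []
        for i in range(12):
            concepts = {f"SNOMEDCT|{rng.integers(0, 6)}": 1, f"SNOMEDCT|{10 + i % 3}": 2}
            records.append(make_record(f"P{i:02d}", concepts, {"C34.1"}))
        report = loocv(CaseBase(records=records), VectorizerParams(), ks=[1, 3, 5])
        for k in (1, 3, 5):
            row = report.get("prevalent", k)
            assert row.precision == 1.0 and row.success_rate == 1.0

    def test_each_record_indexed_once_and_identities(self, rng):
        cb = random_case_base(rng, n_records=10)
        report = loocv(cb, VectorizerParams(), ks=[1, 3])
        ids = [o.index_id for o in report.outcomes]
        assert len(ids) == len(set(ids))
        row = report.get(ALL, 1)
        assert row.precision == row.success_rate

    def test_kmax_validation(self, rng):
        cb = random_case_base(rng, n_records=5)
        with pytest.raises(ValidationError):
            loocv(cb, VectorizerParams(), ks=[10])

    @pytest.mark.parametrize("binary,max_df,min_df", [(False, 1.0, 1), (True, 0.9, 1), (False, 0.8, 2)])
    def test_brute_force_oracle_equivalence(self, rng, binary, max_df, min_df):
        """Package LOOCV matches the independent dictionary-based
        re-implementation exactly on random small bases."""
        for _ in range(6):
            cb = random_case_base(rng, n_records=int(rng.integers(6, 13)), n_codes=3)
            params = VectorizerParams(binary=binary, max_df=max_df, min_df=min_df)
            try:
                report = loocv(cb, params, ks=[1, 3])
            except ValidationError:
                continue
            expected = bf_loocv_outcomes(
                cb.records, binary=binary, max_df=max_df, min_df=min_df, kmax=3
            )
            got = {o.index_id: (o.stratum, list(o.indicators), o.skipped) for o in report.outcomes}
            assert got == {pid: (s, ind, sk) for pid, s, ind, sk in expected}
            rows = [ind for _, _, ind, _ in expected]
            if rows:
                p, psd = bf_precision(rows, 1)
                row = report.get(ALL, 1)
                assert row.precision == pytest.approx(p, abs=1e-12)
                assert row.precision_sd == pytest.approx(psd, abs=1e-12)
                sr, srsd = bf_success_rate(rows, 1)
                assert row.success_rate == pytest.approx(sr, abs=1e-12)
                assert row.success_rate_sd == pytest.approx(srsd, abs=1e-12)


class TestRandomBaseline:
    def _shared_dx_base(self, n=8):
        return CaseBase(records=[
            make_record(f"P{i}", {f"SNOMEDCT|{i % 4}": 1, "SNOMEDCT|9": 1}, {"C34.1"})
            for i in range(n)
        ])

    def test_every_pair_matches_gives_precision_one(self):
        report = random_baseline(self._shared_dx_base(12), ks=[1, 3], seed=5)
        assert report.get("prevalent", 3).precision == 1.0

    def test_same_seed_reproduces_report(self, rng):
        cb = random_case_base(rng, n_records=10)
        a = random_baseline(cb, ks=[1, 3], seed=9)
        b = random_baseline(cb, ks=[1, 3], seed=9)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_matches_analytic_base_rate(self):
        """With a known fraction of diagnosis-sharing pairs, random
        top-1 precision lands within 3 Monte-Carlo SEs of it."""
        records = [
            make_record(f"A{i}", {"SNOMEDCT|1": 1, "SNOMEDCT|2": 1}, {"C34.1"}) for i in range(20)
        ] + [
            make_record(f"B{i}", {"SNOMEDCT|3": 1, "SNOMEDCT|4": 1}, {"E05.0"}) for i in range(20)
        ]
        cb = CaseBase(records=records)
        rho = random_match_base_rate(cb)
        assert rho == pytest.approx(19 / 39)
        report = random_baseline(cb, ks=[1], seed=123, repetitions=30)
        p = report.get(ALL, 1).precision
        se = np.sqrt(rho * (1 - rho) / (40 * 30))
        assert abs(p - rho) < 3 * se


class TestGridSearch:
    def test_grid_sizes(self):
        assert len(enumerate_grid("tfidf")) == 50
        assert len(enumerate_grid("tf")) == 50
        assert len(enumerate_grid("tfidf_sem")) == 200

    def test_single_point_grid_equals_direct_loocv(self, rng):
        cb = random_case_base(rng, n_records=10)
        grid = {"binary": [False], "max_df": [1.0], "min_df": [1]}
        table = grid_search(cb, mode="tfidf", grid=grid, ks=[1])
        direct = loocv(cb, VectorizerParams(), ks=[1]).get(ALL, 1)
        assert len(table) == 1
        assert table.loc[0, "precision_top1"] == pytest.approx(direct.precision)

    def test_noise_token_is_filtered_by_max_df(self):
        """A ubiquitous noise concept drowns the signal unless max_df
        removes it: the best filtered configuration must win."""
        rng = np.random.default_rng(7)
        records = []
        for i in range(24):
            # ubiquitous noise tokens with random counts dominate the
            # cosine unless max_df drops them; the diagnosis signal is
            # two low-count tokens per group
            dx = "C34.1" if i % 2 == 0 else "E05.0"
            concepts = {f"SNOMEDCT|noise{t}": int(rng.integers(1, 50)) for t in range(5)}
            concepts[f"SNOMEDCT|sig-{dx}"] = 1
            concepts[f"SNOMEDCT|sig2-{dx}"] = 1
            records.append(make_record(f"P{i:02d}", concepts, {dx}))
        cb = CaseBase(records=records)
        grid = {"binary": [False], "max_df": [1.0, 0.9], "min_df": [1]}
        table = grid_search(cb, mode="tfidf", grid=grid, ks=[1])
        best = table.iloc[0]
        assert best["max_df"] < 1.0
        filtered = table[table.max_df < 1.0].iloc[0]
        unfiltered = table[table.max_df == 1.0].iloc[0]
        assert filtered["precision_top1"] > unfiltered["precision_top1"]

    def test_deterministic_ordering(self, rng):
        cb = random_case_base(rng, n_records=8)
        grid = {"binary": [True, False], "max_df": [1.0, 0.9], "min_df": [1, 2]}
        a = grid_search(cb, mode="tfidf", grid=grid, ks=[1])
        b = grid_search(cb, mode="tfidf", grid=grid, ks=[1])
        assert a.equals(b)

    def test_default_grid_constant(self):
        assert DEFAULT_GRID["max_df"] == [1.0, 0.9, 0.8, 0.6, 0.4]
        assert DEFAULT_GRID["theta"] == [0.8, 0.85, 0.9, 0.95]
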