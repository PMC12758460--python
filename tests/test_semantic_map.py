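"""Embedding normalization: similarity matrix, θ-thresholded concept map."""

import numpy as np
import pytest

from casematch.data_model import CaseBase
from casematch.errors import ValidationError
from casematch.semantic_map import (
    ConceptMap,
    EmbeddingSet,
    apply_concept_map,
    build_concept_map,
    embed_concepts,
    similarity_matrix,
)
from casematch.synthetic_data import MockEmbeddingBackend, generate_mock_embeddings

from conftest import make_record


def embeddings_from(vectors: dict[str, list[float]]) -> EmbeddingSet:
    names = sorted(vectors)
    return EmbeddingSet(names=names, vectors=np.array([vectors[n] for n in names], float))


class TestEmbedConcepts:
    def test_mock_backend_dimension_and_determinism(self):
        backend = MockEmbeddingBackend(seed=3)
        e1 = embed_concepts(["cough", "fever", "cough"], backend)
        e2 = embed_concepts(["cough", "fever"], backend)
        assert e1.dimension == 768
        assert e1.names == ["cough", "fever"]  # deduplicated, sorted
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_empty_name_rejected(self):
        with pytest.raises(ValidationError):
            embed_concepts(["cough", ""], MockEmbeddingBackend())

    def test_backend_failure_is_annotated(self):
        class Broken:
            name = "broken"

            def __call__(self, names):
                raise RuntimeError("boom")

        with pytest.raises(ValidationError, match="broken"):
            embed_concepts(["cough"], Broken())

    def test_cache_round_trip(self, tmp_path):
        emb = embed_concepts(["cough", "fever"], MockEmbeddingBackend(seed=1))
        emb.save(tmp_path / "emb")
        back = EmbeddingSet.load(tmp_path / "emb")
        assert back.names == emb.names
        np.testing.assert_array_equal(back.vectors, emb.vectors)


class TestSimilarityMatrix:
    def test_hand_computed_cosines(self):
        emb = embeddings_from({"a": [1, 1, 0], "b": [1, 0, 0], "c": [0, 0, 1]})
        s = similarity_matrix(emb)
        i, j, k = (s.names.index(n) for n in "abc")
        assert s.values[i, j] == pytest.approx(1 / np.sqrt(2))
        assert s.values[i, k] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(s.values), 1.0)
        np.testing.assert_allclose(s.values, s.values.T)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            embeddings_from({"a": [0, 0, 0], "b": [1, 0, 0]})


class TestBuildConceptMap:
    def test_synonym_pair_collapses_to_frequent_name(self):
        emb = embeddings_from({"cough": [1, 0.01], "coughing": [1, 0.0], "fever": [0, 1]})
        cmap = build_concept_map(similarity_matrix(emb), 0.9, {"cough": 10, "coughing": 3})
        assert cmap("cough") == "cough"
        assert cmap("coughing") == "cough"
        assert cmap("fever") == "fever"
        assert cmap.n_replaced == 1

    def test_high_threshold_gives_identity(self):
        emb = embeddings_from({"a": [1, 0.2], "b": [1, 0.0]})
        cmap = build_concept_map(similarity_matrix(emb), 0.999)
        assert cmap.n_replaced == 0

    def test_chain_merges_into_one_component(self):
        """a~b and b~c above θ pull a,c together even though S_ac < θ."""
        import networkx as nx

        angles = {"a": 0.0, "b": 0.28, "c": 0.56}  # cos(0.28)≈0.961, cos(0.56)≈0.847
        emb = embeddings_from({n: [np.cos(t), np.sin(t)] for n, t in angles.items()})
        s = similarity_matrix(emb)
        theta = 0.95
        cmap = build_concept_map(s, theta)
        assert cmap("a") == cmap("b") == cmap("c")
        # independent component oracle
        g = nx.Graph()
        g.add_nodes_from(s.names)
        for i, a in enumerate(s.names):
            for j, b in enumerate(s.names):
                if i < j and s.values[i, j] >= theta:
                    g.add_edge(a, b)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got = {}
        for name in s.names:
            got.setdefault(cmap(name), set()).add(name)
        assert {frozenset(v) for v in got.values()} == expected

    def test_ties_broken_lexicographically(self):
        emb = embeddings_from({"zeta": [1, 0], "alpha": [1, 0]})
        cmap = build_concept_map(similarity_matrix(emb), 0.9)
        assert cmap("zeta") == "alpha"

    def test_map_is_idempotent_and_reps_self_map(self):
        emb = generate_mock_embeddings([["a", "b"], ["c", "d"]], ["a", "b", "c", "d", "e"], seed=2)
        cmap = build_concept_map(similarity_matrix(emb), 0.95)
        for name in emb.names:
            assert cmap(cmap(name)) == cmap(name)
        assert cmap(cmap.mapping[name]) == cmap.mapping[name]

    def test_raising_theta_never_merges_more(self):
        emb = generate_mock_embeddings([["a", "b", "c"]], list("abcdefgh"), seed=5)
        sizes = [build_concept_map(similarity_matrix(emb), t).n_replaced for t in (0.8, 0.9, 0.95, 0.999999)]
        assert sizes == sorted(sizes, reverse=True)

    def test_csv_round_trip(self, tmp_path):
        cmap = ConceptMap(theta=0.9, mapping={"coughing": "cough", "cough": "cough"})
        cmap.to_csv(tmp_path / "map.csv")
        back = ConceptMap.from_csv(tmp_path / "map.csv", 0.9)
        assert back.mapping == cmap.mapping


class TestApplyConceptMap:
    def _base(self):
        return CaseBase(
            records=[
                make_record("P1", {"SNOMEDCT|1": 1, "SNOMEDCT|2": 2}, {"B18.1"}),
                make_record("P2", {"SNOMEDCT|2": 1, "LOINC|9|above": 1, "LOINC|8|below": 1}, {"C34.1"}),
            ],
            concept_names={
                "SNOMEDCT|1": "cough",
                "SNOMEDCT|2": "coughing",
                "LOINC|9": "alt high",
                "LOINC|8": "alt low",
            },
        )

    def test_counts_sum_under_merge(self):
        cb = self._base()
        cmap = ConceptMap(theta=0.9, mapping={"coughing": "cough", "cough": "cough"})
        out, n_replaced = apply_concept_map(cb, cmap)
        assert out.get("P1").concepts == {"SNOMEDCT|1": 3}
        assert out.get("P2").concepts["SNOMEDCT|1"] == 1
        assert n_replaced == 1

    def test_relation_preserved_on_rewrite(self):
        cb = self._base()
        cmap = ConceptMap(theta=0.9, mapping={"alt low": "alt high", "alt high": "alt high"})
        out, _ = apply_concept_map(cb, cmap)
        # 'below' token rewritten onto the representative's base, keeping its relation
        assert out.get("P2").concepts == {"SNOMEDCT|2": 1, "LOINC|9|above": 1, "LOINC|9|below": 1}

    def test_identity_map_is_noop_and_idempotent(self):
        cb = self._base()
        identity = ConceptMap(theta=0.95, mapping={})
        out, n = apply_concept_map(cb, identity)
        assert n == 0
        assert all(out.get(r.person_id).concepts == r.concepts for r in cb.records)
        cmap = ConceptMap(theta=0.9, mapping={"coughing": "cough", "cough": "cough"})
        once, _ = apply_concept_map(cb, cmap)
        twice, n2 = apply_concept_map(once, cmap)
        assert n2 == 0
        assert all(twice.get(r.person_id).concepts == r.concepts for r in once.records)

    def test_total_mentions_conserved(self):
        cb = self._base()
        cmap = ConceptMap(theta=0.9, mapping={"coughing": "cough", "cough": "cough",
                                              "alt low": "alt high", "alt high": "alt high"})
        out, _ = apply_concept_map(cb, cmap)
        for r in cb.records:
            assert out.get(r.person_id).total_mentions == r.total_mentions
            assert out.get(r.person_id).distinct_concepts <= r.distinct_concepts


def test_planted_partition_recovery():
    """With mock embeddings, θ=0.95 recovers exactly the planted synonym
    partition (in-group cosines ≥ 0.99, cross-group far below 0.5)."""
    partition = [["term a", "term b", "term c"], ["term x", "term y"]]
    names = [n for grp in partition for n in grp] + [f"solo {i}" for i in range(10)]
    emb = generate_mock_embeddings(partition, names, seed=11)
    s = similarity_matrix(emb)
    cmap = build_concept_map(s, 0.95)
    groups: dict[str, set] = {}
    for name in names:
        groups.setdefault(cmap(name), set()).add(name)
    non_trivial = {frozenset(g) for g in groups.values() if len(g) > 1}
    assert non_trivial == {frozenset(g) for g in partition}
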