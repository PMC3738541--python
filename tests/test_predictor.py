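"""Neighbor selection, subscores, relevance scores, and candidate ranking."""

import math

import pytest

from _utils import naive_scores, random_similarity_matrix
from hdmp.errors import NoLabelsError, ParameterError
from hdmp.grouping import GroupCatalog
from hdmp.mirna_similarity import AssociationSet, MirnaSimilarityMatrix
from hdmp.predictor import (
    PredictionConfig,
    neighbor_subscore,
    rank_candidates,
    relevance_score,
    select_neighbors,
)


def tiny_matrix(sims):
    """Matrix over the ids appearing in ``sims`` (query 'q' vs others)."""
    ids = tuple(sorted({"q", *sims}))

    def fn(u, v):
        if "q" in (u, v):
            other = v if u == "q" else u
            return sims[other]
        return 0.05

    return MirnaSimilarityMatrix.from_function(ids, fn)


class TestSelectNeighbors:
    def test_all_others_when_k_exceeds_pool(self):
        matrix = tiny_matrix({"a": 0.3, "b": 0.6})
        neighbors = select_neighbors("q", matrix, k=10)
        assert [m for m, _ in neighbors] == ["b", "a"]

    def test_top_k_by_similarity(self):
        matrix = tiny_matrix({"a": 0.3, "b": 0.6, "c": 0.5})
        neighbors = select_neighbors("q", matrix, k=2)
        assert [m for m, _ in neighbors] == ["b", "c"]

    def test_ties_break_by_ascending_id(self):
        matrix = tiny_matrix({"b": 0.5, "c": 0.5, "d": 0.4})
        neighbors = select_neighbors("q", matrix, k=2)
        assert [m for m, _ in neighbors] == ["b", "c"]

    def test_query_never_among_neighbors(self, rng):
        matrix = random_similarity_matrix(rng, [f"m{i}" for i in range(8)])
        for u in matrix.ids:
            assert u not in [m for m, _ in select_neighbors(u, matrix, k=7)]

    def test_invalid_k_rejected(self):
        matrix = tiny_matrix({"a": 0.3})
        with pytest.raises(ParameterError):
            select_neighbors("q", matrix, k=0)


class TestNeighborSubscore:
    def test_unlabeled_neighbor_scores_zero(self, paper):
        sc = paper.scenario
        config = PredictionConfig(k=sc.k)
        assert neighbor_subscore(
            sc.query, "mir-02", sc.disease, sc.labels, sc.matrix,
            sc.families, sc.clusters, config,
        ) == 0.0

    def test_shared_family_multiplies_weight(self, paper):
        sc = paper.scenario
        config = PredictionConfig(k=sc.k)
        # MS = 0.6; family of 10 with 6 labeled -> w = 1.15
        assert neighbor_subscore(
            sc.query, "mir-20", sc.disease, sc.labels, sc.matrix,
            sc.families, sc.clusters, config,
        ) == pytest.approx(0.69)

    def test_labeled_neighbor_without_shared_group_is_plain_similarity(self, paper):
        sc = paper.scenario
        config = PredictionConfig(k=sc.k)
        assert neighbor_subscore(
            sc.query, "mir-05", sc.disease, sc.labels, sc.matrix,
            sc.families, sc.clusters, config,
        ) == pytest.approx(0.6)

    def test_family_and_cluster_weights_multiply(self):
        labels = AssociationSet([("v", "d"), ("x1", "d"), ("x2", "d")])
        matrix = tiny_matrix({"v": 0.6, "x1": 0.1, "x2": 0.1})
        # family {q, v, x1, x2, u5}: rate 3/5, alpha 3 -> w_f = 1.2
        families = GroupCatalog(
            kind="family", groups={"f": {"q", "v", "x1", "x2", "u5"}}
        )
        # cluster {q, v, x1, x2}: rate 3/4 -> with beta 7.5, w_g = 1.1
        clusters = GroupCatalog(
            kind="cluster", groups={"c": {"q", "v", "x1", "x2"}}
        )
        config = PredictionConfig(k=3, alpha=3.0, beta=7.5)
        score = neighbor_subscore(
            "q", "v", "d", labels, matrix, families, clusters, config
        )
        assert score == pytest.approx(0.6 * 1.2 * 1.1)


class TestRelevanceScore:
    def test_worked_example_score(self, paper):
        sc = paper.scenario
        score = relevance_score(
            sc.query, sc.disease, sc.labels, sc.matrix,
            sc.families, sc.clusters, PredictionConfig(k=sc.k),
        )
        assert score == pytest.approx(1.99)

    def test_no_labeled_neighbors_scores_zero(self):
        labels = AssociationSet([("far", "d")])
        matrix = tiny_matrix({"a": 0.9, "b": 0.8, "far": 0.1})
        score = relevance_score("q", "d", labels, matrix, config=PredictionConfig(k=2))
        assert score == 0.0

    def test_single_labeled_neighbor_reduces_to_its_similarity(self):
        labels = AssociationSet([("a", "d")])
        matrix = tiny_matrix({"a": 0.37, "b": 0.2})
        score = relevance_score("q", "d", labels, matrix, config=PredictionConfig(k=2))
        assert score == pytest.approx(0.37)

    def test_adding_a_labeled_neighbor_never_decreases_score(self, rng):
        matrix = random_similarity_matrix(rng, [f"m{i}" for i in range(8)])
        config = PredictionConfig(k=5)
        labels = AssociationSet([("m1", "d")])
        previous = relevance_score("m0", "d", labels, matrix, config=config)
        for m in ("m2", "m3", "m4", "m5"):
            labels = AssociationSet(labels.pairs | {(m, "d")})
            current = relevance_score("m0", "d", labels, matrix, config=config)
            assert current >= previous - 1e-12
            previous = current

    def test_stronger_group_boost_never_decreases_score(self, paper):
        sc = paper.scenario
        scores = [
            relevance_score(
                sc.query, sc.disease, sc.labels, sc.matrix, sc.families,
                sc.clusters, PredictionConfig(k=sc.k, alpha=alpha),
            )
            for alpha in (8.0, 4.0, 2.0, 1.0)  # decreasing alpha = stronger boost
        ]
        assert scores == sorted(scores)

    def test_unweighted_full_pool_reduces_to_similarity_sum(self, rng):
        matrix = random_similarity_matrix(rng, [f"m{i}" for i in range(7)])
        labels = AssociationSet([("m2", "d"), ("m4", "d"), ("m5", "d")])
        config = PredictionConfig(k=len(matrix) - 1, alpha=math.inf, beta=math.inf)
        score = relevance_score("m0", "d", labels, matrix, config=config)
        expected = sum(matrix.sim("m0", m) for m in ("m2", "m4", "m5"))
        assert score == pytest.approx(expected)


class TestRankCandidates:
    def test_single_candidate_gets_rank_one(self):
        labels = AssociationSet([("a", "d")])
        matrix = tiny_matrix({"a": 0.0, "b": 0.0})
        ranked = rank_candidates("d", labels, matrix, pool=["b"])
        [(mirna, _, rank)] = ranked.entries
        assert (mirna, rank) == ("b", 1)

    def test_scored_above_unscored(self, paper):
        sc = paper.scenario
        ranked = rank_candidates(
            sc.disease, sc.labels, sc.matrix, sc.families, sc.clusters,
            PredictionConfig(k=sc.k), pool=["mir-01", "mir-16"],
        )
        assert ranked.rank_of("mir-01") == 1
        assert ranked.score_of("mir-01") == pytest.approx(1.99)
        assert ranked.rank_of("mir-16") == 2

    def test_equal_scores_rank_by_ascending_id(self):
        labels = AssociationSet([("z", "d")])
        matrix = tiny_matrix({"b": 0.0, "a": 0.0, "z": 0.0})
        ranked = rank_candidates("d", labels, matrix, pool=["b", "a"])
        assert [m for m, _, _ in ranked.entries] == ["a", "b"]
        assert [r for _, _, r in ranked.entries] == [1, 2]

    def test_default_pool_is_the_unlabeled_complement(self, paper):
        sc = paper.scenario
        ranked = rank_candidates(
            sc.disease, sc.labels, sc.matrix, sc.families, sc.clusters,
            PredictionConfig(k=sc.k),
        )
        pool = {m for m, _, _ in ranked.entries}
        assert pool == set(sc.matrix.ids) - sc.labels.labeled(sc.disease)

    def test_disease_without_labels_rejected(self):
        matrix = tiny_matrix({"a": 0.5})
        with pytest.raises(NoLabelsError):
            rank_candidates("d", AssociationSet([("a", "other")]), matrix)

    def test_matches_definition_level_reference(self, rng):
        for _ in range(10):
            ids = [f"m{i}" for i in range(10)]
            matrix = random_similarity_matrix(rng, ids)
            labels = AssociationSet(
                [(m, "d") for m in ids if rng.random() < 0.4] + [("m0", "d")]
            )
            families = GroupCatalog(
                kind="family",
                groups={"f1": set(ids[:4]), "f2": set(ids[4:7])},
            )
            clusters = GroupCatalog(
                kind="cluster", groups={"c1": set(ids[2:6])}
            )
            config = PredictionConfig(k=int(rng.integers(1, 9)))
            pool = labels.unlabeled("d", universe=ids)
            ranked = rank_candidates(
                "d", labels, matrix, families, clusters, config, pool=pool
            )
            expected = naive_scores(
                "d", labels, matrix, families, clusters, config, pool
            )
            for m, score, _ in ranked.entries:
                assert score == pytest.approx(expected[m], abs=1e-12)
            order = sorted(expected.items(), key=lambda p: (-p[1], p[0]))
            assert [m for m, _, _ in ranked.entries] == [m for m, _ in order]
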