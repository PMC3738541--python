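"""Fold construction, ROC/AUC, cross-validation and hold-out validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _utils import mann_whitney_auc, random_similarity_matrix
from hdmp.errors import EmptyInputError, InsufficientLabelsError, ParameterError
from hdmp.evaluation import (
    evaluate_cv,
    evaluate_disease_cv,
    make_folds,
    roc_auc,
    roc_from_scores,
    updated_dataset_validation,
)
from hdmp.fixtures import SyntheticSpec, generate_corpus, null_corpus
from hdmp.grouping import GroupCatalog
from hdmp.mirna_similarity import AssociationSet, MirnaSimilarityMatrix
from hdmp.predictor import PredictionConfig


class TestMakeFolds:
    def test_even_split(self):
        split = make_folds([f"m{i}" for i in range(10)], n_folds=5, seed=3)
        assert sorted(len(f) for f in split.folds) == [2, 2, 2, 2, 2]

    def test_remainder_spreads_by_one(self):
        split = make_folds([f"m{i}" for i in range(11)], n_folds=5, seed=3)
        assert sorted(len(f) for f in split.folds) == [2, 2, 2, 2, 3]

    def test_partition_covers_all_labels_disjointly(self):
        members = [f"m{i}" for i in range(13)]
        split = make_folds(members, n_folds=5, seed=9)
        seen = [m for fold in split.folds for m in fold]
        assert sorted(seen) == sorted(members)
        assert len(set(seen)) == len(seen)

    def test_same_seed_reproduces_partition(self):
        members = [f"m{i}" for i in range(12)]
        assert make_folds(members, 5, seed=7) == make_folds(members, 5, seed=7)
        assert make_folds(members, 5, seed=7) != make_folds(members, 5, seed=8)

    def test_too_few_labels_rejected(self):
        with pytest.raises(InsufficientLabelsError):
            make_folds(["m1", "m2"], n_folds=5, seed=0)


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([1, 2, 3], pool_size=10).area == 1.0

    def test_inverted_ranking(self):
        assert roc_auc([8, 9, 10], pool_size=10).area == 0.0

    def test_single_positive_closed_form(self):
        for n in (5, 9, 12):
            for r in range(1, n + 1):
                if n - 1 == 0:
                    continue
                curve = roc_auc([r], pool_size=n)
                assert curve.area == pytest.approx((n - r) / (n - 1))

    def test_curve_runs_from_origin_to_corner(self):
        curve = roc_auc([2, 5], pool_size=8)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_no_positives_rejected(self):
        with pytest.raises(EmptyInputError):
            roc_auc([], pool_size=5)

    def test_out_of_pool_rank_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([6], pool_size=5)

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(
        scores=st.lists(
            st.integers(min_value=0, max_value=4), min_size=2, max_size=12
        ),
        n_pos=st.integers(min_value=1, max_value=11),
    )
    def test_area_equals_pair_counting_statistic(self, scores, n_pos):
        """Trapezoidal AUC equals the Mann-Whitney statistic, ties = 1/2."""
        if n_pos >= len(scores):
            n_pos = len(scores) - 1
        pos, neg = scores[:n_pos], scores[n_pos:]
        curve = roc_from_scores(pos, neg)
        assert curve.area == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-12)


def planted_instance(n_labeled=10, n_other=20, seed=0):
    """Labeled miRNAs mutually similar, everything else dissimilar noise."""
    rng = np.random.default_rng(seed)
    labeled = [f"pos{i:02d}" for i in range(n_labeled)]
    others = [f"neg{i:02d}" for i in range(n_other)]
    ids = tuple(sorted(labeled + others))
    in_group = set(labeled)

    def sim(u, v):
        if u in in_group and v in in_group:
            return 0.8 + 0.15 * rng.random()
        return 0.05 * rng.random()

    matrix = MirnaSimilarityMatrix.from_function(ids, sim)
    labels = AssociationSet(
        [(m, "dx") for m in labeled] + [(m, "other") for m in others]
    )
    return matrix, labels


class TestEvaluateDiseaseCv:
    def test_planted_signal_recovers_high_auc(self):
        aucs = []
        for seed in range(20):
            matrix, labels = planted_instance(seed=seed)
            result = evaluate_disease_cv(
                "dx", labels, matrix, config=PredictionConfig(k=5), seed=seed
            )
            aucs.append(result.mean_auc)
        assert np.mean(aucs) >= 0.95

    def test_random_labels_on_noise_sit_near_chance(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            ids = [f"m{i:02d}" for i in range(30)]
            matrix = random_similarity_matrix(rng, ids)
            chosen = rng.choice(len(ids), size=10, replace=False)
            labels = AssociationSet(
                [(ids[i], "dx") for i in chosen] + [(m, "bg") for m in ids]
            )
            result = evaluate_disease_cv(
                "dx", labels, matrix, config=PredictionConfig(k=5), seed=seed
            )
            aucs.append(result.mean_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_same_seed_reproduces_fold_aucs(self):
        matrix, labels = planted_instance(seed=4)
        first = evaluate_disease_cv("dx", labels, matrix, seed=11)
        second = evaluate_disease_cv("dx", labels, matrix, seed=11)
        assert first == second

    def test_training_positives_never_enter_the_pool(self, monkeypatch):
        import hdmp.evaluation as evaluation_module
        from hdmp.predictor import rank_candidates as real_rank

        matrix, labels = planted_instance(n_labeled=6, n_other=8, seed=2)
        observed = []

        def spy(disease, training, fold_matrix, *args, **kwargs):
            observed.append((set(kwargs["pool"]), training.labeled(disease)))
            return real_rank(disease, training, fold_matrix, *args, **kwargs)

        monkeypatch.setattr(evaluation_module, "rank_candidates", spy)
        evaluate_disease_cv("dx", labels, matrix, n_folds=3, seed=0)
        assert len(observed) == 3
        for pool, training_positives in observed:
            assert not (pool & training_positives)

    def test_infinite_factors_match_groupless_run(self):
        matrix, labels = planted_instance(seed=6)
        families = GroupCatalog(kind="family", groups={"f": {"pos00", "neg00"}})
        clusters = GroupCatalog(kind="cluster", groups={"c": {"pos01", "neg01"}})
        weightless = PredictionConfig(k=5, alpha=math.inf, beta=math.inf)
        with_groups = evaluate_disease_cv(
            "dx", labels, matrix, families, clusters, weightless, seed=3
        )
        without_groups = evaluate_disease_cv(
            "dx", labels, matrix, None, None, PredictionConfig(k=5), seed=3
        )
        assert with_groups.fold_aucs == without_groups.fold_aucs


class TestEvaluateCv:
    def test_report_skips_small_diseases_and_averages_unweighted(self):
        matrix, labels = planted_instance(n_labeled=8, n_other=10)
        labels = AssociationSet(labels.pairs | {("neg00", "rare")})
        report = evaluate_cv(
            labels, matrix, min_labels=5, n_folds=4, seed=0,
            diseases=["dx", "rare"],
        )
        assert [r.disease for r in report.results] == ["dx"]
        assert dict(report.skipped)["rare"].startswith("only 1")
        assert report.grand_mean == pytest.approx(
            np.mean([r.mean_auc for r in report.results])
        )

    def test_dataframe_contains_fold_and_summary_rows(self):
        matrix, labels = planted_instance(n_labeled=8, n_other=10)
        report = evaluate_cv(labels, matrix, min_labels=5, n_folds=4, seed=0)
        frame = report.to_dataframe()
        assert set(frame.columns) == {"disease", "fold", "auc"}
        assert (frame["fold"] == "mean").sum() >= 2  # per-disease + grand


class TestUpdatedDatasetValidation:
    def test_disease_without_additions_is_skipped(self):
        matrix, labels = planted_instance(n_labeled=6, n_other=6)
        report = updated_dataset_validation(
            labels, labels, matrix, min_labels=3
        )
        assert report.results == ()
        assert dict(report.skipped)["dx"] == "no new additions"

    def test_single_top_ranked_addition_gives_auc_one(self):
        labeled = [f"pos{i}" for i in range(4)]
        ids = tuple(sorted(labeled + ["star", "dud1", "dud2"]))

        def sim(u, v):
            if "star" in (u, v) and (u in labeled or v in labeled):
                return 0.9
            if u in labeled and v in labeled:
                return 0.9
            return 0.01

        matrix = MirnaSimilarityMatrix.from_function(ids, sim)
        old = AssociationSet(
            [(m, "dx") for m in labeled] + [(m, "bg") for m in ids]
        )
        new = AssociationSet(old.pairs | {("star", "dx")})
        report = updated_dataset_validation(
            old, new, matrix, config=PredictionConfig(k=3), min_labels=2
        )
        [result] = report.results
        assert result.fold_aucs == (1.0,)

    def test_planted_temporal_split_beats_null(self):
        spec = SyntheticSpec(
            n_mirnas=32, n_modules=4, family_size=5, cluster_size=5
        )
        planted_aucs, null_aucs = [], []
        for seed in range(20):
            for corpus, sink in (
                (generate_corpus(SyntheticSpec(
                    n_mirnas=32, n_modules=4, family_size=5, cluster_size=5,
                    seed=seed)), planted_aucs),
                (null_corpus(SyntheticSpec(
                    n_mirnas=32, n_modules=4, family_size=5, cluster_size=5,
                    p_in=0.25, p_out=0.25, seed=seed)), null_aucs),
            ):
                assoc = corpus.associations
                rng = np.random.default_rng(seed)
                # hide 30% of each disease's labels as the "new" additions
                hidden = []
                for d in assoc.diseases:
                    members = sorted(assoc.labeled(d))
                    n_hide = len(members) // 3
                    if n_hide and len(members) - n_hide >= 2:
                        chosen = rng.choice(len(members), n_hide, replace=False)
                        hidden.extend((members[i], d) for i in chosen)
                old = assoc.without(hidden)
                from hdmp.disease_similarity import PairwiseDiseaseSimilarity
                from hdmp.mirna_similarity import build_similarity_matrix

                pairwise = PairwiseDiseaseSimilarity(corpus.ontology)
                matrix = build_similarity_matrix(old, pairwise)
                report = updated_dataset_validation(
                    old, assoc, matrix,
                    corpus.families.restrict_to(old.mirnas),
                    corpus.clusters.restrict_to(old.mirnas),
                    min_labels=4,
                )
                if report.grand_mean is not None:
                    sink.append(report.grand_mean)
        assert np.mean(planted_aucs) > np.mean(null_aucs) + 0.1
        assert np.mean(planted_aucs) > 0.7
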