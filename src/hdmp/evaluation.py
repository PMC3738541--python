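"""Cross-validation and temporal hold-out evaluation with ROC/AUC.

Per-disease 5-fold cross-validation hides one fifth of a disease's labeled
miRNAs per fold, rebuilds everything the hidden labels could influence
(the affected similarity rows and all group weights), ranks a candidate
pool made of the unlabeled miRNAs plus the hidden positives, and measures
how highly the hidden positives rank via the area under the ROC curve.
AUC is computed rank-based (equivalently the Mann-Whitney pair statistic,
with tied scores counted 1/2), so it is deterministic and threshold-free.

The temporal hold-out ("updated dataset") validation instead trains on an
older association snapshot and treats associations added in a newer
snapshot as the positives to recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import EmptyInputError, InsufficientLabelsError, ParameterError
from .grouping import GroupCatalog
from .mirna_similarity import (
    AssociationSet,
    MirnaSimilarityMatrix,
    update_similarity_rows,
)
from .predictor import PredictionConfig, rank_candidates

__all__ = [
    "FoldSplit",
    "RocCurve",
    "DiseaseResult",
    "EvaluationReport",
    "make_folds",
    "roc_from_scores",
    "roc_auc",
    "evaluate_disease_cv",
    "evaluate_cv",
    "updated_dataset_validation",
    "sweep_parameter",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_LABELS = 60  # headline eligibility: diseases with >= 60 labels


@dataclass(frozen=True)
class FoldSplit:
    """A seeded partition of one disease's labeled miRNAs into n folds
    whose sizes differ by at most one."""

    disease: Optional[str]
    folds: Tuple[Tuple[str, ...], ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve as (FPR, TPR) points from (0,0) to (1,1), plus its
    trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    area: float


@dataclass(frozen=True)
class DiseaseResult:
    """Per-disease evaluation outcome: one AUC per fold (a single entry
    for the hold-out validation)."""

    disease: str
    fold_aucs: Tuple[float, ...]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass(frozen=True)
class EvaluationReport:
    """Evaluation results over many diseases.

    The grand mean is the unweighted mean of per-disease mean AUCs, so
    diseases with many labels do not dominate it.
    """

    results: Tuple[DiseaseResult, ...]
    skipped: Tuple[Tuple[str, str], ...] = ()
    config: PredictionConfig = field(default_factory=PredictionConfig)

    @property
    def per_disease_mean(self) -> Dict[str, float]:
        return {r.disease: r.mean_auc for r in self.results}

    @property
    def grand_mean(self) -> Optional[float]:
        if not self.results:
            return None
        return float(np.mean([r.mean_auc for r in self.results]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for result in self.results:
            for fold, auc in enumerate(result.fold_aucs, start=1):
                rows.append((result.disease, fold, auc))
            rows.append((result.disease, "mean", result.mean_auc))
        if self.grand_mean is not None:
            rows.append(("ALL", "mean", self.grand_mean))
        for disease, reason in self.skipped:
            rows.append((disease, "skipped", reason))
        return pd.DataFrame(rows, columns=["disease", "fold", "auc"])


def make_folds(
    labeled: Iterable[str],
    n_folds: int = 5,
    seed: int = 0,
    disease: Optional[str] = None,
) -> FoldSplit:
    """Seeded shuffle followed by round-robin assignment: reproducible, and
    fold sizes differ by at most one."""
    members = sorted(labeled)
    if n_folds < 2:
        raise ParameterError(f"need at least 2 folds, got {n_folds}")
    if len(members) < n_folds:
        raise InsufficientLabelsError(
            f"{len(members)} labeled miRNAs cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(members))
    shuffled = [members[i] for i in order]
    folds = tuple(tuple(shuffled[i::n_folds]) for i in range(n_folds))
    return FoldSplit(disease=disease, folds=folds, seed=seed)


def roc_from_scores(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> RocCurve:
    """ROC curve and AUC from raw candidate scores.

    The area equals the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs ordered correctly, ties counted 1/2.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0:
        raise EmptyInputError("ROC curve undefined without positives")
    if neg.size == 0:
        raise EmptyInputError("ROC curve undefined without negatives")
    y_true = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    y_score = np.concatenate([pos, neg])
    fpr, tpr, _ = roc_curve(y_true, y_score, drop_intermediate=False)
    area = float(roc_auc_score(y_true, y_score))
    return RocCurve(fpr=fpr, tpr=tpr, area=area)


def roc_auc(positive_ranks: Sequence[int], pool_size: int) -> RocCurve:
    """ROC curve from the 1-based ranks of the positives in a candidate
    pool; all non-positive ranks are negatives.  Sweeping the rank cutoff
    yields sensitivity (positives above the cutoff) against 1-specificity
    (negatives above the cutoff)."""
    ranks = sorted(int(r) for r in positive_ranks)
    if not ranks:
        raise EmptyInputError("ROC curve undefined without positives")
    if len(set(ranks)) != len(ranks):
        raise ParameterError("positive ranks must be distinct")
    if ranks[0] < 1 or ranks[-1] > pool_size:
        raise ParameterError(
            f"ranks {ranks} outside pool of size {pool_size}"
        )
    if len(ranks) >= pool_size:
        raise EmptyInputError("ROC curve undefined without negatives")
    positives = set(ranks)
    pos_scores = [pool_size - r for r in ranks]
    neg_scores = [
        pool_size - r for r in range(1, pool_size + 1) if r not in positives
    ]
    return roc_from_scores(pos_scores, neg_scores)


def evaluate_disease_cv(
    disease: str,
    associations: AssociationSet,
    matrix: MirnaSimilarityMatrix,
    families: Optional[GroupCatalog] = None,
    clusters: Optional[GroupCatalog] = None,
    config: Optional[PredictionConfig] = None,
    n_folds: int = 5,
    seed: int = 0,
    disease_sim: Optional[Callable[[str, str], float]] = None,
) -> DiseaseResult:
    """n-fold cross-validation of one disease.

    Per fold: the held-out (miRNA, disease) labels are removed from the
    association set, the similarity rows of the held-out miRNAs are
    recomputed from the reduced set when ``disease_sim`` is given (so the
    hidden labels cannot leak through the matrix), group weights follow
    the training labels automatically, and the pool of unlabeled miRNAs
    plus held-out positives is ranked.  The fold AUC compares held-out
    scores against the scores of the always-unlabeled miRNAs.
    """
    if config is None:
        config = PredictionConfig()
    labeled = associations.labeled(disease)
    split = make_folds(labeled, n_folds=n_folds, seed=seed, disease=disease)
    negatives = associations.unlabeled(disease, universe=matrix.ids)
    aucs: List[float] = []
    for fold in split.folds:
        held_out = sorted(fold)
        training = associations.without((m, disease) for m in held_out)
        if disease_sim is not None:
            fold_matrix = update_similarity_rows(
                matrix, training, held_out, disease_sim
            )
        else:
            fold_matrix = matrix
        pool = list(negatives) + held_out
        ranked = rank_candidates(
            disease, training, fold_matrix, families, clusters, config, pool=pool
        )
        scores = {m: s for m, s, _ in ranked.entries}
        curve = roc_from_scores(
            [scores[m] for m in held_out], [scores[m] for m in negatives]
        )
        aucs.append(curve.area)
    return DiseaseResult(disease=disease, fold_aucs=tuple(aucs))


def evaluate_cv(
    associations: AssociationSet,
    matrix: MirnaSimilarityMatrix,
    families: Optional[GroupCatalog] = None,
    clusters: Optional[GroupCatalog] = None,
    config: Optional[PredictionConfig] = None,
    min_labels: int = DEFAULT_MIN_LABELS,
    n_folds: int = 5,
    seed: int = 0,
    diseases: Optional[Iterable[str]] = None,
    disease_sim: Optional[Callable[[str, str], float]] = None,
) -> EvaluationReport:
    """Cross-validate every eligible disease (>= ``min_labels`` labeled
    miRNAs) and aggregate into an :class:`EvaluationReport`.  Ineligible
    diseases are reported as skipped, not errors."""
    if config is None:
        config = PredictionConfig()
    targets = tuple(diseases) if diseases is not None else associations.diseases
    results: List[DiseaseResult] = []
    skipped: List[Tuple[str, str]] = []
    for disease in targets:
        n_labeled = len(associations.labeled(disease))
        if n_labeled < max(min_labels, n_folds):
            skipped.append(
                (disease, f"only {n_labeled} labeled miRNAs")
            )
            continue
        results.append(
            evaluate_disease_cv(
                disease,
                associations,
                matrix,
                families,
                clusters,
                config,
                n_folds=n_folds,
                seed=seed,
                disease_sim=disease_sim,
            )
        )
    return EvaluationReport(
        results=tuple(results), skipped=tuple(skipped), config=config
    )


def updated_dataset_validation(
    old: AssociationSet,
    new: AssociationSet,
    matrix: MirnaSimilarityMatrix,
    families: Optional[GroupCatalog] = None,
    clusters: Optional[GroupCatalog] = None,
    config: Optional[PredictionConfig] = None,
    min_labels: int = DEFAULT_MIN_LABELS,
) -> EvaluationReport:
    """Temporal hold-out: train on the older snapshot, recover additions.

    ``matrix`` must be built from ``old``.  Old pairs missing from ``new``
    violate the additions-only premise; they are logged and ignored.  For
    each disease in the old snapshot with enough labels, the positives are
    the miRNAs newly associated in ``new`` (restricted to the matrix
    universe), the pool is everything unlabeled under ``old``, and scores
    come from the old labels only.
    """
    if config is None:
        config = PredictionConfig()
    removed = old.pairs - new.pairs
    if removed:
        logger.warning(
            "updated-dataset validation: %d old pairs missing from the "
            "new snapshot; ignoring them", len(removed),
        )
        old = old.without(removed)
    universe = set(matrix.ids)
    results: List[DiseaseResult] = []
    skipped: List[Tuple[str, str]] = []
    for disease in old.diseases:
        old_labeled = old.labeled(disease)
        if len(old_labeled) < min_labels:
            skipped.append((disease, f"only {len(old_labeled)} labeled miRNAs"))
            continue
        additions = (new.labeled(disease) - old_labeled) & universe
        if not additions:
            skipped.append((disease, "no new additions"))
            continue
        pool = old.unlabeled(disease, universe=universe)
        negatives = sorted(set(pool) - additions)
        if not negatives:
            skipped.append((disease, "no negatives left in pool"))
            continue
        ranked = rank_candidates(
            disease, old, matrix, families, clusters, config, pool=pool
        )
        scores = {m: s for m, s, _ in ranked.entries}
        curve = roc_from_scores(
            [scores[m] for m in sorted(additions)],
            [scores[m] for m in negatives],
        )
        results.append(DiseaseResult(disease=disease, fold_aucs=(curve.area,)))
    return EvaluationReport(
        results=tuple(results), skipped=tuple(skipped), config=config
    )


def sweep_parameter(
    parameter: str,
    values: Iterable,
    associations: AssociationSet,
    matrix: MirnaSimilarityMatrix,
    families: Optional[GroupCatalog] = None,
    clusters: Optional[GroupCatalog] = None,
    base_config: Optional[PredictionConfig] = None,
    **evaluate_kwargs,
) -> pd.DataFrame:
    """Grand-mean CV AUC as one of k/alpha/beta varies, others held at the
    base configuration.  Returns a tidy frame (parameter, value, mean_auc)."""
    if parameter not in ("k", "alpha", "beta"):
        raise ParameterError(f"cannot sweep parameter {parameter!r}")
    if base_config is None:
        base_config = PredictionConfig()
    rows = []
    for value in values:
        kwargs = {
            "k": base_config.k,
            "alpha": base_config.alpha,
            "beta": base_config.beta,
        }
        kwargs[parameter] = int(value) if parameter == "k" else float(value)
        config = PredictionConfig(**kwargs)
        report = evaluate_cv(
            associations, matrix, families, clusters, config, **evaluate_kwargs
        )
        rows.append((parameter, value, report.grand_mean))
    return pd.DataFrame(rows, columns=["parameter", "value", "mean_auc"])
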