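"""The weighted k-most-similar-neighbor scoring algorithm.

For a disease d and a candidate miRNA u, the k miRNAs most functionally
similar to u are inspected.  Each neighbor v contributes a subscore:

* 0 when v is not labeled with d;
* MS(u, v) when v is labeled and shares no group with u;
* MS(u, v) multiplied by the family weight w_f(d) and/or cluster weight
  w_g(d) when u and v share that family and/or cluster.

The relevance score of u is the sum over its k neighbors; candidates are
ranked by descending score.  Unlabeled neighbors occupy neighbor slots and
contribute nothing, so the local density of labeled miRNAs among the most
similar neighbors drives the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .errors import NoLabelsError, ParameterError
from .grouping import GroupCatalog, group_rate, group_weight
from .mirna_similarity import AssociationSet, MirnaSimilarityMatrix, normalize_mirna_id

__all__ = [
    "PredictionConfig",
    "RankedCandidates",
    "select_neighbors",
    "neighbor_subscore",
    "relevance_score",
    "rank_candidates",
]


@dataclass(frozen=True)
class PredictionConfig:
    """Scoring knobs: neighborhood size k (default 20, the best-performing
    setting), family adjustment factor alpha and cluster adjustment factor
    beta (both default 4).  Sending a factor to infinity disables that
    group's boost (weights collapse to 1)."""

    k: int = 20
    alpha: float = 4.0
    beta: float = 4.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError(
                f"adjustment factors must be > 0, got alpha={self.alpha}, "
                f"beta={self.beta}"
            )


@dataclass(frozen=True)
class RankedCandidates:
    """Scored, ordered candidates for one disease; dense 1-based ranks,
    ties broken by ascending miRNA id."""

    disease: str
    entries: Tuple[Tuple[str, float, int], ...]

    def rank_of(self, mirna: str) -> int:
        key = normalize_mirna_id(mirna)
        for m, _, rank in self.entries:
            if m == key:
                return rank
        raise KeyError(f"{mirna!r} not among ranked candidates")

    def score_of(self, mirna: str) -> float:
        key = normalize_mirna_id(mirna)
        for m, score, _ in self.entries:
            if m == key:
                return score
        raise KeyError(f"{mirna!r} not among ranked candidates")

    def top(self, n: int) -> Tuple[Tuple[str, float, int], ...]:
        return self.entries[:n]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rank, m, score) for m, score, rank in self.entries],
            columns=["rank", "mirna_id", "score"],
        )

    def __len__(self) -> int:
        return len(self.entries)


def select_neighbors(
    u: str, matrix: MirnaSimilarityMatrix, k: int
) -> List[Tuple[str, float]]:
    """The k most similar miRNAs to ``u`` (excluding ``u`` itself), in
    descending similarity with ties broken by ascending id.  Fewer than k
    are returned when the pool is small."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    i = matrix.index(u)
    row = matrix.row(u)
    others = [
        (matrix.ids[j], float(row[j])) for j in range(len(matrix)) if j != i
    ]
    others.sort(key=lambda pair: (-pair[1], pair[0]))
    return others[:k]


def _pair_weight(
    u: str,
    v: str,
    disease: str,
    labels: AssociationSet,
    catalog: Optional[GroupCatalog],
    factor: float,
    memo: Optional[Dict[Tuple[str, str], float]] = None,
) -> float:
    if catalog is None:
        return 1.0
    gid = catalog.shared_group(u, v)
    if gid is None:
        return 1.0
    key = (catalog.kind, gid)
    if memo is not None and key in memo:
        return memo[key]
    weight = group_weight(group_rate(catalog.groups[gid], disease, labels), factor)
    if memo is not None:
        memo[key] = weight
    return weight


def neighbor_subscore(
    u: str,
    v: str,
    disease: str,
    labels: AssociationSet,
    matrix: MirnaSimilarityMatrix,
    families: Optional[GroupCatalog] = None,
    clusters: Optional[GroupCatalog] = None,
    config: Optional[PredictionConfig] = None,
    _memo: Optional[Dict[Tuple[str, str], float]] = None,
) -> float:
    """Subscore of neighbor ``v`` for query ``u`` and ``disease``.

    Zero for an unlabeled neighbor; otherwise MS(u, v) boosted by the
    family and/or cluster weight when the *pair* shares that group.  Group
    rates are taken from the current ``labels``, so cross-validation folds
    automatically use training-only weights.
    """
    if config is None:
        config = PredictionConfig()
    if normalize_mirna_id(v) not in labels.labeled(disease):
        return 0.0
    weight = _pair_weight(u, v, disease, labels, families, config.alpha, _memo)
    weight *= _pair_weight(u, v, disease, labels, clusters, config.beta, _memo)
    return matrix.sim(u, v) * weight


def relevance_score(
    u: str,
    disease: str,
    labels: AssociationSet,
    matrix: MirnaSimilarityMatrix,
    families: Optional[GroupCatalog] = None,
    clusters: Optional[GroupCatalog] = None,
    config: Optional[PredictionConfig] = None,
    _memo: Optional[Dict[Tuple[str, str], float]] = None,
) -> float:
    """Score(u) = sum of the subscores of u's k most similar neighbors."""
    if config is None:
        config = PredictionConfig()
    return sum(
        neighbor_subscore(
            u, v, disease, labels, matrix, families, clusters, config, _memo
        )
        for v, _ in select_neighbors(u, matrix, config.k)
    )


def rank_candidates(
    disease: str,
    labels: AssociationSet,
    matrix: MirnaSimilarityMatrix,
    families: Optional[GroupCatalog] = None,
    clusters: Optional[GroupCatalog] = None,
    config: Optional[PredictionConfig] = None,
    pool: Optional[Iterable[str]] = None,
) -> RankedCandidates:
    """Score and rank the candidate pool for ``disease``.

    The pool defaults to all matrix miRNAs unlabeled for the disease
    (prediction mode); evaluation passes an explicit pool that also holds
    the hidden test miRNAs.  Ordering is (score desc, id asc), ranks are
    dense and 1-based, and the result is deterministic for fixed inputs.
    """
    if config is None:
        config = PredictionConfig()
    if not labels.labeled(disease):
        raise NoLabelsError(f"disease {disease!r} has no labeled miRNAs")
    if pool is None:
        candidates = labels.unlabeled(disease, universe=matrix.ids)
    else:
        candidates = tuple(sorted({normalize_mirna_id(m) for m in pool}))
    memo: Dict[Tuple[str, str], float] = {}
    scored = [
        (
            m,
            relevance_score(
                m, disease, labels, matrix, families, clusters, config, memo
            ),
        )
        for m in candidates
    ]
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    entries = tuple(
        (m, score, rank) for rank, (m, score) in enumerate(scored, start=1)
    )
    return RankedCandidates(disease=disease, entries=entries)
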