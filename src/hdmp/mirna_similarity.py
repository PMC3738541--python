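"""miRNA-miRNA functional similarity from associated disease groups.

Functionally similar miRNAs tend to be implicated in similar diseases, so
the similarity of two miRNAs ``u`` and ``v`` is measured on their disease
groups ``DT(u)`` and ``DT(v)``: every disease of one group is matched to
its most similar disease in the other group, and the best-match
similarities are averaged,

``MS(u, v) = [ sum_{d in DT(u)} S(d, DT(v)) + sum_{d in DT(v)} S(d, DT(u)) ]
             / (|DT(u)| + |DT(v)|)``.

``MS`` is symmetric, bounded in [0, 1], and equals 1 when the two groups
coincide.  The full symmetric matrix over all miRNAs of an association set
is the substrate for neighbor selection in the predictor.
"""

from __future__ import annotations

import logging
from typing import Callable, Dict, FrozenSet, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .disease_similarity import group_similarity
from .errors import EmptyInputError, ParameterError, UnknownTermError, UnusableMirnaError

__all__ = [
    "normalize_mirna_id",
    "AssociationSet",
    "MirnaSimilarityMatrix",
    "mirna_functional_similarity",
    "build_similarity_matrix",
    "update_similarity_rows",
]

logger = logging.getLogger(__name__)


def normalize_mirna_id(mirna_id: str) -> str:
    """Canonical precursor-style id: trimmed and lowercased, so
    ``hsa-miR-21`` and ``hsa-mir-21`` collapse to one identifier."""
    return mirna_id.strip().lower()


class AssociationSet:
    """Set semantics over (miRNA, disease) association pairs.

    Duplicate records collapse; miRNA ids are normalized on entry.  The
    derived views are the disease group ``DT(u)`` of a miRNA, the labeled
    set ``Q`` of a disease, and the unlabeled complement ``U`` relative to
    a miRNA universe (by default the miRNAs of this set).
    """

    def __init__(self, pairs: Iterable[Tuple[str, str]]):
        normalized = frozenset(
            (normalize_mirna_id(m), str(d).strip()) for m, d in pairs
        )
        self._pairs = normalized
        by_mirna: Dict[str, set] = {}
        by_disease: Dict[str, set] = {}
        for m, d in normalized:
            by_mirna.setdefault(m, set()).add(d)
            by_disease.setdefault(d, set()).add(m)
        self._by_mirna = {m: frozenset(s) for m, s in by_mirna.items()}
        self._by_disease = {d: frozenset(s) for d, s in by_disease.items()}

    @property
    def pairs(self) -> FrozenSet[Tuple[str, str]]:
        return self._pairs

    @property
    def mirnas(self) -> Tuple[str, ...]:
        return tuple(sorted(self._by_mirna))

    @property
    def diseases(self) -> Tuple[str, ...]:
        return tuple(sorted(self._by_disease))

    def diseases_of(self, mirna: str) -> FrozenSet[str]:
        return self._by_mirna.get(normalize_mirna_id(mirna), frozenset())

    def labeled(self, disease: str) -> FrozenSet[str]:
        """The labeled miRNA set Q of ``disease``."""
        return self._by_disease.get(disease, frozenset())

    def unlabeled(
        self, disease: str, universe: Optional[Iterable[str]] = None
    ) -> Tuple[str, ...]:
        """Sorted unlabeled complement U of ``disease`` within ``universe``."""
        pool = set(universe) if universe is not None else set(self._by_mirna)
        return tuple(sorted(pool - self.labeled(disease)))

    def without(self, pairs: Iterable[Tuple[str, str]]) -> "AssociationSet":
        """A new set with the given pairs removed (miRNAs left with no
        diseases simply disappear from the derived views)."""
        drop = {(normalize_mirna_id(m), str(d).strip()) for m, d in pairs}
        return AssociationSet(self._pairs - drop)

    def filter_to_ontology(self, ontology) -> Tuple["AssociationSet", list]:
        """Keep pairs whose disease resolves in ``ontology``; disease keys
        are canonicalized to term ids.  Returns the filtered set and the
        dropped pairs; kept/dropped counts are logged."""
        kept, dropped = [], []
        for m, d in sorted(self._pairs):
            try:
                kept.append((m, ontology.resolve(d).term_id))
            except UnknownTermError:
                dropped.append((m, d))
        logger.info(
            "association filtering: kept %d pairs, dropped %d with "
            "unresolvable diseases",
            len(kept),
            len(dropped),
        )
        if not kept:
            raise EmptyInputError(
                "no associations survive ontology filtering"
            )
        return AssociationSet(kept), dropped

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        m, d = pair
        return (normalize_mirna_id(m), str(d).strip()) in self._pairs

    def __eq__(self, other) -> bool:
        return isinstance(other, AssociationSet) and self._pairs == other._pairs

    def __hash__(self) -> int:
        return hash(self._pairs)

    def __repr__(self) -> str:
        return (
            f"AssociationSet({len(self._pairs)} pairs, "
            f"{len(self._by_mirna)} miRNAs, {len(self._by_disease)} diseases)"
        )


class MirnaSimilarityMatrix:
    """Dense symmetric MS matrix with a sorted miRNA index.

    The diagonal is fixed to 1 by convention (self-similarity is never used
    by the predictor, whose neighbor sets exclude the query).
    """

    def __init__(self, ids: Sequence[str], values: np.ndarray, *, validate: bool = True):
        ids = tuple(ids)
        values = np.asarray(values, dtype=float)
        if validate:
            if len(set(ids)) != len(ids):
                raise ParameterError("duplicate miRNA ids in matrix index")
            if values.shape != (len(ids), len(ids)):
                raise ParameterError(
                    f"matrix shape {values.shape} does not match {len(ids)} ids"
                )
            if not np.allclose(values, values.T, atol=1e-9):
                raise ParameterError("similarity matrix is not symmetric")
            if values.min() < -1e-9 or values.max() > 1.0 + 1e-9:
                raise ParameterError("similarity values outside [0, 1]")
            if not np.allclose(np.diag(values), 1.0):
                raise ParameterError("matrix diagonal must be 1")
        self._ids = ids
        self._index = {m: i for i, m in enumerate(ids)}
        self._values = values

    @property
    def ids(self) -> Tuple[str, ...]:
        return self._ids

    @property
    def values(self) -> np.ndarray:
        return self._values

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, mirna: str) -> bool:
        return normalize_mirna_id(mirna) in self._index

    def index(self, mirna: str) -> int:
        key = normalize_mirna_id(mirna)
        if key not in self._index:
            raise UnknownTermError(f"miRNA {mirna!r} not in similarity matrix")
        return self._index[key]

    def sim(self, u: str, v: str) -> float:
        return float(self._values[self.index(u), self.index(v)])

    def row(self, mirna: str) -> np.ndarray:
        return self._values[self.index(mirna)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=self._ids, columns=self._ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="mirna_id")

    @classmethod
    def from_tsv(cls, path) -> "MirnaSimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(frame.index), frame.to_numpy())

    @classmethod
    def from_function(
        cls, ids: Iterable[str], fn: Callable[[str, str], float]
    ) -> "MirnaSimilarityMatrix":
        ordered = tuple(sorted(normalize_mirna_id(m) for m in ids))
        n = len(ordered)
        values = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = fn(ordered[i], ordered[j])
        return cls(ordered, values)


def mirna_functional_similarity(
    u: str,
    v: str,
    associations: AssociationSet,
    disease_sim: Callable[[str, str], float],
) -> float:
    """MS(u, v): average best-match similarity between the disease groups.

    ``disease_sim`` is any pairwise DS function (typically a cached
    :class:`~hdmp.disease_similarity.PairwiseDiseaseSimilarity`).
    """
    dt_u = associations.diseases_of(u)
    dt_v = associations.diseases_of(v)
    if not dt_u:
        raise UnusableMirnaError(f"miRNA {u!r} has no associated diseases")
    if not dt_v:
        raise UnusableMirnaError(f"miRNA {v!r} has no associated diseases")
    if normalize_mirna_id(u) == normalize_mirna_id(v):
        return 1.0
    forward = sum(group_similarity(d, dt_v, disease_sim) for d in dt_u)
    backward = sum(group_similarity(d, dt_u, disease_sim) for d in dt_v)
    return min(1.0, (forward + backward) / (len(dt_u) + len(dt_v)))


def build_similarity_matrix(
    associations: AssociationSet,
    disease_sim: Callable[[str, str], float],
) -> MirnaSimilarityMatrix:
    """Assemble the full symmetric MS matrix over all miRNAs of
    ``associations``.

    Pairwise disease similarities are evaluated once per distinct disease
    pair and reused through a dense lookup, which keeps the assembly
    deterministic and fast for thousands of miRNA pairs.
    """
    mirnas = associations.mirnas
    if not mirnas:
        raise EmptyInputError("association set contains no miRNAs")
    diseases = associations.diseases
    d_index = {d: i for i, d in enumerate(diseases)}
    n_d = len(diseases)
    ds = np.ones((n_d, n_d))
    for i in range(n_d):
        for j in range(i + 1, n_d):
            ds[i, j] = ds[j, i] = disease_sim(diseases[i], diseases[j])

    dt_idx = {
        m: np.fromiter(
            (d_index[d] for d in sorted(associations.diseases_of(m))),
            dtype=np.intp,
        )
        for m in mirnas
    }
    n = len(mirnas)
    values = np.eye(n)
    for i in range(n):
        ti = dt_idx[mirnas[i]]
        for j in range(i + 1, n):
            tj = dt_idx[mirnas[j]]
            block = ds[np.ix_(ti, tj)]
            ms = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                len(ti) + len(tj)
            )
            values[i, j] = values[j, i] = min(1.0, ms)
    return MirnaSimilarityMatrix(mirnas, values)


def update_similarity_rows(
    matrix: MirnaSimilarityMatrix,
    associations: AssociationSet,
    changed: Iterable[str],
    disease_sim: Callable[[str, str], float],
) -> MirnaSimilarityMatrix:
    """Recompute the rows/columns of ``changed`` miRNAs against the current
    ``associations`` (used when cross-validation hides some labels).

    A changed miRNA left with an empty disease group gets similarity 0 to
    every other miRNA: with no known associations its function carries no
    information.  Entries between two unchanged miRNAs are untouched.
    """
    changed_ids = [normalize_mirna_id(m) for m in changed]
    for m in changed_ids:
        matrix.index(m)  # raises for unknown ids
    values = matrix.values.copy()
    changed_set = set(changed_ids)
    for m in changed_ids:
        i = matrix.index(m)
        dt_m = associations.diseases_of(m)
        for j, other in enumerate(matrix.ids):
            if j == i:
                continue
            if other in changed_set and matrix.index(other) < i:
                continue  # already refreshed from the other side
            dt_o = associations.diseases_of(other)
            if not dt_m or not dt_o:
                ms = 0.0
            else:
                ms = mirna_functional_similarity(m, other, associations, disease_sim)
            values[i, j] = values[j, i] = ms
    return MirnaSimilarityMatrix(matrix.ids, values, validate=False)
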