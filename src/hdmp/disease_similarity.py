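"""Pairwise disease similarity.

Three layers are combined here:

* **Semantic similarity** ``SS(A, B)``: the share of the two diseases'
  semantic values carried by their shared ancestor terms,

  ``SS(A, B) = sum_{t in T_A ∩ T_B} (D_A(t) + D_B(t)) / (DV(A) + DV(B))``,

  under either contribution scheme (layer or information content).
* **Phenotype similarity** ``PS(A, B)``: a text-mining-derived similarity
  between clinical phenotype records (MimMiner-style), reached through a
  many-to-many mapping from ontology terms to phenotype ids.  When either
  disease maps to no phenotype the value is *absent* rather than zero.
* **Fused similarity** ``DS(A, B) = lambda*SS + (1-lambda)*PS`` when PS is
  present, else ``DS = SS``; ``lambda`` defaults to 0.5.

``group_similarity`` lifts DS to a disease-vs-disease-group similarity by
best match: ``S(d, DT) = max_{d' in DT} DS(d, d')``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

from .errors import (
    EmptyGroupError,
    MixedOntologyError,
    ParameterError,
)
from .ontology import (
    ContributionMap,
    DiseaseDAG,
    ICTable,
    Ontology,
    build_disease_dag,
    compute_information_content,
    contribution_map,
    semantic_value,
)

__all__ = [
    "DiseaseSimilarityConfig",
    "PhenotypeSimilarityTable",
    "semantic_similarity",
    "phenotype_similarity",
    "disease_similarity",
    "group_similarity",
    "PairwiseDiseaseSimilarity",
]


@dataclass(frozen=True)
class DiseaseSimilarityConfig:
    """Knobs of the disease-similarity layer.

    scheme : ``"layer"`` or ``"ic"`` contribution scheme (default ``"ic"``,
        the proposed measure; ``"layer"`` reproduces the depth-decay one).
    delta : semantic contribution factor of the layer scheme, in (0, 1].
    fusion_weight : lambda weighting SS against PS, in [0, 1].
    ic_table : IC values for the ic scheme; when ``None`` it is derived
        from the ontology at first use.
    """

    scheme: str = "ic"
    delta: float = 0.5
    fusion_weight: float = 0.5
    ic_table: Optional[ICTable] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("layer", "ic"):
            raise ParameterError(f"unknown similarity scheme {self.scheme!r}")
        if not (0.0 < self.delta <= 1.0):
            raise ParameterError(f"delta must be in (0, 1], got {self.delta}")
        if not (0.0 <= self.fusion_weight <= 1.0):
            raise ParameterError(
                f"fusion weight must be in [0, 1], got {self.fusion_weight}"
            )


def _contributions(dag: DiseaseDAG, config: DiseaseSimilarityConfig) -> ContributionMap:
    return contribution_map(
        dag, config.scheme, delta=config.delta, ic_table=config.ic_table
    )


def semantic_similarity(
    dag_a: DiseaseDAG, dag_b: DiseaseDAG, config: Optional[DiseaseSimilarityConfig] = None
) -> float:
    """SS(A, B) over two DAGs built from the same ontology.

    Symmetric, bounded in [0, 1], equal to 1 for identical DAGs and to 0
    exactly when the DAGs share no term.
    """
    if config is None:
        config = DiseaseSimilarityConfig(scheme="layer")
    if dag_a.source is not dag_b.source:
        raise MixedOntologyError(
            f"DAGs of {dag_a.disease.term_id!r} and {dag_b.disease.term_id!r} "
            "come from different ontologies"
        )
    ca = _contributions(dag_a, config)
    cb = _contributions(dag_b, config)
    shared = dag_a.nodes & dag_b.nodes
    if not shared:
        return 0.0
    numerator = sum(ca[t] + cb[t] for t in shared)
    denominator = semantic_value(ca) + semantic_value(cb)
    return min(1.0, numerator / denominator)


class PhenotypeSimilarityTable:
    """Sparse symmetric phenotype-phenotype similarity in [0, 1].

    Stored pairs are order-normalized so the symmetric closure is implied;
    the diagonal is implicitly 1 and unstored off-diagonal pairs are 0.
    """

    def __init__(self, pairs: Mapping[Tuple[str, str], float] | Iterable[Tuple[str, str, float]]):
        items: Iterable[Tuple[str, str, float]]
        if isinstance(pairs, Mapping):
            items = ((a, b, v) for (a, b), v in pairs.items())
        else:
            items = pairs
        self._values: Dict[Tuple[str, str], float] = {}
        self._ids: Set[str] = set()
        for a, b, value in items:
            value = float(value)
            if not (0.0 <= value <= 1.0):
                raise ParameterError(
                    f"phenotype similarity for ({a!r}, {b!r}) outside [0, 1]: {value}"
                )
            key = (a, b) if a <= b else (b, a)
            previous = self._values.get(key)
            if previous is not None and abs(previous - value) > 1e-12:
                raise ParameterError(
                    f"conflicting similarities for pair ({a!r}, {b!r}): "
                    f"{previous} vs {value}"
                )
            self._values[key] = value
            self._ids.add(a)
            self._ids.add(b)

    @property
    def ids(self) -> FrozenSet[str]:
        return frozenset(self._ids)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._values.get(key, 0.0)

    def __len__(self) -> int:
        return len(self._values)


def phenotype_similarity(
    a: str,
    b: str,
    table: PhenotypeSimilarityTable,
    mapping: Mapping[str, Set[str]],
) -> Optional[float]:
    """PS between two ontology terms, or ``None`` when unmapped.

    Multiple phenotype mappings are aggregated optimistically: the maximum
    over all mapped phenotype pairs.
    """
    phenos_a = mapping.get(a) or ()
    phenos_b = mapping.get(b) or ()
    if not phenos_a or not phenos_b:
        return None
    return max(table.get(pa, pb) for pa in phenos_a for pb in phenos_b)


def disease_similarity(
    dag_a: DiseaseDAG,
    dag_b: DiseaseDAG,
    config: Optional[DiseaseSimilarityConfig] = None,
    phenotypes: Optional[PhenotypeSimilarityTable] = None,
    mapping: Optional[Mapping[str, Set[str]]] = None,
) -> float:
    """DS(A, B): semantic similarity fused with phenotype similarity.

    ``DS = lambda*SS + (1-lambda)*PS`` when PS is available, otherwise the
    semantic similarity alone (missing phenotype data degrades gracefully,
    never errors).
    """
    if config is None:
        config = DiseaseSimilarityConfig(scheme="layer")
    ss = semantic_similarity(dag_a, dag_b, config)
    ps: Optional[float] = None
    if phenotypes is not None and mapping is not None:
        ps = phenotype_similarity(
            dag_a.disease.term_id, dag_b.disease.term_id, phenotypes, mapping
        )
    if ps is None:
        return ss
    lam = config.fusion_weight
    return lam * ss + (1.0 - lam) * ps


def group_similarity(
    disease: str,
    group: Iterable[str],
    pairwise: Callable[[str, str], float],
) -> float:
    """Best-match similarity S(d, DT) = max over DT of DS(d, d').

    Equals 1 whenever ``disease`` itself belongs to the group (DS(d, d)=1).
    """
    members = list(group)
    if not members:
        raise EmptyGroupError(f"empty disease group for {disease!r}")
    return max(pairwise(disease, member) for member in members)


class PairwiseDiseaseSimilarity:
    """Cached DS over one ontology; callable as ``pairwise(a, b)``.

    Builds each disease DAG and its contribution map once, and memoizes
    every requested DS value, so that assembling a full miRNA similarity
    matrix is quadratic in the number of *distinct* diseases only.  When
    the ic scheme is selected without an explicit table, term information
    content is computed from the ontology.
    """

    def __init__(
        self,
        ontology: Ontology,
        config: Optional[DiseaseSimilarityConfig] = None,
        phenotypes: Optional[PhenotypeSimilarityTable] = None,
        mapping: Optional[Mapping[str, Set[str]]] = None,
    ):
        if config is None:
            config = DiseaseSimilarityConfig()
        if config.scheme == "ic" and config.ic_table is None:
            config = replace(config, ic_table=compute_information_content(ontology))
        self.ontology = ontology
        self.config = config
        self.phenotypes = phenotypes
        self.mapping = mapping
        self._dags: Dict[str, DiseaseDAG] = {}
        self._cache: Dict[Tuple[str, str], float] = {}

    def dag(self, disease: str) -> DiseaseDAG:
        term_id = self.ontology.resolve(disease).term_id
        if term_id not in self._dags:
            self._dags[term_id] = build_disease_dag(self.ontology, term_id)
        return self._dags[term_id]

    def __call__(self, a: str, b: str) -> float:
        id_a = self.ontology.resolve(a).term_id
        id_b = self.ontology.resolve(b).term_id
        if id_a == id_b:
            return 1.0
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        value = self._cache.get(key)
        if value is None:
            value = disease_similarity(
                self.dag(id_a),
                self.dag(id_b),
                self.config,
                self.phenotypes,
                self.mapping,
            )
            self._cache[key] = value
        return value
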