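"""Disease ontology handling: term tables, per-disease ancestor DAGs,
semantic contributions, and term information content.

A disease vocabulary in the MeSH style is poly-hierarchical: every term
occupies one or more dot-separated *tree numbers* (for example
``C06.552.697``), and removing the last dotted component of a tree number
yields the position of a parent term.  The sub-graph of all ancestors of a
disease, rooted at the disease itself, is that disease's DAG.  Each node of
the DAG carries a *semantic contribution* toward the disease under one of
two schemes:

* **layer**: a node at depth ``k`` (minimum number of child->parent edges
  from the disease) contributes ``delta**k``, with ``delta`` the semantic
  contribution factor (0.5 by default), so contributions decay with
  generality;
* **ic**: a node contributes its information content,
  ``IC(t) = -log_b(n_t / N)``, where ``n_t`` is the number of disease DAGs
  containing the term out of ``N`` DAGs in total (one DAG per term), so
  rare -- i.e. specific -- terms contribute more regardless of depth.

The sum of contributions over a DAG is the disease's *semantic value*
``DV``, the normalizer used by the semantic similarity of two diseases.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional

import networkx as nx

from .errors import (
    CoverageError,
    EmptyInputError,
    OntologyIntegrityError,
    ParameterError,
    UnknownTermError,
)

__all__ = [
    "DiseaseTerm",
    "Ontology",
    "DiseaseDAG",
    "ContributionMap",
    "ICTable",
    "normalize_name",
    "build_disease_dag",
    "contribution_map",
    "semantic_value",
    "information_content",
    "compute_information_content",
]


def normalize_name(name: str) -> str:
    """Normalize a disease display name: lowercase, collapse whitespace."""
    return " ".join(name.strip().lower().split())


@dataclass(frozen=True)
class DiseaseTerm:
    """One ontology descriptor.

    Parameters
    ----------
    term_id : str
        Opaque unique key (e.g. a MeSH descriptor UI such as ``D008113``).
    name : str
        Display name; matching against names is case/whitespace-insensitive.
    tree_numbers : frozenset of str
        Non-empty set of dot-separated hierarchy positions.
    """

    term_id: str
    name: str
    tree_numbers: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tree_numbers", frozenset(self.tree_numbers))
        if not self.term_id:
            raise OntologyIntegrityError("term with empty term_id")
        if not self.tree_numbers:
            raise OntologyIntegrityError(
                f"term {self.term_id!r} has no tree numbers"
            )
        for tn in self.tree_numbers:
            if not tn or any(not part for part in tn.split(".")):
                raise OntologyIntegrityError(
                    f"term {self.term_id!r} has malformed tree number {tn!r}"
                )

    @property
    def is_root(self) -> bool:
        """True when any tree number has a single component (hierarchy root)."""
        return any("." not in tn for tn in self.tree_numbers)


class Ontology:
    """An immutable collection of :class:`DiseaseTerm` indexed by id, by
    normalized name, and by tree number.

    Construction validates integrity: term ids are unique, tree numbers are
    unique, and every tree-number prefix (parent position) resolves to a
    term in the table.
    """

    def __init__(self, terms: Iterable[DiseaseTerm]):
        self._by_id: Dict[str, DiseaseTerm] = {}
        self._by_tree: Dict[str, str] = {}
        self._by_name: Dict[str, str] = {}
        for term in terms:
            if term.term_id in self._by_id:
                raise OntologyIntegrityError(
                    f"duplicate term_id {term.term_id!r}"
                )
            self._by_id[term.term_id] = term
            self._by_name.setdefault(normalize_name(term.name), term.term_id)
            for tn in term.tree_numbers:
                if tn in self._by_tree:
                    raise OntologyIntegrityError(
                        f"tree number {tn!r} claimed by both "
                        f"{self._by_tree[tn]!r} and {term.term_id!r}"
                    )
                self._by_tree[tn] = term.term_id
        if not self._by_id:
            raise EmptyInputError("ontology contains no terms")
        for term in self._by_id.values():
            for tn in term.tree_numbers:
                if "." in tn:
                    prefix = tn.rsplit(".", 1)[0]
                    if prefix not in self._by_tree:
                        raise OntologyIntegrityError(
                            f"tree number {tn!r} of term {term.term_id!r} "
                            f"has dangling prefix {prefix!r}"
                        )
        self._ancestor_cache: Dict[str, FrozenSet[str]] = {}

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[DiseaseTerm]:
        return iter(self._by_id.values())

    def __contains__(self, key: str) -> bool:
        try:
            self.resolve(key)
        except UnknownTermError:
            return False
        return True

    def __getitem__(self, term_id: str) -> DiseaseTerm:
        try:
            return self._by_id[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    def resolve(self, key: str) -> DiseaseTerm:
        """Look a term up by id, falling back to normalized-name matching."""
        if key in self._by_id:
            return self._by_id[key]
        name_key = normalize_name(key)
        if name_key in self._by_name:
            return self._by_id[self._by_name[name_key]]
        raise UnknownTermError(f"unknown disease term {key!r}")

    def parents(self, term: DiseaseTerm) -> list[DiseaseTerm]:
        """Direct parents implied by every tree number, sorted by id."""
        parent_ids = {
            self._by_tree[tn.rsplit(".", 1)[0]]
            for tn in term.tree_numbers
            if "." in tn
        }
        return [self._by_id[pid] for pid in sorted(parent_ids)]

    def ancestor_closure(self, term_id: str) -> FrozenSet[str]:
        """Ids of the term and all its ancestors (memoized)."""
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        term = self[term_id]
        seen = {term_id}
        queue = deque([term])
        while queue:
            for parent in self.parents(queue.popleft()):
                if parent.term_id not in seen:
                    seen.add(parent.term_id)
                    queue.append(parent)
        closure = frozenset(seen)
        self._ancestor_cache[term_id] = closure
        return closure

    @property
    def roots(self) -> list[DiseaseTerm]:
        return sorted(
            (t for t in self if t.is_root), key=lambda t: t.term_id
        )


@dataclass(frozen=True)
class DiseaseDAG:
    """The ancestor DAG of one disease.

    ``graph`` holds child->parent edges over term ids; ``depths`` maps every
    node (the disease itself plus all ancestors) to its minimum edge
    distance from the disease node (the disease has depth 0).
    """

    disease: DiseaseTerm
    graph: nx.DiGraph
    depths: Mapping[str, int]
    source: Ontology = field(repr=False, compare=False)

    @property
    def nodes(self) -> FrozenSet[str]:
        return frozenset(self.depths)

    def term(self, term_id: str) -> DiseaseTerm:
        return self.source[term_id]

    def __len__(self) -> int:
        return len(self.depths)


def build_disease_dag(ontology: Ontology, disease: str) -> DiseaseDAG:
    """Build the ancestor DAG of ``disease`` (an id or a display name).

    The DAG is the union of every ancestor chain implied by every tree
    number of the disease, deduplicated by term id; each node is labeled
    with its minimum depth (breadth-first level).
    """
    term = ontology.resolve(disease)
    graph = nx.DiGraph()
    graph.add_node(term.term_id)
    depths: Dict[str, int] = {term.term_id: 0}
    queue = deque([term])
    while queue:
        current = queue.popleft()
        for parent in ontology.parents(current):
            graph.add_edge(current.term_id, parent.term_id)
            if parent.term_id not in depths:
                depths[parent.term_id] = depths[current.term_id] + 1
                queue.append(parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise OntologyIntegrityError(
            f"ancestor graph of {term.term_id!r} contains a cycle"
        )
    return DiseaseDAG(disease=term, graph=graph, depths=depths, source=ontology)


@dataclass(frozen=True)
class ContributionMap:
    """Per-node semantic contributions of one disease DAG.

    ``scheme`` is ``"layer"`` (contribution ``delta**depth``) or ``"ic"``
    (contribution ``IC(t)``); ``delta`` is set for the layer scheme only.
    """

    values: Mapping[str, float]
    scheme: str
    delta: Optional[float] = None

    def __getitem__(self, term_id: str) -> float:
        return self.values[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.values

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()


@dataclass(frozen=True)
class ICTable:
    """Information content per term.

    ``values[t] = -log_base(n_t / total)`` where ``n_t`` counts the disease
    DAGs containing ``t``.  Tables may also be constructed from externally
    supplied IC values (``counts``/``total`` then stay ``None``).
    """

    values: Mapping[str, float]
    counts: Optional[Mapping[str, int]] = None
    total: Optional[int] = None
    base: float = 2.0

    @classmethod
    def from_values(cls, values: Mapping[str, float], base: float = 2.0) -> "ICTable":
        return cls(values=dict(values), base=base)

    def __getitem__(self, term_id: str) -> float:
        return self.values[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.values

    def get(self, term_id: str, default=None):
        return self.values.get(term_id, default)

    def __len__(self) -> int:
        return len(self.values)


def information_content(n_t: int, total: int, base: float = 2.0) -> float:
    """IC of a term present in ``n_t`` of ``total`` disease DAGs."""
    if total <= 0 or n_t <= 0 or n_t > total:
        raise ParameterError(
            f"invalid DAG counts: n_t={n_t}, total={total}"
        )
    if base <= 1.0:
        raise ParameterError(f"log base must exceed 1, got {base}")
    return -math.log(n_t / total) / math.log(base)


def compute_information_content(ontology: Ontology, base: float = 2.0) -> ICTable:
    """Compute the IC of every term from the ontology itself.

    Every term induces exactly one disease DAG, so ``total = len(ontology)``
    and ``n_t`` is the number of ancestor closures containing ``t`` (each
    term contains itself, hence ``n_t >= 1``).  A term present in every DAG
    has IC exactly 0.
    """
    counts: Counter[str] = Counter()
    for term in ontology:
        counts.update(ontology.ancestor_closure(term.term_id))
    total = len(ontology)
    values = {
        term_id: information_content(n, total, base)
        for term_id, n in counts.items()
    }
    return ICTable(values=values, counts=dict(counts), total=total, base=base)


def contribution_map(
    dag: DiseaseDAG,
    scheme: str = "layer",
    *,
    delta: float = 0.5,
    ic_table: Optional[ICTable] = None,
) -> ContributionMap:
    """Assign a semantic contribution to every node of ``dag``.

    Layer scheme: ``delta**depth`` with ``delta`` in (0, 1].  IC scheme:
    the node's information content; every DAG node must be covered by
    ``ic_table``.
    """
    if scheme == "layer":
        if not (0.0 < delta <= 1.0):
            raise ParameterError(
                f"semantic contribution factor must be in (0, 1], got {delta}"
            )
        values = {t: delta**depth for t, depth in dag.depths.items()}
        return ContributionMap(values=values, scheme="layer", delta=delta)
    if scheme == "ic":
        if ic_table is None:
            raise ParameterError("ic scheme requires an ICTable")
        missing = sorted(t for t in dag.depths if t not in ic_table)
        if missing:
            raise CoverageError(
                f"IC table does not cover DAG terms: {', '.join(missing)}"
            )
        values = {t: ic_table[t] for t in dag.depths}
        return ContributionMap(values=values, scheme="ic")
    raise ParameterError(f"unknown contribution scheme {scheme!r}")


def semantic_value(contributions: ContributionMap) -> float:
    """DV of a disease: the sum of its DAG's contributions."""
    if len(contributions) == 0:
        raise EmptyInputError("contribution map is empty")
    return float(sum(contributions.values.values()))
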