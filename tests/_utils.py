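"""Independent reference implementations used as oracles by the tests.

Everything here is deliberately naive (explicit enumeration, double loops)
and separate from the package's own code paths.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from hdmp.grouping import group_rate
from hdmp.ontology import DiseaseTerm, Ontology


def random_ontology(rng: np.random.Generator, n_terms: int = 12) -> Ontology:
    """A random poly-hierarchy: each term takes 1-2 tree positions, each a
    fresh root or a child of an existing position."""
    terms: List[DiseaseTerm] = []
    positions: List[str] = []
    for i in range(n_terms):
        n_pos = 1 + int(rng.integers(2))
        mine = set()
        for j in range(n_pos):
            if not positions or rng.random() < 0.25:
                mine.add(f"R{i:02d}{j}")
            else:
                parent = positions[int(rng.integers(len(positions)))]
                mine.add(f"{parent}.{i:02d}{j}")
        terms.append(DiseaseTerm(f"T{i:03d}", f"random term {i}", frozenset(mine)))
        positions.extend(sorted(mine))
    return Ontology(terms)


def path_lengths(ontology: Ontology, disease: str) -> Dict[str, List[int]]:
    """Every parent-chain path length from the disease to each ancestor,
    by exhaustive DFS (exponential; fine for tiny ontologies)."""
    lengths: Dict[str, List[int]] = {}

    def dfs(term, depth):
        lengths.setdefault(term.term_id, []).append(depth)
        for parent in ontology.parents(term):
            dfs(parent, depth + 1)

    dfs(ontology.resolve(disease), 0)
    return lengths


def naive_semantic_similarity(ontology: Ontology, a: str, b: str, delta: float) -> float:
    """Layer-scheme SS by explicit enumeration, with depths taken from
    exhaustive path enumeration rather than BFS."""
    la = path_lengths(ontology, a)
    lb = path_lengths(ontology, b)
    ca = {t: delta ** min(ls) for t, ls in la.items()}
    cb = {t: delta ** min(ls) for t, ls in lb.items()}
    shared = set(ca) & set(cb)
    if not shared:
        return 0.0
    return sum(ca[t] + cb[t] for t in shared) / (sum(ca.values()) + sum(cb.values()))


def mann_whitney_auc(pos, neg) -> float:
    """Fraction of (positive, negative) pairs ordered correctly; ties 1/2."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_scores(disease, labels, matrix, families, clusters, config, pool):
    """Relevance scores computed from the definitions with plain loops."""
    labeled = labels.labeled(disease)
    scores = {}
    for u in pool:
        neighbors = sorted(
            ((v, matrix.sim(u, v)) for v in matrix.ids if v != u),
            key=lambda p: (-p[1], p[0]),
        )[: config.k]
        total = 0.0
        for v, ms in neighbors:
            if v not in labeled:
                continue
            weight = 1.0
            for catalog, factor in ((families, config.alpha), (clusters, config.beta)):
                if catalog is None:
                    continue
                gid = catalog.shared_group(u, v)
                if gid is not None:
                    weight *= 1.0 + group_rate(catalog.groups[gid], disease, labels) / factor
            total += ms * weight
        scores[u] = total
    return scores


def random_similarity_matrix(rng: np.random.Generator, ids):
    """A random valid similarity matrix over the given ids."""
    from hdmp.mirna_similarity import MirnaSimilarityMatrix

    ids = tuple(sorted(ids))
    n = len(ids)
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    return MirnaSimilarityMatrix(ids, sym)
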