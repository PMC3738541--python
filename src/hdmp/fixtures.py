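"""Deterministic fixtures: the published worked example and synthetic corpora.

``paper_fixture`` reconstructs the worked example threaded through the
method description: the liver-neoplasms / pancreatic-neoplasms / breast-
neoplasms disease DAGs (with real MeSH-style descriptor ids and tree
numbers), the printed information-content values of the liver-neoplasms
ancestors, the two example miRNA disease groups, the five-member family
with its per-disease association pattern, and the six-neighbor scoring
scenario.  Every number a test asserts against this fixture comes from the
published arithmetic.

``generate_corpus`` fabricates a complete input bundle (ontology,
associations, families, precursor coordinates, phenotype similarities and
term-phenotype mapping) with *planted disease modules*: the miRNAs of one
module associate with a group of sibling leaf diseases (shared parent,
hence nonzero shared-ancestor similarity) with high probability ``p_in``
and with everything else at background rate ``p_out``.  ``null_corpus``
severs that structure (uniform association probability), giving the
no-signal reference on which a ranker should sit at AUC ~ 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .disease_similarity import PhenotypeSimilarityTable
from .errors import ParameterError
from .grouping import GenomicLocus, GroupCatalog, build_clusters
from .mirna_similarity import AssociationSet
from .ontology import DiseaseTerm, ICTable, Ontology

__all__ = [
    "PaperFixture",
    "NeighborScenario",
    "paper_fixture",
    "SyntheticSpec",
    "SyntheticCorpus",
    "generate_corpus",
    "null_corpus",
]

# MeSH-style descriptor ids of the worked example's terms.
LIVER_NEOPLASMS = "D008113"
PANCREATIC_NEOPLASMS = "D010190"
BREAST_NEOPLASMS = "D001943"
DIGESTIVE_SYSTEM_NEOPLASMS = "D004067"
NEOPLASMS_BY_SITE = "D009371"
NEOPLASMS = "D009369"
LIVER_DISEASES = "D008107"
DIGESTIVE_SYSTEM_DISEASES = "D004066"
ENDOCRINE_GLAND_NEOPLASMS = "D004701"
PANCREATIC_DISEASES = "D010182"
ENDOCRINE_SYSTEM_DISEASES = "D004700"

#: Printed IC values of the liver-neoplasms DAG terms (base-2 convention).
PRINTED_IC = {
    LIVER_NEOPLASMS: 10.160,
    DIGESTIVE_SYSTEM_NEOPLASMS: 6.838,
    NEOPLASMS_BY_SITE: 4.453,
    NEOPLASMS: 2.785,
    LIVER_DISEASES: 6.116,
    DIGESTIVE_SYSTEM_DISEASES: 3.961,
}


def _worked_example_ontology() -> Ontology:
    terms = [
        DiseaseTerm(NEOPLASMS, "Neoplasms", frozenset({"C04"})),
        DiseaseTerm(NEOPLASMS_BY_SITE, "Neoplasms by Site", frozenset({"C04.588"})),
        DiseaseTerm(
            DIGESTIVE_SYSTEM_NEOPLASMS,
            "Digestive System Neoplasms",
            frozenset({"C04.588.274", "C06.301"}),
        ),
        DiseaseTerm(
            ENDOCRINE_GLAND_NEOPLASMS,
            "Endocrine Gland Neoplasms",
            frozenset({"C04.588.322", "C19.344"}),
        ),
        DiseaseTerm(
            DIGESTIVE_SYSTEM_DISEASES,
            "Digestive System Diseases",
            frozenset({"C06"}),
        ),
        DiseaseTerm(LIVER_DISEASES, "Liver Diseases", frozenset({"C06.552"})),
        DiseaseTerm(
            PANCREATIC_DISEASES, "Pancreatic Diseases", frozenset({"C06.689"})
        ),
        DiseaseTerm(
            ENDOCRINE_SYSTEM_DISEASES,
            "Endocrine System Diseases",
            frozenset({"C19"}),
        ),
        DiseaseTerm(
            LIVER_NEOPLASMS,
            "Liver Neoplasms",
            frozenset({"C04.588.274.623", "C06.301.623", "C06.552.697"}),
        ),
        DiseaseTerm(
            PANCREATIC_NEOPLASMS,
            "Pancreatic Neoplasms",
            frozenset(
                {
                    "C04.588.274.761",
                    "C04.588.322.475",
                    "C06.301.761",
                    "C06.689.667",
                    "C19.344.421",
                }
            ),
        ),
        DiseaseTerm(BREAST_NEOPLASMS, "Breast Neoplasms", frozenset({"C04.588.180"})),
    ]
    return Ontology(terms)


@dataclass(frozen=True)
class NeighborScenario:
    """The six-neighbor scoring scenario: a query miRNA whose three labeled
    neighbors have similarities 0.6, 0.7 and 0.6, the last sharing a
    ten-member family in which six miRNAs carry the disease label (so the
    family weight is 1 + 0.6/4 = 1.15), plus three unlabeled neighbors."""

    matrix: "object"
    labels: AssociationSet
    families: GroupCatalog
    clusters: GroupCatalog
    disease: str
    query: str
    k: int


@dataclass(frozen=True)
class PaperFixture:
    """Bundle of the worked-example inputs."""

    ontology: Ontology
    printed_ic: ICTable
    liver_neoplasms: str
    pancreatic_neoplasms: str
    breast_neoplasms: str
    mirna_associations: AssociationSet  # DT_u = {LN, BN}, DT_v = {PN, BN}
    family_members: FrozenSet[str]
    family_associations: AssociationSet
    scenario: NeighborScenario


def _neighbor_scenario() -> NeighborScenario:
    from .mirna_similarity import MirnaSimilarityMatrix

    family_pool = tuple(f"mir-f{i}" for i in range(1, 9))
    ids = ("mir-01", "mir-02", "mir-05", "mir-08", "mir-10", "mir-16", "mir-20")
    all_ids = tuple(sorted(ids + family_pool))
    query_sims = {
        "mir-05": 0.6,
        "mir-10": 0.7,
        "mir-20": 0.6,
        "mir-02": 0.5,
        "mir-08": 0.45,
        "mir-16": 0.4,
    }

    def sim(u: str, v: str) -> float:
        if u == "mir-01" and v in query_sims:
            return query_sims[v]
        if v == "mir-01" and u in query_sims:
            return query_sims[u]
        return 0.1

    matrix = MirnaSimilarityMatrix.from_function(all_ids, sim)
    labeled = ("mir-05", "mir-10", "mir-20", "mir-f1", "mir-f2", "mir-f3",
               "mir-f4", "mir-f5")
    labels = AssociationSet((m, "d") for m in labeled)
    families = GroupCatalog(
        kind="family",
        groups={"fam-i": frozenset(("mir-01", "mir-20") + family_pool)},
        factor=4.0,
    )
    return NeighborScenario(
        matrix=matrix,
        labels=labels,
        families=families,
        clusters=GroupCatalog.empty("cluster"),
        disease="d",
        query="mir-01",
        k=6,
    )


def paper_fixture() -> PaperFixture:
    """Reconstruct every worked-example input as first-class objects."""
    ontology = _worked_example_ontology()
    mirna_associations = AssociationSet(
        [
            ("mirna-u", LIVER_NEOPLASMS),
            ("mirna-u", BREAST_NEOPLASMS),
            ("mirna-v", PANCREATIC_NEOPLASMS),
            ("mirna-v", BREAST_NEOPLASMS),
        ]
    )
    family_members = frozenset(f"mir-{i}" for i in range(1, 6))
    family_associations = AssociationSet(
        [
            ("mir-1", "d1"), ("mir-3", "d1"),
            ("mir-1", "d2"), ("mir-2", "d2"), ("mir-4", "d2"), ("mir-5", "d2"),
            ("mir-2", "d3"), ("mir-3", "d3"), ("mir-4", "d3"),
            ("mir-2", "d4"), ("mir-3", "d4"),
            ("mir-3", "d5"), ("mir-5", "d5"),
        ]
    )
    return PaperFixture(
        ontology=ontology,
        printed_ic=ICTable.from_values(PRINTED_IC),
        liver_neoplasms=LIVER_NEOPLASMS,
        pancreatic_neoplasms=PANCREATIC_NEOPLASMS,
        breast_neoplasms=BREAST_NEOPLASMS,
        mirna_associations=mirna_associations,
        family_members=family_members,
        family_associations=family_associations,
        scenario=_neighbor_scenario(),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic corpora.

    Defaults encode the benchmark conditions: 60 miRNAs split over 4
    planted modules, within-module association probability 0.8 against a
    0.05 background, an 8x6 two-level disease hierarchy whose sibling
    leaves form the module disease groups, and module-aligned families and
    genomic clusters of five members each.
    """

    n_mirnas: int = 60
    n_modules: int = 4
    p_in: float = 0.8
    p_out: float = 0.05
    n_parents: int = 8
    leaves_per_parent: int = 6
    n_families: int = 4
    family_size: int = 5
    n_clusters: int = 4
    cluster_size: int = 5
    phenotype_coverage: float = 0.75
    ps_sibling: float = 0.6
    ps_background: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_mirnas", "n_modules", "n_parents", "leaves_per_parent",
            "n_families", "family_size", "n_clusters", "cluster_size",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ParameterError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, "
                f"p_out={self.p_out}"
            )
        if self.n_modules > self.n_parents:
            raise ParameterError("each module needs its own disease parent")
        if self.n_mirnas // self.n_modules < max(self.family_size, self.cluster_size):
            raise ParameterError(
                "modules too small for the requested family/cluster sizes"
            )
        if not (0.0 <= self.phenotype_coverage <= 1.0):
            raise ParameterError("phenotype_coverage must be in [0, 1]")
        for name in ("ps_sibling", "ps_background"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCorpus:
    """In-memory synthetic input bundle plus the generating spec."""

    spec: SyntheticSpec
    planted: bool
    ontology: Ontology
    associations: AssociationSet
    families: GroupCatalog
    loci: Tuple[GenomicLocus, ...]
    phenotypes: PhenotypeSimilarityTable
    phenotype_pairs: Tuple[Tuple[str, str, float], ...]
    mapping: Dict[str, FrozenSet[str]]
    module_of: Dict[str, int]
    module_diseases: Tuple[Tuple[str, ...], ...]

    @property
    def clusters(self) -> GroupCatalog:
        return build_clusters(self.loci)

    def write(self, out_dir) -> Dict[str, Path]:
        """Write the bundle in the dialects the readers accept; reruns with
        the same spec produce byte-identical files."""
        from . import io as hdmp_io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ontology": out / "ontology.tsv",
            "associations": out / "associations.tsv",
            "families": out / "families.tsv",
            "loci": out / "loci.gff3",
            "phenotypes": out / "phenotypes.tsv",
            "mapping": out / "mapping.tsv",
        }
        hdmp_io.write_ontology_tsv(self.ontology, paths["ontology"])
        hdmp_io.write_associations_tsv(self.associations, paths["associations"])
        hdmp_io.write_family_tsv(self.families, paths["families"])
        hdmp_io.write_gff3(self.loci, paths["loci"])
        hdmp_io.write_phenotype_tsv(self.phenotype_pairs, paths["phenotypes"])
        hdmp_io.write_mapping_tsv(self.mapping, paths["mapping"])
        return paths


def _synthetic_ontology(spec: SyntheticSpec) -> Tuple[Ontology, List[List[str]]]:
    terms: List[DiseaseTerm] = []
    leaves_by_parent: List[List[str]] = []
    leaf_no = 0
    for p in range(spec.n_parents):
        parent_tree = f"C{p + 1:02d}"
        terms.append(
            DiseaseTerm(
                f"G{p + 1:03d}",
                f"disease group {p + 1}",
                frozenset({parent_tree}),
            )
        )
        leaves: List[str] = []
        for l in range(spec.leaves_per_parent):
            leaf_no += 1
            term_id = f"D{leaf_no:03d}"
            terms.append(
                DiseaseTerm(
                    term_id,
                    f"synthetic disease {p + 1}-{l + 1}",
                    frozenset({f"{parent_tree}.{l + 1:03d}"}),
                )
            )
            leaves.append(term_id)
        leaves_by_parent.append(leaves)
    return Ontology(terms), leaves_by_parent


def _generate(spec: SyntheticSpec, planted: bool) -> SyntheticCorpus:
    rng = np.random.default_rng(spec.seed)
    ontology, leaves_by_parent = _synthetic_ontology(spec)
    all_leaves = [leaf for leaves in leaves_by_parent for leaf in leaves]
    module_diseases = tuple(
        tuple(leaves_by_parent[j]) for j in range(spec.n_modules)
    )

    mirnas = [f"hsa-mir-{i + 1:03d}" for i in range(spec.n_mirnas)]
    module_of = {m: i % spec.n_modules for i, m in enumerate(mirnas)}

    pairs: List[Tuple[str, str]] = []
    for m in mirnas:
        own = set(module_diseases[module_of[m]]) if planted else set()
        mine: List[str] = []
        for d in all_leaves:
            p = (spec.p_in if d in own else spec.p_out) if planted else spec.p_in
            if rng.random() < p:
                mine.append(d)
        if not mine:
            fallback = sorted(own) if own else all_leaves
            mine.append(fallback[int(rng.integers(len(fallback)))])
        pairs.extend((m, d) for d in mine)
    associations = AssociationSet(pairs)

    # module-aligned families and clusters; members never straddle modules,
    # and family/cluster memberships within a module stay disjoint
    used_family: Dict[int, set] = {j: set() for j in range(spec.n_modules)}
    family_groups: Dict[str, FrozenSet[str]] = {}
    for f in range(spec.n_families):
        j = f % spec.n_modules
        candidates = [
            m for m in mirnas if module_of[m] == j and m not in used_family[j]
        ]
        if len(candidates) < spec.family_size:
            continue
        chosen = sorted(
            rng.choice(len(candidates), size=spec.family_size, replace=False)
        )
        members = frozenset(candidates[i] for i in chosen)
        used_family[j] |= set(members)
        family_groups[f"fam-{f + 1:02d}"] = members
    families = GroupCatalog(kind="family", groups=family_groups)

    used_cluster: Dict[int, set] = {j: set() for j in range(spec.n_modules)}
    loci: List[GenomicLocus] = []
    scattered: List[str] = []
    for c in range(spec.n_clusters):
        j = c % spec.n_modules
        candidates = [
            m for m in mirnas if module_of[m] == j and m not in used_cluster[j]
        ]
        if len(candidates) < spec.cluster_size:
            continue
        chosen = sorted(
            rng.choice(len(candidates), size=spec.cluster_size, replace=False)
        )
        members = [candidates[i] for i in chosen]
        used_cluster[j] |= set(members)
        position = 10_000
        for m in members:
            length = int(rng.integers(60, 120))
            loci.append(
                GenomicLocus(m, f"chr{c + 1}", position, position + length, "+")
            )
            position += length + int(rng.integers(1_000, 15_000))
    clustered = {locus.mirna_id for locus in loci}
    scattered = [m for m in mirnas if m not in clustered]
    for i, m in enumerate(scattered):  # isolated precursors, far apart
        start = 1_000_000 + i * 1_000_000
        loci.append(GenomicLocus(m, "chrU", start, start + 80, "+"))

    mapped_mask = rng.random(len(all_leaves)) < spec.phenotype_coverage
    mapping: Dict[str, FrozenSet[str]] = {}
    pheno_of: Dict[str, str] = {}
    for i, d in enumerate(all_leaves):
        if mapped_mask[i]:
            pheno = f"OMIM:{600000 + i}"
            mapping[d] = frozenset({pheno})
            pheno_of[d] = pheno
    parent_of = {
        leaf: p
        for p, leaves in enumerate(leaves_by_parent)
        for leaf in leaves
    }
    pheno_pairs: List[Tuple[str, str, float]] = []
    mapped = sorted(pheno_of)
    for i, a in enumerate(mapped):
        for b in mapped[i + 1:]:
            value = (
                spec.ps_sibling
                if parent_of[a] == parent_of[b]
                else spec.ps_background
            )
            pheno_pairs.append((pheno_of[a], pheno_of[b], value))
    phenotypes = PhenotypeSimilarityTable(pheno_pairs)

    return SyntheticCorpus(
        spec=spec,
        planted=planted,
        ontology=ontology,
        associations=associations,
        families=families,
        loci=tuple(loci),
        phenotypes=phenotypes,
        phenotype_pairs=tuple(pheno_pairs),
        mapping=mapping,
        module_of=module_of,
        module_diseases=module_diseases,
    )


def generate_corpus(spec: Optional[SyntheticSpec] = None) -> SyntheticCorpus:
    """A corpus with planted disease modules (signal present)."""
    return _generate(spec if spec is not None else SyntheticSpec(), planted=True)


def null_corpus(spec: Optional[SyntheticSpec] = None) -> SyntheticCorpus:
    """A corpus whose associations ignore the ontology structure entirely:
    every (miRNA, disease) pair is drawn at the same probability
    ``spec.p_in`` (set p_in == p_out for a fully specified null)."""
    if spec is None:
        spec = SyntheticSpec(p_in=0.2, p_out=0.2)
    return _generate(spec, planted=False)


DEFAULT_SYNTHETIC_MIN_LABELS = 8  # eligibility floor at synthetic scale


def evaluate_corpus(
    corpus: SyntheticCorpus,
    config=None,
    min_labels: int = DEFAULT_SYNTHETIC_MIN_LABELS,
    n_folds: int = 5,
    seed: int = 0,
    use_phenotypes: bool = True,
):
    """Run the full pipeline on a synthetic corpus and cross-validate.

    Composes the cached pairwise disease similarity (ic scheme, fused with
    the corpus phenotype table when ``use_phenotypes``), the miRNA
    similarity matrix, the family/cluster catalogs restricted to the
    corpus miRNAs, and per-disease 5-fold cross-validation with
    leakage-free per-fold matrix refreshes.
    """
    from .disease_similarity import PairwiseDiseaseSimilarity
    from .evaluation import evaluate_cv
    from .mirna_similarity import build_similarity_matrix

    pairwise = PairwiseDiseaseSimilarity(
        corpus.ontology,
        phenotypes=corpus.phenotypes if use_phenotypes else None,
        mapping=corpus.mapping if use_phenotypes else None,
    )
    matrix = build_similarity_matrix(corpus.associations, pairwise)
    mirnas = corpus.associations.mirnas
    families = corpus.families.restrict_to(mirnas)
    clusters = corpus.clusters.restrict_to(mirnas)
    return evaluate_cv(
        corpus.associations,
        matrix,
        families,
        clusters,
        config,
        min_labels=min_labels,
        n_folds=n_folds,
        seed=seed,
        disease_sim=pairwise,
    )
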