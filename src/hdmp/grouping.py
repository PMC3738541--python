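"""miRNA families and genomic clusters, and their per-disease weights.

Members of one miRNA family share a seed region and hence target sets;
members of one genomic cluster (precursors within 20 kb on a chromosome)
are typically co-transcribed.  Both are therefore enriched for shared
disease associations, which the predictor exploits: for a group g and a
disease d, the fraction of group members already labeled with d,

    r_g(d) = |{m in g : m labeled with d}| / |g|,

is turned into a multiplicative weight  w_g(d) = 1 + r_g(d) / factor,
bounded in [1, 1 + 1/factor].  The adjustment factor (alpha for families,
beta for clusters) defaults to 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

from .errors import EmptyGroupError, ParameterError
from .mirna_similarity import AssociationSet, normalize_mirna_id

__all__ = [
    "GenomicLocus",
    "GroupCatalog",
    "build_clusters",
    "group_rate",
    "group_weight",
    "compute_group_weights",
]

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_GAP = 20_000  # bp; max inter-precursor gap within a cluster


@dataclass(frozen=True)
class GenomicLocus:
    """One precursor locus; 1-based inclusive coordinates (GFF3 convention)."""

    mirna_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_id", normalize_mirna_id(self.mirna_id))
        if not self.chromosome:
            raise ParameterError(f"locus of {self.mirna_id!r} has empty chromosome")
        if self.start > self.end:
            raise ParameterError(
                f"locus of {self.mirna_id!r} has start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class GroupCatalog:
    """Named miRNA groups of one kind ('family' or 'cluster').

    Each miRNA belongs to at most one group; duplicate family membership
    keeps the first group encountered (with a warning), and clusters are
    unioned upstream.  ``factor`` is the default weight-adjustment factor.
    """

    kind: str
    groups: Mapping[str, FrozenSet[str]]
    factor: float = 4.0
    _member_to_group: Dict[str, str] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.kind not in ("family", "cluster"):
            raise ParameterError(f"unknown group kind {self.kind!r}")
        if self.factor <= 0:
            raise ParameterError(f"adjustment factor must be > 0, got {self.factor}")
        cleaned: Dict[str, FrozenSet[str]] = {}
        membership: Dict[str, str] = {}
        for gid in sorted(self.groups):
            members = frozenset(normalize_mirna_id(m) for m in self.groups[gid])
            if not members:
                raise EmptyGroupError(f"{self.kind} {gid!r} has no members")
            kept = []
            for m in sorted(members):
                if m in membership:
                    logger.warning(
                        "miRNA %s already in %s %s; ignoring membership in %s",
                        m, self.kind, membership[m], gid,
                    )
                else:
                    membership[m] = gid
                    kept.append(m)
            if kept:
                cleaned[gid] = frozenset(kept)
        object.__setattr__(self, "groups", cleaned)
        object.__setattr__(self, "_member_to_group", membership)

    @classmethod
    def empty(cls, kind: str) -> "GroupCatalog":
        catalog = object.__new__(cls)
        object.__setattr__(catalog, "kind", kind)
        object.__setattr__(catalog, "groups", {})
        object.__setattr__(catalog, "factor", 4.0)
        object.__setattr__(catalog, "_member_to_group", {})
        return catalog

    def group_of(self, mirna: str) -> Optional[str]:
        return self._member_to_group.get(normalize_mirna_id(mirna))

    def shared_group(self, u: str, v: str) -> Optional[str]:
        gu = self.group_of(u)
        if gu is not None and gu == self.group_of(v):
            return gu
        return None

    def restrict_to(self, mirnas: Iterable[str]) -> "GroupCatalog":
        """Restrict membership to the given miRNA universe (e.g. the
        association set) before group sizes enter any rate."""
        universe = {normalize_mirna_id(m) for m in mirnas}
        groups = {}
        for gid, members in self.groups.items():
            kept = members & universe
            if kept:
                groups[gid] = kept
        return GroupCatalog(kind=self.kind, groups=groups, factor=self.factor)

    def __len__(self) -> int:
        return len(self.groups)


def build_clusters(
    loci: Iterable[GenomicLocus], max_gap: int = DEFAULT_CLUSTER_GAP
) -> GroupCatalog:
    """Chain loci into genomic clusters by single linkage.

    Per chromosome, loci sorted by start are merged while the inter-interval
    gap (``next.start - prev.end - 1``, floored at 0 for overlaps) stays
    within ``max_gap``; strand is ignored.  A miRNA with several loci joins
    every chain any locus falls in, and chains sharing a miRNA are unioned.
    Singleton clusters are discarded: a lone miRNA can never share its
    cluster with a neighbor, so it carries no weight.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    by_chrom: Dict[str, List[GenomicLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)

    chains: List[set] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.mirna_id))
        current: set = set()
        reach = None  # rightmost end of the open chain
        for locus in ordered:
            if reach is not None and max(0, locus.start - reach - 1) <= max_gap:
                current.add(locus.mirna_id)
                reach = max(reach, locus.end)
            else:
                if current:
                    chains.append(current)
                current = {locus.mirna_id}
                reach = locus.end
        if current:
            chains.append(current)

    # union chains sharing a miRNA (multi-locus precursors)
    merged: List[set] = []
    for chain in chains:
        absorbed = chain
        remaining = []
        for existing in merged:
            if existing & absorbed:
                absorbed = absorbed | existing
            else:
                remaining.append(existing)
        remaining.append(absorbed)
        merged = remaining

    multi = sorted(
        (tuple(sorted(c)) for c in merged if len(c) > 1), key=lambda t: t
    )
    groups = {
        f"cluster-{i + 1:03d}": frozenset(members)
        for i, members in enumerate(multi)
    }
    return GroupCatalog(kind="cluster", groups=groups)


def group_rate(group: Iterable[str], disease: str, labels: AssociationSet) -> float:
    """Fraction of group members labeled with ``disease``."""
    members = {normalize_mirna_id(m) for m in group}
    if not members:
        raise EmptyGroupError("cannot compute a rate for an empty group")
    labeled = labels.labeled(disease)
    return len(members & labeled) / len(members)


def group_weight(rate: float, factor: float) -> float:
    """w = 1 + rate / factor; bounded in [1, 1 + 1/factor]."""
    if factor <= 0:
        raise ParameterError(f"adjustment factor must be > 0, got {factor}")
    if not (0.0 <= rate <= 1.0):
        raise ParameterError(f"rate must be in [0, 1], got {rate}")
    if math.isinf(factor):
        return 1.0
    return 1.0 + rate / factor


def compute_group_weights(
    catalog: GroupCatalog,
    labels: AssociationSet,
    diseases: Optional[Iterable[str]] = None,
    factor: Optional[float] = None,
) -> Dict[Tuple[str, str], float]:
    """Weight table (group id, disease) -> w for every group and disease.

    ``factor`` overrides the catalog's default adjustment factor.  During
    cross-validation the caller passes training labels only, so held-out
    associations never leak into a rate.
    """
    factor = catalog.factor if factor is None else factor
    disease_list = tuple(diseases) if diseases is not None else labels.diseases
    table: Dict[Tuple[str, str], float] = {}
    for gid, members in catalog.groups.items():
        for d in disease_list:
            table[(gid, d)] = group_weight(group_rate(members, d, labels), factor)
    return table
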