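"""Readers and writers for every input dialect.

TSV dialect throughout: tab-separated, UTF-8, ``#`` comment lines, no
quoting.  Genomic coordinates are 1-based inclusive (GFF3 convention).
The ontology reader additionally accepts MeSH ASCII descriptor records
(``MH = ``/``MN = ``/``UI = `` lines), and the family reader accepts
miFam-style stanzas (``AC``/``ID``/``MI`` lines separated by ``//``).
Each reader re-reads its own writer's output losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

from .disease_similarity import PhenotypeSimilarityTable
from .errors import EmptyInputError, ParameterError, ParseError
from .grouping import GenomicLocus, GroupCatalog
from .mirna_similarity import AssociationSet
from .ontology import DiseaseTerm, Ontology

__all__ = [
    "read_ontology",
    "read_associations",
    "read_family",
    "read_gff3_loci",
    "read_group_inputs",
    "read_phenotype_inputs",
    "write_ontology_tsv",
    "write_associations_tsv",
    "write_family_tsv",
    "write_gff3",
    "write_phenotype_tsv",
    "write_mapping_tsv",
]

logger = logging.getLogger(__name__)


def _data_lines(path) -> List[Tuple[int, str]]:
    """(1-based line number, stripped line) for non-blank, non-comment lines."""
    out = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


# ---------------------------------------------------------------- ontology

def _read_ontology_tsv(path, lines) -> Ontology:
    header = lines[0][1].split("\t")
    wanted = ["term_id", "name", "tree_numbers"]
    if [h.strip().lower() for h in header[:3]] != wanted:
        raise ParseError(
            f"ontology TSV must start with header {wanted}", path, lines[0][0]
        )
    terms = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError("expected 3 tab-separated columns", path, lineno)
        term_id, name, tree_field = fields[0].strip(), fields[1].strip(), fields[2]
        tree_numbers = frozenset(
            tn.strip() for tn in tree_field.split(";") if tn.strip()
        )
        if not tree_numbers:
            raise ParseError(f"term {term_id!r} has no tree numbers", path, lineno)
        terms.append(DiseaseTerm(term_id, name, tree_numbers))
    return Ontology(terms)


def _read_ontology_mesh(path, lines) -> Ontology:
    records: List[Dict[str, List[str]]] = []
    current: Optional[Dict[str, List[str]]] = None
    for lineno, line in lines:
        if line.startswith("*NEWRECORD"):
            current = {"MH": [], "MN": [], "UI": []}
            records.append(current)
            continue
        if " = " not in line:
            raise ParseError("expected 'KEY = value' record line", path, lineno)
        key, _, value = line.partition(" = ")
        key = key.strip()
        if key not in ("MH", "MN", "UI"):
            continue
        if current is None:  # header-less single-record files are accepted
            current = {"MH": [], "MN": [], "UI": []}
            records.append(current)
        current[key].append(value.strip())
    terms = []
    for record in records:
        if not record["MH"] or not record["MN"]:
            raise ParseError("descriptor record lacks MH or MN lines", path)
        name = record["MH"][0]
        term_id = record["UI"][0] if record["UI"] else name
        terms.append(DiseaseTerm(term_id, name, frozenset(record["MN"])))
    return Ontology(terms)


def read_ontology(path) -> Ontology:
    """Parse a disease ontology table, auto-detecting TSV vs MeSH ASCII."""
    lines = _data_lines(path)
    if not lines:
        raise EmptyInputError(f"ontology file {path} is empty")
    first = lines[0][1]
    if first.startswith("*NEWRECORD") or first.split(" = ")[0].strip() in (
        "MH", "UI", "RECTYPE",
    ):
        return _read_ontology_mesh(path, lines)
    return _read_ontology_tsv(path, lines)


def write_ontology_tsv(ontology: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("term_id\tname\ttree_numbers\n")
        for term in sorted(ontology, key=lambda t: t.term_id):
            trees = ";".join(sorted(term.tree_numbers))
            handle.write(f"{term.term_id}\t{term.name}\t{trees}\n")


# ------------------------------------------------------------ associations

def read_associations(path, ontology: Optional[Ontology] = None) -> AssociationSet:
    """Read 2-column miRNA-disease pairs; dedupe and normalize.

    With an ontology, pairs whose disease cannot be resolved (by id or
    name) are dropped with logged counts and the rest are canonicalized to
    term ids — mirroring the curation step that discards records with
    unrecognized disease or miRNA names.
    """
    lines = _data_lines(path)
    if not lines:
        raise EmptyInputError(f"association file {path} is empty")
    if lines[0][1].split("\t")[0].strip().lower() in ("mirna_id", "mirna"):
        lines = lines[1:]
    pairs = []
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError("expected 'mirna<TAB>disease'", path, lineno)
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise EmptyInputError(f"association file {path} has no data rows")
    associations = AssociationSet(pairs)
    if ontology is not None:
        associations, _ = associations.filter_to_ontology(ontology)
    return associations


def write_associations_tsv(associations: AssociationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("mirna_id\tdisease\n")
        for m, d in sorted(associations.pairs):
            handle.write(f"{m}\t{d}\n")


# ----------------------------------------------------------------- groups

def _read_family_mifam(path, lines) -> GroupCatalog:
    groups: Dict[str, FrozenSet[str]] = {}
    accession: Optional[str] = None
    family_id: Optional[str] = None
    members: List[str] = []

    def flush(lineno):
        nonlocal accession, family_id, members
        if not members:
            accession = family_id = None
            return
        gid = family_id or accession
        if gid is None:
            raise ParseError("family stanza lacks ID/AC lines", path, lineno)
        groups[gid] = frozenset(members)
        accession, family_id, members = None, None, []

    last_lineno = 0
    for lineno, line in lines:
        last_lineno = lineno
        if line.startswith("//"):
            flush(lineno)
            continue
        tag, *rest = line.split()
        if tag == "AC" and rest:
            accession = rest[0]
        elif tag == "ID" and rest:
            family_id = rest[0]
        elif tag == "MI":
            if not rest:
                raise ParseError("MI line lacks a miRNA name", path, lineno)
            members.append(rest[-1])
    flush(last_lineno)
    return GroupCatalog(kind="family", groups=groups)


def read_family(path) -> GroupCatalog:
    """Parse miRNA families from miFam stanzas or 2-column TSV
    ``family_id<TAB>mirna_id``; ``None``/missing path yields an empty
    catalog (all family weights 1)."""
    if path is None:
        return GroupCatalog.empty("family")
    lines = _data_lines(path)
    if not lines:
        return GroupCatalog.empty("family")
    first_tag = lines[0][1].split()[0]
    if first_tag in ("AC", "ID", "MI"):
        return _read_family_mifam(path, lines)
    if lines[0][1].split("\t")[0].strip().lower() in ("family_id", "family"):
        lines = lines[1:]
    groups: Dict[str, set] = {}
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError("expected 'family_id<TAB>mirna_id'", path, lineno)
        groups.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return GroupCatalog(
        kind="family", groups={g: frozenset(ms) for g, ms in groups.items()}
    )


def write_family_tsv(catalog: GroupCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("family_id\tmirna_id\n")
        for gid in sorted(catalog.groups):
            for m in sorted(catalog.groups[gid]):
                handle.write(f"{gid}\t{m}\n")


GFF_FEATURE = "miRNA_primary_transcript"


def read_gff3_loci(path) -> Tuple[GenomicLocus, ...]:
    """Precursor loci from a miRBase-style GFF3: ``miRNA_primary_transcript``
    features with a ``Name=`` attribute as the miRNA id."""
    loci = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError("GFF3 line must have 9 columns", path, lineno)
            if fields[2] != GFF_FEATURE:
                continue
            attributes = dict(
                part.split("=", 1)
                for part in fields[8].split(";")
                if "=" in part
            )
            name = attributes.get("Name")
            if not name:
                raise ParseError(
                    f"{GFF_FEATURE} record lacks a Name= attribute", path, lineno
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            try:
                loci.append(
                    GenomicLocus(name, fields[0], start, end, fields[6])
                )
            except ParameterError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return tuple(loci)


def write_gff3(loci: Iterable[GenomicLocus], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##gff-version 3\n")
        ordered = sorted(loci, key=lambda l: (l.chromosome, l.start, l.mirna_id))
        for i, locus in enumerate(ordered, start=1):
            handle.write(
                f"{locus.chromosome}\t.\t{GFF_FEATURE}\t{locus.start}\t"
                f"{locus.end}\t.\t{locus.strand}\t.\t"
                f"ID=MI{i:07d};Name={locus.mirna_id}\n"
            )


def read_group_inputs(
    family_path=None, gff3_path=None, max_gap: int = 20_000
) -> Tuple[GroupCatalog, GroupCatalog]:
    """Family and cluster catalogs; either input may be absent (empty
    catalog, every weight 1)."""
    from .grouping import build_clusters

    families = read_family(family_path)
    if gff3_path is None:
        clusters = GroupCatalog.empty("cluster")
    else:
        clusters = build_clusters(read_gff3_loci(gff3_path), max_gap=max_gap)
    return families, clusters


# -------------------------------------------------------------- phenotypes

def read_phenotype_inputs(
    matrix_path=None, mapping_path=None
) -> Tuple[Optional[PhenotypeSimilarityTable], Optional[Dict[str, FrozenSet[str]]]]:
    """Phenotype similarity table plus term->phenotype mapping.

    Both present: parsed and validated (similarities must lie in [0, 1];
    symmetric closure is implied by order-normalized storage).  Both
    absent: ``(None, None)`` — the disease similarity then falls back to
    its semantic component globally.
    """
    if matrix_path is None and mapping_path is None:
        return None, None
    if matrix_path is None or mapping_path is None:
        raise ParameterError(
            "phenotype matrix and mapping must be given together (or neither)"
        )
    triples = []
    for lineno, line in _data_lines(matrix_path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                "expected 'pheno_a<TAB>pheno_b<TAB>similarity'",
                matrix_path, lineno,
            )
        if fields[2].strip().lower() == "similarity":
            continue
        try:
            value = float(fields[2])
        except ValueError:
            raise ParseError("non-numeric similarity", matrix_path, lineno) from None
        if not (0.0 <= value <= 1.0):
            raise ParseError(
                f"similarity for ({fields[0]!r}, {fields[1]!r}) outside "
                f"[0, 1]: {value}",
                matrix_path, lineno,
            )
        triples.append((fields[0].strip(), fields[1].strip(), value))
    table = PhenotypeSimilarityTable(triples)

    mapping: Dict[str, set] = {}
    for lineno, line in _data_lines(mapping_path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                "expected 'term_id<TAB>phenotype_id'", mapping_path, lineno
            )
        if fields[1].strip().lower() == "phenotype_id":
            continue
        mapping.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return table, {t: frozenset(p) for t, p in mapping.items()}


def write_phenotype_tsv(pairs: Iterable[Tuple[str, str, float]], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("pheno_a\tpheno_b\tsimilarity\n")
        for a, b, value in sorted(pairs):
            handle.write(f"{a}\t{b}\t{value:.6g}\n")


def write_mapping_tsv(mapping: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("term_id\tphenotype_id\n")
        for term in sorted(mapping):
            for pheno in sorted(mapping[term]):
                handle.write(f"{term}\t{pheno}\n")
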