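"""Readers and the population pipeline.

Annotation (GAF 2.x), interaction (PSI-MI TAB 2.5) and tabular (TSV)
sources are read into typed records, filtered through the canonical ID
mapping (unmappable entities are dropped, never invented), reduced to the
protein sets of interest — ``core`` proteins annotated to a Biological
Process term of the seed ontology, extended one round by association via
interactions, shared pathways and orthology — and finally written into the
knowledge graph as asserted statements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .model import (
    ACTIVATES,
    ENCODED_BY,
    HAS_FUNCTION,
    HAS_INTERACTION_TYPE,
    HAS_MODIFIED_RESIDUE,
    HAS_PARTICIPANT,
    IN_TAXON,
    LOCATED_IN,
    MEMBER_OF_PATHWAY,
    PARTICIPATES_IN,
    REGULATES,
    REPRESSES,
    Curie,
    GraphError,
    KnowledgeGraph,
    TermNode,
    logger,
)

ASPECT_PREDICATES = {
    "P": PARTICIPATES_IN,
    "F": HAS_FUNCTION,
    "C": LOCATED_IN,
}


# --------------------------------------------------------------------------
# Typed records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRecord:
    protein: Curie
    go_term: Curie
    aspect: str  # P / F / C
    evidence_code: str = ""
    taxon: Curie | None = None

    def __post_init__(self) -> None:
        if self.aspect not in ("P", "F", "C"):
            raise GraphError(f"annotation aspect must be P/F/C, got {self.aspect!r}")
        if self.go_term.namespace != "GO":
            raise GraphError(f"annotation term {self.go_term} is not a GO term")


@dataclass(frozen=True)
class InteractionRecord:
    interaction_id: Curie  # intact namespace
    participant_a: Curie
    participant_b: Curie
    interaction_type: Curie  # MI namespace

    def __post_init__(self) -> None:
        if self.interaction_type.namespace != "MI":
            raise GraphError(
                f"interaction type {self.interaction_type} is not an MI term")

    @property
    def is_self_interaction(self) -> bool:
        return self.participant_a == self.participant_b


@dataclass(frozen=True)
class PathwayMembership:
    protein: Curie
    pathway: Curie

    def __post_init__(self) -> None:
        if self.pathway.namespace != "KEGG":
            raise GraphError(f"pathway {self.pathway} is not a KEGG id")


@dataclass(frozen=True)
class OrthologyPair:
    """Unordered pair of orthologous proteins."""

    protein_a: Curie
    protein_b: Curie

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise GraphError(f"orthology pair must relate distinct proteins "
                             f"({self.protein_a})")

    def as_frozenset(self) -> frozenset[Curie]:
        return frozenset((self.protein_a, self.protein_b))


@dataclass(frozen=True)
class ProteinInfo:
    accession: Curie
    gene: Curie | None = None
    symbol: str = ""
    modified_residues: tuple[str, ...] = ()
    taxon: Curie | None = None

    def __post_init__(self) -> None:
        if self.gene is not None and self.gene.namespace != "NCBIGene":
            raise GraphError(f"gene {self.gene} must be an NCBIGene id")


MODES = ("activator", "repressor", "unknown")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A DbTF -> target-gene link from a curated regulatory resource."""

    regulator: Curie
    target_gene: str  # gene symbol, normalized upper-case
    mode: str = "unknown"
    source_db: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_gene", self.target_gene.strip().upper())
        mode = (self.mode or "unknown").strip().lower()
        if mode not in MODES:
            mode = "unknown"
        object.__setattr__(self, "mode", mode)


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

class ReadResult(list):
    """A list of records plus per-row accounting of skipped input lines."""

    def __init__(self, records: Iterable, skipped: int = 0,
                 warnings: Sequence[str] = ()) -> None:
        super().__init__(records)
        self.skipped = int(skipped)
        self.warnings = list(warnings)


def _iter_lines(stream) -> Iterator[str]:
    if isinstance(stream, (str, bytes)):
        import io
        stream = io.StringIO(stream if isinstance(stream, str) else stream.decode())
    yield from stream


def read_gaf(stream) -> ReadResult:
    """Read a GAF 2.x gene-association file.

    ``!`` comment lines are ignored; data rows have 17 tab-separated
    columns (15-column GAF 2.0 rows are tolerated).  Malformed rows —
    wrong column count, bad aspect, non-GO term — are skipped and counted.
    """
    records: list[AnnotationRecord] = []
    warnings: list[str] = []
    skipped = 0
    for lineno, raw in enumerate(_iter_lines(stream), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            skipped += 1
            warnings.append(f"line {lineno}: expected >=15 columns, got {len(cols)}")
            continue
        db, db_id, _symbol, _qual, go_id = cols[0], cols[1], cols[2], cols[3], cols[4]
        evidence, aspect, taxon_field = cols[6], cols[8], cols[12]
        try:
            go_term = Curie.parse(go_id)
            if go_term.namespace != "GO":
                raise GraphError(f"not a GO id: {go_id}")
            taxon = None
            if taxon_field:
                first = taxon_field.split("|")[0]
                taxon = Curie("NCBITaxon", first.split(":")[-1])
            rec = AnnotationRecord(
                protein=Curie(db, db_id),
                go_term=go_term,
                aspect=aspect,
                evidence_code=evidence,
                taxon=taxon,
            )
        except GraphError as exc:
            skipped += 1
            warnings.append(f"line {lineno}: {exc}")
            continue
        records.append(rec)
    if skipped:
        logger.warning("read_gaf: skipped %d malformed rows", skipped)
    return ReadResult(records, skipped, warnings)


_MI_TYPE_RE = re.compile(r"(MI:\d+)")


def _parse_mitab_id(field_value: str) -> Curie:
    # e.g. 'uniprotkb:P16220' -> UniProtKB:P16220
    first = field_value.split("|")[0].strip()
    if ":" not in first:
        raise GraphError(f"unparseable interactor id {field_value!r}")
    ns, local = first.split(":", 1)
    ns = {"uniprotkb": "UniProtKB", "intact": "intact"}.get(ns.lower(), ns)
    return Curie(ns, local)


def read_mitab(stream) -> ReadResult:
    """Read PSI-MI TAB 2.5.

    Only the interactor ids (columns 1-2), the interaction type (column
    12, e.g. ``psi-mi:"MI:0407"(direct interaction)``) and the interaction
    id (column 14) are consumed.  Rows without a parseable MI type or
    interaction id are skipped and counted.
    """
    records: list[InteractionRecord] = []
    warnings: list[str] = []
    skipped = 0
    for lineno, raw in enumerate(_iter_lines(stream), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 14:
            skipped += 1
            warnings.append(f"line {lineno}: expected >=14 columns, got {len(cols)}")
            continue
        try:
            a = _parse_mitab_id(cols[0])
            b = _parse_mitab_id(cols[1])
            m = _MI_TYPE_RE.search(cols[11])
            if not m:
                raise GraphError(f"no MI type in {cols[11]!r}")
            itype = Curie.parse(m.group(1))
            iid = _parse_mitab_id(cols[13])
            if iid.namespace != "intact":
                iid = Curie("intact", iid.local_id)
            rec = InteractionRecord(iid, a, b, itype)
        except GraphError as exc:
            skipped += 1
            warnings.append(f"line {lineno}: {exc}")
            continue
        records.append(rec)
    if skipped:
        logger.warning("read_mitab: skipped %d malformed rows", skipped)
    return ReadResult(records, skipped, warnings)


def read_table(stream, schema: Sequence[str]) -> pd.DataFrame:
    """Read a UTF-8, tab-delimited table with a header row.

    *schema* lists required columns; missing ones raise an error naming
    them.  Extra columns are preserved.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, comment=None,
                     keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise GraphError(f"table is missing required columns: {missing}")
    return df


def read_pathways(stream) -> ReadResult:
    df = read_table(stream, ["protein", "pathway"])
    return ReadResult(
        PathwayMembership(Curie.parse(r.protein), Curie.parse(r.pathway))
        for r in df.itertuples()
    )


def read_orthology(stream) -> ReadResult:
    df = read_table(stream, ["protein_a", "protein_b"])
    return ReadResult(
        OrthologyPair(Curie.parse(r.protein_a), Curie.parse(r.protein_b))
        for r in df.itertuples()
    )


def read_protein_info(stream) -> ReadResult:
    df = read_table(stream, ["accession", "gene", "symbol",
                             "modified_residues", "taxon"])
    records = []
    for r in df.itertuples():
        residues = tuple(x for x in r.modified_residues.split("|") if x)
        records.append(ProteinInfo(
            accession=Curie.parse(r.accession),
            gene=Curie.parse(r.gene) if r.gene else None,
            symbol=r.symbol,
            modified_residues=residues,
            taxon=Curie.parse(r.taxon) if r.taxon else None,
        ))
    return ReadResult(records)


def read_regulatory_edges(stream) -> ReadResult:
    df = read_table(stream, ["regulator", "target_gene", "mode", "source_db"])
    return ReadResult(
        RegulatoryEdge(Curie.parse(r.regulator), r.target_gene, r.mode,
                       r.source_db or "other")
        for r in df.itertuples()
    )


def read_dbtf_catalog(stream) -> set[Curie]:
    df = read_table(stream, ["protein"])
    return {Curie.parse(r.protein) for r in df.itertuples()}


def read_membership(stream) -> set[Curie]:
    df = read_table(stream, ["protein"])
    return {Curie.parse(r.protein) for r in df.itertuples()}


# --------------------------------------------------------------------------
# ID mapping
# --------------------------------------------------------------------------

@dataclass
class IdMapping:
    """Mapping (source namespace, source id) -> canonical protein Curie.

    Lookups of unmapped keys return ``None``; an id is never fabricated.
    """

    entries: dict[tuple[str, str], Curie] = field(default_factory=dict)

    @classmethod
    def from_table(cls, stream) -> "IdMapping":
        df = read_table(stream, ["source_namespace", "source_id", "canonical"])
        return cls({
            (r.source_namespace, r.source_id): Curie.parse(r.canonical)
            for r in df.itertuples()
        })

    @classmethod
    def identity(cls, curies: Iterable[Curie]) -> "IdMapping":
        return cls({(c.namespace, c.local_id): c for c in curies})

    def get(self, curie: Curie) -> Curie | None:
        return self.entries.get((curie.namespace, curie.local_id))

    def __len__(self) -> int:
        return len(self.entries)


def _mapped_fields(record) -> tuple[str, ...]:
    """Which Curie fields of a record must pass the ID mapping."""
    if isinstance(record, AnnotationRecord):
        return ("protein",)
    if isinstance(record, InteractionRecord):
        return ("participant_a", "participant_b")
    if isinstance(record, PathwayMembership):
        return ("protein",)
    if isinstance(record, OrthologyPair):
        return ("protein_a", "protein_b")
    if isinstance(record, ProteinInfo):
        return ("accession",)
    if isinstance(record, RegulatoryEdge):
        return ("regulator",)
    raise GraphError(f"cannot ID-map record of type {type(record).__name__}")


def apply_id_mapping(records: Iterable, mapping: IdMapping) -> tuple[list, int]:
    """Canonicalize identifiers; drop records with any unmappable one.

    Returns (kept records with canonical Curies substituted, dropped count).
    Dropping is the contract — unmapped entities are omitted, not guessed.
    """
    kept: list = []
    dropped = 0
    for rec in records:
        subs = {}
        ok = True
        for fname in _mapped_fields(rec):
            canonical = mapping.get(getattr(rec, fname))
            if canonical is None:
                ok = False
                break
            subs[fname] = canonical
        if not ok:
            dropped += 1
            continue
        kept.append(replace(rec, **subs))
    return kept, dropped


# --------------------------------------------------------------------------
# Protein selection
# --------------------------------------------------------------------------

def select_core_proteins(annotations: Iterable[AnnotationRecord],
                         seed: KnowledgeGraph) -> set[Curie]:
    """Proteins with >=1 Biological Process annotation to a seed-ontology term.

    These 'core' proteins anchor the association-based extension.
    """
    seed_terms = set(seed.nodes)
    return {
        rec.protein
        for rec in annotations
        if rec.aspect == "P" and rec.go_term in seed_terms
    }


def extend_by_association(core: set[Curie],
                          interactions: Iterable[InteractionRecord] = (),
                          pathways: Iterable[PathwayMembership] = (),
                          orthology: Iterable[OrthologyPair] = (),
                          rounds: int = 1) -> set[Curie]:
    """Extend *core* by one round (default) of association.

    Adds every protein that interacts with, shares a KEGG pathway with, or
    is orthologous to a core protein.  A single round: partners of partners
    are not pulled in unless *rounds* is raised.
    """
    interactions = list(interactions)
    pathways = list(pathways)
    orthology = list(orthology)

    by_pathway: dict[Curie, set[Curie]] = {}
    for pm in pathways:
        by_pathway.setdefault(pm.pathway, set()).add(pm.protein)

    selected = set(core)
    frontier = set(core)
    for _ in range(rounds):
        added: set[Curie] = set()
        for rec in interactions:
            if rec.participant_a in frontier:
                added.add(rec.participant_b)
            if rec.participant_b in frontier:
                added.add(rec.participant_a)
        for pm in pathways:
            if pm.protein in frontier:
                added |= by_pathway[pm.pathway]
        for op in orthology:
            if op.protein_a in frontier:
                added.add(op.protein_b)
            if op.protein_b in frontier:
                added.add(op.protein_a)
        frontier = added - selected
        selected |= added
        if not frontier:
            break
    return selected


# --------------------------------------------------------------------------
# Graph population
# --------------------------------------------------------------------------

@dataclass
class PopulationReport:
    """Per-predicate counts of the statements added by populate_graph."""

    statements_added: dict[str, int] = field(default_factory=dict)
    annotations_outside_seed: int = 0

    def bump(self, predicate_name: str, n: int = 1) -> None:
        self.statements_added[predicate_name] = (
            self.statements_added.get(predicate_name, 0) + n)


def populate_graph(seed: KnowledgeGraph,
                   proteins: set[Curie],
                   annotations: Iterable[AnnotationRecord] = (),
                   interactions: Iterable[InteractionRecord] = (),
                   pathways: Iterable[PathwayMembership] = (),
                   infos: Iterable[ProteinInfo] = (),
                   edges: Iterable[RegulatoryEdge] = (),
                   gene_symbols: Mapping[str, Curie] | None = None,
                   name: str = "") -> tuple[KnowledgeGraph, PopulationReport]:
    """Write the selected data into a copy of the seed ontology.

    Asserted statements added per record type:

    * annotation -> ``participates_in`` (P) / ``has_function`` (F) /
      ``located_in`` (C), plus ``in_taxon`` when the record carries one;
      annotations to terms absent from the seed are counted and skipped
      (the seed defines the ontological scope of the graph);
    * interaction -> a reified interaction node with two
      ``has_participant`` statements and one ``has_interaction_type``;
    * pathway membership -> ``member_of_pathway``;
    * protein info -> ``encoded_by`` (gene nodes only when an NCBI gene
      reference exists), ``has_modified_residue``, ``in_taxon``;
    * regulatory edge -> ``activates`` / ``represses`` / ``regulates`` by
      mode; symbolic targets that the gene-symbol index cannot resolve
      become ``SYMBOL:<name>`` placeholder nodes.
    """
    graph = seed.copy(name=name or seed.name)
    report = PopulationReport()
    gene_symbols = dict(gene_symbols or {})

    info_by_accession = {}
    for info in infos:
        info_by_accession[info.accession] = info
        if info.gene is not None and info.symbol:
            gene_symbols.setdefault(info.symbol.upper(), info.gene)

    def protein_node(p: Curie) -> None:
        info = info_by_accession.get(p)
        graph.add_node(p, label=info.symbol if info else "")

    for p in sorted(proteins, key=str):
        protein_node(p)

    for rec in annotations:
        if rec.protein not in proteins:
            continue
        if rec.go_term not in graph.nodes:
            report.annotations_outside_seed += 1
            continue
        pred = ASPECT_PREDICATES[rec.aspect]
        if graph.assert_triple(rec.protein, pred, rec.go_term, source="gaf"):
            report.bump(graph.relations[pred].name)
        if rec.taxon is not None:
            graph.add_node(rec.taxon)
            if graph.assert_triple(rec.protein, IN_TAXON, rec.taxon, source="gaf"):
                report.bump("in_taxon")

    for rec in interactions:
        if rec.participant_a not in proteins or rec.participant_b not in proteins:
            continue
        graph.add_node(rec.interaction_id)
        graph.add_node(rec.interaction_type)
        n = 0
        n += graph.assert_triple(rec.interaction_id, HAS_PARTICIPANT,
                                 rec.participant_a, source="mitab")
        n += graph.assert_triple(rec.interaction_id, HAS_PARTICIPANT,
                                 rec.participant_b, source="mitab")
        report.bump("has_participant", n)
        if graph.assert_triple(rec.interaction_id, HAS_INTERACTION_TYPE,
                               rec.interaction_type, source="mitab"):
            report.bump("has_interaction_type")

    for pm in pathways:
        if pm.protein not in proteins:
            continue
        graph.add_node(pm.pathway)
        if graph.assert_triple(pm.protein, MEMBER_OF_PATHWAY, pm.pathway,
                               source="pathways"):
            report.bump("member_of_pathway")

    for info in info_by_accession.values():
        if info.accession not in proteins:
            continue
        if info.gene is not None:
            graph.add_node(info.gene, label=info.symbol)
            if graph.assert_triple(info.accession, ENCODED_BY, info.gene,
                                   source="protein_info"):
                report.bump("encoded_by")
        for residue in info.modified_residues:
            res = Curie("SSB", residue)  # spaces become underscores
            graph.add_node(res, label=residue)
            if graph.assert_triple(info.accession, HAS_MODIFIED_RESIDUE, res,
                                   source="protein_info"):
                report.bump("has_modified_residue")
        if info.taxon is not None:
            graph.add_node(info.taxon)
            if graph.assert_triple(info.accession, IN_TAXON, info.taxon,
                                   source="protein_info"):
                report.bump("in_taxon")

    mode_predicate = {"activator": ACTIVATES, "repressor": REPRESSES,
                      "unknown": REGULATES}
    for edge in edges:
        if edge.regulator not in proteins:
            continue
        target = gene_symbols.get(edge.target_gene)
        if target is None:
            target = Curie("SYMBOL", edge.target_gene)
        graph.add_node(target, label=edge.target_gene)
        pred = mode_predicate[edge.mode]
        if graph.assert_triple(edge.regulator, pred, target,
                               source=edge.source_db):
            report.bump(graph.relations[pred].name)

    return graph, report
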