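"""Core knowledge-graph data model and ontology assembly.

The knowledge base is a set of typed nodes connected by relation-typed
statements (triples).  Nodes carry a category derived from their identifier
namespace (protein, gene, pathway, ...), relations carry the metadata that
drives rule-based inference (transitivity, reflexivity, superrelations,
compositions, priority over subsumption), and every statement records its
provenance: ``asserted`` (read from an input source) or ``inferred``
(produced by the closure).

Three nested application graphs are built from the same inputs by extracting
sub-domains rooted at increasingly specific ontology terms and linking them,
together with molecular-function / cellular-component / interaction-type
fragments, under a small upper-level ontology (ULO).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import yaml

logger = logging.getLogger("gexkg")

# --------------------------------------------------------------------------
# Identifiers
# --------------------------------------------------------------------------

#: namespace -> node category.  Everything else is an ontology class.
CATEGORY_BY_NAMESPACE: Mapping[str, str] = {
    "UniProtKB": "protein",
    "KEGG": "pathway",
    "NCBIGene": "gene",
    "NCBITaxon": "taxon",
    "SSB": "modified_residue",
    "intact": "interaction",
}

NODE_CATEGORIES = frozenset(
    {"ontology_class", "protein", "gene", "pathway", "interaction",
     "modified_residue", "taxon"}
)

#: namespace used for relation identifiers parsed from bare OBO tokens.
REL_NS = "rel"


class GraphError(ValueError):
    """Raised on violations of the knowledge-graph contracts."""


@dataclass(frozen=True, order=True)
class Curie:
    """Compact identifier ``namespace:local_id``.

    Two serializations are used: the OBO dialect ``GO:0010467`` and the
    triple dialect ``GO_0010467`` (underscore separator, used in exported
    URIs).  Both round-trip losslessly because namespaces may contain
    neither ``:`` nor ``_``.  Whitespace in the local part (e.g. modified
    residue names) is replaced by underscores at construction.
    """

    namespace: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.namespace:
            raise GraphError("Curie namespace must be non-empty")
        if any(c in self.namespace for c in ":_") or self.namespace != self.namespace.strip():
            raise GraphError(f"invalid Curie namespace {self.namespace!r}")
        if not self.local_id:
            raise GraphError("Curie local id must be non-empty")
        cleaned = "_".join(self.local_id.split())
        if cleaned != self.local_id:
            object.__setattr__(self, "local_id", cleaned)

    def __str__(self) -> str:  # OBO dialect
        return f"{self.namespace}:{self.local_id}"

    @property
    def triple_form(self) -> str:
        return f"{self.namespace}_{self.local_id}"

    @classmethod
    def parse(cls, text: str, default_namespace: str = REL_NS) -> "Curie":
        """Parse either dialect; bare tokens get *default_namespace*."""
        text = text.strip()
        if ":" in text:
            ns, local = text.split(":", 1)
        elif "_" in text:
            ns, local = text.split("_", 1)
        else:
            ns, local = default_namespace, text
        return cls(ns, local)

    @property
    def category(self) -> str:
        return CATEGORY_BY_NAMESPACE.get(self.namespace, "ontology_class")


@dataclass(frozen=True)
class TermNode:
    """A node of the knowledge graph: an ontology class or a data entity."""

    id: Curie
    label: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        expected = self.id.category
        if not self.category:
            object.__setattr__(self, "category", expected)
        elif self.category != expected:
            raise GraphError(
                f"category {self.category!r} inconsistent with namespace of {self.id}"
                f" (expected {expected!r})"
            )


@dataclass(frozen=True)
class RelationType:
    """Relation metadata driving the inference rules.

    ``compositions`` maps a second relation ``s`` to the produced relation
    ``t``:  ``x r y  and  y s z``  entails  ``x t z``.
    """

    id: Curie
    name: str = ""
    transitive: bool = False
    reflexive: bool = False
    superrelations: frozenset[Curie] = frozenset()
    compositions: tuple[tuple[Curie, Curie], ...] = ()
    priority_over_subsumption: bool = False

    def __post_init__(self) -> None:
        if self.id in self.superrelations:
            raise GraphError(f"relation {self.id} cannot be its own superrelation")
        if not self.name:
            object.__setattr__(self, "name", self.id.local_id)
        object.__setattr__(self, "superrelations", frozenset(self.superrelations))
        object.__setattr__(self, "compositions",
                           tuple(sorted(self.compositions, key=lambda p: (str(p[0]), str(p[1])))))

    @property
    def composition_map(self) -> dict[Curie, Curie]:
        return dict(self.compositions)


ASSERTED = "asserted"
INFERRED = "inferred"


@dataclass(frozen=True)
class Statement:
    """A triple with provenance.  Identity is the (s, p, o) key only."""

    subject: Curie
    predicate: Curie
    object: Curie
    provenance: str = ASSERTED
    source: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in (ASSERTED, INFERRED):
            raise GraphError(f"unknown provenance {self.provenance!r}")

    @property
    def key(self) -> tuple[Curie, Curie, Curie]:
        return (self.subject, self.predicate, self.object)


# --------------------------------------------------------------------------
# Built-in relation vocabulary
# --------------------------------------------------------------------------

def _rel(local: str) -> Curie:
    return Curie(REL_NS, local)


IS_A = _rel("is_a")
PART_OF = _rel("part_of")
PARTICIPATES_IN = _rel("participates_in")
HAS_FUNCTION = _rel("has_function")
LOCATED_IN = _rel("located_in")
MEMBER_OF_PATHWAY = _rel("member_of_pathway")
ENCODED_BY = _rel("encoded_by")
HAS_MODIFIED_RESIDUE = _rel("has_modified_residue")
IN_TAXON = _rel("in_taxon")
HAS_PARTICIPANT = _rel("has_participant")
HAS_INTERACTION_TYPE = _rel("has_interaction_type")
REGULATES = _rel("regulates")
ACTIVATES = _rel("activates")
REPRESSES = _rel("represses")


def default_relation_types() -> dict[Curie, RelationType]:
    """The shipped relation vocabulary with its inference metadata.

    Annotation relations (participates_in / has_function / located_in) take
    priority over subsumption so that protein annotations propagate along
    the ontology ``is_a`` hierarchy, reproducing true-path-style inference.
    """
    rels = [
        RelationType(IS_A, "is_a", transitive=True),
        RelationType(PART_OF, "part_of", transitive=True, reflexive=True,
                     compositions=((PART_OF, PART_OF),)),
        RelationType(PARTICIPATES_IN, "participates_in", priority_over_subsumption=True),
        RelationType(HAS_FUNCTION, "has_function", priority_over_subsumption=True),
        RelationType(LOCATED_IN, "located_in", priority_over_subsumption=True,
                     compositions=((PART_OF, LOCATED_IN),)),
        RelationType(MEMBER_OF_PATHWAY, "member_of_pathway"),
        RelationType(ENCODED_BY, "encoded_by"),
        RelationType(HAS_MODIFIED_RESIDUE, "has_modified_residue"),
        RelationType(IN_TAXON, "in_taxon"),
        RelationType(HAS_PARTICIPANT, "has_participant"),
        RelationType(HAS_INTERACTION_TYPE, "has_interaction_type"),
        RelationType(REGULATES, "regulates"),
        RelationType(ACTIVATES, "activates", superrelations=frozenset({REGULATES})),
        RelationType(REPRESSES, "represses", superrelations=frozenset({REGULATES})),
    ]
    return {r.id: r for r in rels}


def load_relation_metadata(path_or_stream) -> dict[Curie, RelationType]:
    """Load relation metadata from YAML.

    Schema::

        relations:
          part_of:
            transitive: true
            reflexive: true
            compositions: {part_of: part_of}
          activates:
            superrelations: [regulates]
    """
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    data = data or {}
    out: dict[Curie, RelationType] = {}
    for name, meta in (data.get("relations") or {}).items():
        meta = meta or {}
        rid = _parse_rel_token(name)
        comps = tuple(
            (_parse_rel_token(k), _parse_rel_token(v))
            for k, v in (meta.get("compositions") or {}).items()
        )
        out[rid] = RelationType(
            rid,
            name=meta.get("name", name),
            transitive=bool(meta.get("transitive", False)),
            reflexive=bool(meta.get("reflexive", False)),
            superrelations=frozenset(_parse_rel_token(s)
                                     for s in meta.get("superrelations", [])),
            compositions=comps,
            priority_over_subsumption=bool(meta.get("priority_over_subsumption", False)),
        )
    _validate_relation_refs(out)
    return out


def _parse_rel_token(token: str,
                     by_name: Mapping[str, Curie] | None = None) -> Curie:
    """Resolve a relation token: a declared relation name wins; a CURIE
    parses as such; a bare name lands in the ``rel`` namespace whole
    (bare OBO relation ids like ``part_of`` are names, never the
    underscore triple dialect)."""
    if by_name and token in by_name:
        return by_name[token]
    if ":" in token:
        return Curie.parse(token)
    return Curie(REL_NS, token)


def _validate_relation_refs(rels: Mapping[Curie, RelationType]) -> None:
    for r in rels.values():
        for s in r.superrelations:
            if s not in rels:
                raise GraphError(f"relation {r.id} names undeclared superrelation {s}")
        for second, produced in r.compositions:
            if second not in rels or produced not in rels:
                raise GraphError(
                    f"relation {r.id} composition ({second} -> {produced}) "
                    "references undeclared relations")


def dump_relation_metadata(rels: Mapping[Curie, RelationType], path) -> None:
    data: dict = {"relations": {}}
    for rid in sorted(rels, key=str):
        r = rels[rid]
        entry: dict = {}
        if r.transitive:
            entry["transitive"] = True
        if r.reflexive:
            entry["reflexive"] = True
        if r.priority_over_subsumption:
            entry["priority_over_subsumption"] = True
        if r.superrelations:
            entry["superrelations"] = sorted(rels[s].name for s in r.superrelations)
        if r.compositions:
            entry["compositions"] = {rels[a].name: rels[b].name for a, b in r.compositions}
        data["relations"][r.name] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# --------------------------------------------------------------------------
# The graph store
# --------------------------------------------------------------------------

class KnowledgeGraph:
    """In-process store of typed nodes and relation-typed statements.

    Invariants enforced on mutation:

    * every Curie mentioned in a statement resolves to a declared node and
      its predicate to a declared relation (closure under reference);
    * ``(subject, predicate, object)`` is unique; on collision an asserted
      statement wins over an inferred one.
    """

    def __init__(self, name: str = "",
                 relations: Mapping[Curie, RelationType] | None = None) -> None:
        self.name = name
        self.nodes: dict[Curie, TermNode] = {}
        self.relations: dict[Curie, RelationType] = dict(relations or {})
        self._statements: dict[tuple[Curie, Curie, Curie], Statement] = {}

    # -- nodes / relations --------------------------------------------------

    def add_node(self, node: TermNode | Curie, label: str = "") -> TermNode:
        if isinstance(node, Curie):
            node = TermNode(node, label=label)
        existing = self.nodes.get(node.id)
        if existing is not None:
            if node.label and not existing.label:
                self.nodes[node.id] = node
            return self.nodes[node.id]
        self.nodes[node.id] = node
        return node

    def add_relation(self, rel: RelationType) -> None:
        existing = self.relations.get(rel.id)
        if existing is not None and existing != rel:
            raise GraphError(
                f"conflicting metadata for relation {rel.id}: "
                f"{existing} vs {rel}")
        self.relations[rel.id] = rel

    def relation_named(self, name: str) -> RelationType | None:
        for r in self.relations.values():
            if r.name == name:
                return r
        return None

    # -- statements ---------------------------------------------------------

    def add_statement(self, st: Statement) -> bool:
        """Add *st*; return True if the statement set changed.

        Duplicate (s, p, o) keys are dropped; an asserted statement replaces
        an inferred one but never vice versa.
        """
        if st.subject not in self.nodes:
            raise GraphError(f"statement subject {st.subject} is not a declared node")
        if st.object not in self.nodes:
            raise GraphError(f"statement object {st.object} is not a declared node")
        if st.predicate not in self.relations:
            raise GraphError(f"statement predicate {st.predicate} is not a declared relation")
        old = self._statements.get(st.key)
        if old is None:
            self._statements[st.key] = st
            return True
        if old.provenance == INFERRED and st.provenance == ASSERTED:
            self._statements[st.key] = st
        return False

    def assert_triple(self, subject: Curie, predicate: Curie, object: Curie,
                      source: str = "") -> bool:
        return self.add_statement(Statement(subject, predicate, object,
                                            ASSERTED, source))

    @property
    def statements(self) -> Iterator[Statement]:
        return iter(self._statements.values())

    def statement_keys(self) -> set[tuple[Curie, Curie, Curie]]:
        return set(self._statements)

    def has_statement(self, subject: Curie, predicate: Curie, object: Curie) -> bool:
        return (subject, predicate, object) in self._statements

    def by_predicate(self, predicate: Curie) -> list[Statement]:
        return [s for s in self._statements.values() if s.predicate == predicate]

    def n_statements(self, provenance: str | None = None) -> int:
        if provenance is None:
            return len(self._statements)
        return sum(1 for s in self._statements.values() if s.provenance == provenance)

    # -- views / traversal --------------------------------------------------

    def copy(self, name: str | None = None) -> "KnowledgeGraph":
        g = KnowledgeGraph(self.name if name is None else name, self.relations)
        g.nodes = dict(self.nodes)
        g._statements = dict(self._statements)
        return g

    def filter_provenance(self, provenance: str) -> "KnowledgeGraph":
        """A view keeping all nodes/relations but only *provenance* statements."""
        g = KnowledgeGraph(f"{self.name}[{provenance}]", self.relations)
        g.nodes = dict(self.nodes)
        g._statements = {k: s for k, s in self._statements.items()
                         if s.provenance == provenance}
        return g

    def descendants(self, root: Curie,
                    edge_predicates: Iterable[Curie] = (IS_A, PART_OF)) -> set[Curie]:
        """Nodes from which *root* is reachable along *edge_predicates*.

        The root itself is not included.
        """
        preds = set(edge_predicates)
        incoming: dict[Curie, list[Curie]] = {}
        for st in self._statements.values():
            if st.predicate in preds:
                incoming.setdefault(st.object, []).append(st.subject)
        seen: set[Curie] = set()
        stack = list(incoming.get(root, []))
        while stack:
            n = stack.pop()
            if n in seen or n == root:
                continue
            seen.add(n)
            stack.extend(incoming.get(n, []))
        return seen

    def ancestors(self, term: Curie,
                  edge_predicates: Iterable[Curie] = (IS_A,)) -> set[Curie]:
        preds = set(edge_predicates)
        outgoing: dict[Curie, list[Curie]] = {}
        for st in self._statements.values():
            if st.predicate in preds:
                outgoing.setdefault(st.subject, []).append(st.object)
        seen: set[Curie] = set()
        stack = list(outgoing.get(term, []))
        while stack:
            n = stack.pop()
            if n in seen or n == term:
                continue
            seen.add(n)
            stack.extend(outgoing.get(n, []))
        return seen

    def __len__(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:
        return (f"<KnowledgeGraph {self.name!r}: {len(self.nodes)} nodes, "
                f"{len(self._statements)} statements>")


# --------------------------------------------------------------------------
# OBO 1.2 I/O
# --------------------------------------------------------------------------

class OboParseError(GraphError):
    pass


_RECOGNIZED_TAGS = {"id", "name", "is_a", "relationship",
                    "is_transitive", "is_reflexive"}


def _strip_obo_comment(value: str) -> str:
    # an unescaped "!" starts a trailing comment
    out = []
    prev = ""
    for ch in value:
        if ch == "!" and prev != "\\":
            break
        out.append(ch)
        prev = ch
    return "".join(out).strip()


def parse_obo(stream, name: str = "",
              relations: Mapping[Curie, RelationType] | None = None) -> KnowledgeGraph:
    """Parse an OBO 1.2 document into a knowledge graph.

    One node per ``[Term]`` stanza; one asserted statement per ``is_a`` /
    ``relationship`` line.  ``[Typedef]`` stanzas declare relations, with
    ``is_transitive`` / ``is_reflexive`` populating the metadata flags.
    Unknown tags are ignored with a logged warning.  Terms referenced by a
    statement but not declared in their own stanza are created with an
    empty label so the graph stays closed under reference.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    stanzas: list[tuple[str, int, list[tuple[str, str, int]]]] = []
    current: list[tuple[str, str, int]] | None = None
    kind = ""
    start_line = 0
    unknown_tags: set[str] = set()
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            kind = line.strip("[]")
            current = []
            start_line = lineno
            stanzas.append((kind, start_line, current))
            continue
        if ":" not in line:
            continue
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = _strip_obo_comment(value)
        if current is None:
            continue  # header tags (format-version etc.)
        if tag not in _RECOGNIZED_TAGS:
            if tag not in unknown_tags:
                unknown_tags.add(tag)
                logger.warning("OBO parse: ignoring unknown tag %r (line %d)", tag, lineno)
            continue
        current.append((tag, value, lineno))

    graph = KnowledgeGraph(name, relations)
    rel_by_name = {r.name: r.id for r in graph.relations.values()}

    # pass 1: Typedefs declare the relation vocabulary
    for skind, sline, tags in stanzas:
        if skind != "Typedef":
            continue
        tagmap = {t: v for t, v, _ in tags}
        if "id" not in tagmap:
            raise OboParseError(f"[Typedef] stanza at line {sline} has no id")
        rid = _parse_rel_token(tagmap["id"], rel_by_name)
        base = graph.relations.get(rid)
        rel = RelationType(
            rid,
            name=tagmap.get("name", tagmap["id"]),
            transitive=tagmap.get("is_transitive", "").lower() == "true"
            or bool(base and base.transitive),
            reflexive=tagmap.get("is_reflexive", "").lower() == "true"
            or bool(base and base.reflexive),
            superrelations=base.superrelations if base else frozenset(),
            compositions=base.compositions if base else (),
            priority_over_subsumption=bool(base and base.priority_over_subsumption),
        )
        graph.relations[rid] = rel
        rel_by_name[rel.name] = rid
    if IS_A not in graph.relations:
        graph.relations[IS_A] = default_relation_types()[IS_A]

    # pass 2: Terms
    pending: list[tuple[Curie, Curie, Curie, int]] = []
    for skind, sline, tags in stanzas:
        if skind != "Term":
            continue
        tagmap_id = next((v for t, v, _ in tags if t == "id"), None)
        if tagmap_id is None:
            raise OboParseError(f"[Term] stanza at line {sline} has no id")
        term = Curie.parse(tagmap_id)
        label = next((v for t, v, _ in tags if t == "name"), "")
        graph.add_node(term, label=label)
        for tag, value, lineno in tags:
            if tag == "is_a":
                pending.append((term, IS_A, Curie.parse(value), lineno))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) != 2:
                    raise OboParseError(
                        f"malformed relationship line {lineno}: {value!r}")
                rel_id = _parse_rel_token(parts[0], rel_by_name)
                if rel_id not in graph.relations:
                    raise OboParseError(
                        f"relationship at line {lineno} uses undeclared relation "
                        f"{parts[0]!r}")
                pending.append((term, rel_id, Curie.parse(parts[1]), lineno))

    for subject, predicate, object_, lineno in pending:
        graph.add_node(object_)
        graph.add_node(subject)
        graph.assert_triple(subject, predicate, object_, source="obo")
    return graph


def serialize_obo(graph: KnowledgeGraph) -> str:
    """Serialize nodes and *asserted* statements as OBO 1.2.

    Deterministic: terms and their statement lines are sorted
    lexicographically by Curie string.
    """
    lines = ["format-version: 1.2", ""]
    out_by_subject: dict[Curie, list[str]] = {}
    used_rels: set[Curie] = set()
    for st in graph.statements:
        if st.provenance != ASSERTED:
            continue
        if st.predicate == IS_A:
            entry = f"is_a: {st.object}"
        else:
            entry = f"relationship: {graph.relations[st.predicate].name} {st.object}"
            used_rels.add(st.predicate)
        out_by_subject.setdefault(st.subject, []).append(entry)

    for nid in sorted(graph.nodes, key=str):
        node = graph.nodes[nid]
        lines.append("[Term]")
        lines.append(f"id: {node.id}")
        if node.label:
            lines.append(f"name: {node.label}")
        for entry in sorted(out_by_subject.get(nid, [])):
            lines.append(entry)
        lines.append("")

    # typedefs only for relations actually used in relationship lines
    for rid in sorted(used_rels, key=str):
        rel = graph.relations[rid]
        lines.append("[Typedef]")
        lines.append(f"id: {rel.name}")
        lines.append(f"name: {rel.name}")
        if rel.transitive:
            lines.append("is_transitive: true")
        if rel.reflexive:
            lines.append("is_reflexive: true")
        lines.append("")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# Upper-level ontology
# --------------------------------------------------------------------------

#: (term id, label, parent id) — a concise upper level gluing ontology
#: classes and data-facing term types under a single root.  Anchors used by
#: the assembly: 'biological process', 'molecular function',
#: 'cellular component', 'interaction type'.
DEFAULT_ULO_SPEC: tuple[tuple[str, str, str | None], ...] = (
    ("ULO:0000001", "entity", None),
    ("ULO:0000002", "material entity", "ULO:0000001"),
    ("ULO:0000003", "chemical entity", "ULO:0000002"),
    ("ULO:0000004", "macromolecule", "ULO:0000003"),
    ("ULO:0000005", "nucleic acid", "ULO:0000004"),
    ("ULO:0000006", "organism", "ULO:0000002"),
    ("ULO:0000007", "process", "ULO:0000001"),
    ("ULO:0000008", "biological process", "ULO:0000007"),
    ("ULO:0000009", "interaction", "ULO:0000007"),
    ("ULO:0000010", "interaction type", "ULO:0000009"),
    ("ULO:0000011", "pathway", "ULO:0000007"),
    ("ULO:0000012", "attribute", "ULO:0000001"),
    ("ULO:0000013", "molecular function", "ULO:0000012"),
    ("ULO:0000014", "cellular component", "ULO:0000002"),
    ("ULO:0000015", "modified residue", "ULO:0000012"),
    ("ULO:0000016", "information content entity", "ULO:0000001"),
)


def assemble_ulo(spec: Sequence[tuple[str, str, str | None]] | None = None,
                 name: str = "ULO") -> KnowledgeGraph:
    """Assemble the upper-level ontology from (id, label, parent) triples.

    The term list must be acyclic with exactly one root (parent ``None``);
    every non-root term gains an asserted ``is_a`` statement to its parent.
    """
    spec = tuple(spec) if spec is not None else DEFAULT_ULO_SPEC
    roots = [tid for tid, _, parent in spec if parent is None]
    if len(roots) != 1:
        raise GraphError(f"ULO spec must have exactly one root, found {len(roots)}")
    dag = nx.DiGraph()
    dag.add_nodes_from(tid for tid, _, _ in spec)
    dag.add_edges_from((tid, parent) for tid, _, parent in spec if parent is not None)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise GraphError(f"ULO spec contains a cycle: {cycle}")
    declared = {tid for tid, _, _ in spec}
    graph = KnowledgeGraph(name, default_relation_types())
    for tid, label, _ in spec:
        graph.add_node(Curie.parse(tid), label=label)
    for tid, _, parent in spec:
        if parent is None:
            continue
        if parent not in declared:
            raise GraphError(f"ULO spec parent {parent!r} is not a declared term")
        graph.assert_triple(Curie.parse(tid), IS_A, Curie.parse(parent), source="ulo")
    return graph


def find_by_label(graph: KnowledgeGraph, label: str) -> Curie:
    """The Curie of the unique node with the given label (case-insensitive)."""
    hits = [n.id for n in graph.nodes.values()
            if n.label.lower() == label.lower()]
    if not hits:
        raise GraphError(f"no node labelled {label!r} in graph {graph.name!r}")
    if len(hits) > 1:
        raise GraphError(f"label {label!r} is ambiguous in graph {graph.name!r}")
    return hits[0]


# --------------------------------------------------------------------------
# Sub-domain extraction, linking, merging
# --------------------------------------------------------------------------

def extract_subdomain(graph: KnowledgeGraph, root: Curie,
                      edge_predicates: Iterable[Curie] = (IS_A, PART_OF),
                      name: str = "") -> KnowledgeGraph:
    """Extract *root* plus all its descendants and every statement among them.

    Descendants are nodes from which *root* is reachable along
    *edge_predicates* (default ``is_a`` and ``part_of``).
    """
    if root not in graph.nodes:
        raise GraphError(f"sub-domain root {root} is not in graph {graph.name!r}")
    keep = graph.descendants(root, edge_predicates) | {root}
    sub = KnowledgeGraph(name or f"{graph.name}/{root}", graph.relations)
    for n in keep:
        sub.add_node(graph.nodes[n])
    for st in graph.statements:
        if st.subject in keep and st.object in keep:
            sub.add_statement(st)
    return sub


def link_to_ulo(ulo: KnowledgeGraph, fragment: KnowledgeGraph,
                fragment_root: Curie, anchor: Curie,
                name: str = "") -> KnowledgeGraph:
    """Merge *fragment* into *ulo* and subordinate its root under *anchor*.

    Exactly one asserted ``is_a`` statement (fragment_root -> anchor) is
    added; re-linking an already linked fragment is a no-op (deduplication).
    """
    if anchor not in ulo.nodes:
        raise GraphError(f"anchor {anchor} is not in the ULO graph")
    if fragment_root not in fragment.nodes:
        raise GraphError(f"fragment root {fragment_root} is not in the fragment")
    merged = merge_graphs([ulo, fragment], name or ulo.name)
    merged.assert_triple(fragment_root, IS_A, anchor, source="link_to_ulo")
    return merged


def merge_graphs(graphs: Sequence[KnowledgeGraph], name: str = "") -> KnowledgeGraph:
    """Set-union of nodes, relations and statements.

    Statements deduplicate on (s, p, o) with asserted provenance preferred.
    Conflicting metadata for the same relation id is an error.
    """
    merged = KnowledgeGraph(name)
    for g in graphs:
        for rel in g.relations.values():
            merged.add_relation(rel)
        for node in g.nodes.values():
            merged.add_node(node)
        for st in g.statements:
            merged.add_statement(st)
    return merged


# --------------------------------------------------------------------------
# N-Triples export
# --------------------------------------------------------------------------

DEFAULT_BASE_IRI = "http://example.org/gexkg/"


def to_ntriples(graph: KnowledgeGraph, base_iri: str = DEFAULT_BASE_IRI,
                provenance: str | None = None) -> str:
    """Serialize the graph as sorted N-Triples.

    Every node becomes one ``<base_iri><namespace>_<local_id>`` URI; node
    labels are emitted as ``rdfs:label`` literals.  *provenance* restricts
    the exported statements to ``asserted`` or ``inferred``.
    """
    from rdflib import Graph as RdfGraph, Literal, Namespace, RDFS, URIRef

    ns = Namespace(base_iri)
    rg = RdfGraph()
    for node in graph.nodes.values():
        if node.label:
            rg.add((URIRef(ns + node.id.triple_form), RDFS.label, Literal(node.label)))
    for st in graph.statements:
        if provenance is not None and st.provenance != provenance:
            continue
        rg.add((URIRef(ns + st.subject.triple_form),
                URIRef(ns + st.predicate.triple_form),
                URIRef(ns + st.object.triple_form)))
    lines = sorted(rg.serialize(format="nt").splitlines())
    return "\n".join(line for line in lines if line.strip()) + "\n"
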