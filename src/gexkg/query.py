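"""Selector algebra over the knowledge graph and the built-in templates.

A query template is a boolean tree (union / intersection) of labelled
clauses; each clause is either a term selector — proteins carrying an
annotation statement of a given predicate to a given ontology term — or an
interaction selector — proteins co-participating in a reified interaction
node with a given partner, optionally of a given interaction type.

The five built-in regulatory-candidate templates cover the published use
cases around the transcription factors CREB1, NFkB1/RELA and TCF7L2:

* **Q1** — activators of CREB1:
  (positive regulation of CREB TF activity  ∪  CREB-binding function  ∪
  direct interaction (MI:0407) with CREB1)  ∪
  (positive regulation of DNA-binding TF activity  ∩  physical
  association (MI:0914) with CREB1);
* **Q2** — repressors of CREB1: negative regulation of CREB TF activity
  ∪ (negative regulation of DNA-binding TF activity ∩ interaction with
  CREB1; the interaction conjunct is toggleable);
* **Q3** — chromatin modifiers regulating CREB1: (histone
  acetyltransferase ∪ histone deacetylase activity) ∩ regulation of
  DNA-binding TF activity ∩ any interaction with CREB1;
* **Q4** — NFkB repressors routed to proteasomal degradation: negative
  regulation of NFkB TF activity ∩ (ubiquitin ligase complex ∪ ubiquitin
  binding ∪ ubiquitination-type interaction (MI:0220) ∪ the ubiquitin
  mediated proteolysis pathway);
* **Q5** — dual-role partners of TCF7L2: interacts with TCF7L2 ∩
  negative regulation ∩ positive regulation of DNA-binding TF activity.

All term and protein identifiers are parameters with the published
defaults, so the same templates run against synthetic graphs that inject
those anchor identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .inference import compute_closure  # noqa: F401  (re-exported convenience)
from .integration import RegulatoryEdge
from .model import (
    HAS_FUNCTION,
    HAS_INTERACTION_TYPE,
    HAS_PARTICIPANT,
    IN_TAXON,
    IS_A,
    LOCATED_IN,
    MEMBER_OF_PATHWAY,
    PARTICIPATES_IN,
    Curie,
    GraphError,
    KnowledgeGraph,
)


class QueryError(GraphError):
    pass


# --------------------------------------------------------------------------
# Selectors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TermSelector:
    """Proteins with a *predicate* statement to *term*.

    With ``use_descendants`` the match extends to statements targeting any
    ``is_a`` descendant of *term* — closure-aware matching for graphs that
    have not been closed.  Built-in templates switch this off and let the
    computed closure perform the generalization instead, which is what
    makes the asserted/inferred provenance partition meaningful.
    """

    predicate: Curie
    term: Curie
    use_descendants: bool = True

    def referenced(self) -> tuple[Curie, ...]:
        return (self.term,)

    def matches(self, graph: KnowledgeGraph) -> set[Curie]:
        terms = {self.term}
        if self.use_descendants:
            terms |= graph.descendants(self.term, (IS_A,))
        return {
            st.subject
            for st in graph.by_predicate(self.predicate)
            if st.object in terms
            and graph.nodes[st.subject].category == "protein"
        }


@dataclass(frozen=True)
class InteractionSelector:
    """Proteins co-participating in a reified interaction node.

    *partner* restricts to interactions involving that protein (the match
    itself excludes the partner); ``None`` matches any interaction of the
    given type.  *interaction_type* restricts the interaction's MI type,
    extended to its ``is_a`` descendants when ``use_descendants`` is set.
    """

    partner: Curie | None
    interaction_type: Curie | None = None
    use_descendants: bool = False

    def referenced(self) -> tuple[Curie, ...]:
        out = []
        if self.partner is not None:
            out.append(self.partner)
        if self.interaction_type is not None:
            out.append(self.interaction_type)
        return tuple(out)

    def matches(self, graph: KnowledgeGraph) -> set[Curie]:
        types: set[Curie] | None = None
        if self.interaction_type is not None:
            types = {self.interaction_type}
            if self.use_descendants:
                types |= graph.descendants(self.interaction_type, (IS_A,))
        participants: dict[Curie, set[Curie]] = {}
        for st in graph.by_predicate(HAS_PARTICIPANT):
            participants.setdefault(st.subject, set()).add(st.object)
        type_of: dict[Curie, set[Curie]] = {}
        if types is not None:
            for st in graph.by_predicate(HAS_INTERACTION_TYPE):
                type_of.setdefault(st.subject, set()).add(st.object)
        hits: set[Curie] = set()
        for inode, parts in participants.items():
            if types is not None and not (type_of.get(inode, set()) & types):
                continue
            if self.partner is not None:
                if self.partner not in parts:
                    continue
                hits |= {p for p in parts if p != self.partner}
            else:
                hits |= parts
        return {p for p in hits if graph.nodes[p].category == "protein"}


Selector = Union[TermSelector, InteractionSelector]


@dataclass(frozen=True)
class Clause:
    label: str
    selector: Selector


@dataclass(frozen=True)
class AnyOf:
    children: tuple = ()


@dataclass(frozen=True)
class AllOf:
    children: tuple = ()


Expression = Union[Clause, AnyOf, AllOf, None]


@dataclass(frozen=True)
class QueryTemplate:
    name: str
    expression: Expression = None
    taxon: Curie | None = None


@dataclass(frozen=True)
class CandidateResult:
    protein: Curie
    matched_clauses: frozenset[str]
    provenance_class: str | None = None  # asserted_only / inferred_only / both


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def _referenced_curies(expr: Expression) -> set[Curie]:
    if expr is None:
        return set()
    if isinstance(expr, Clause):
        return set(expr.selector.referenced())
    return set().union(*(_referenced_curies(c) for c in expr.children)) \
        if expr.children else set()


def _eval(expr: Expression, graph: KnowledgeGraph) -> dict[Curie, set[str]]:
    if expr is None:
        return {}
    if isinstance(expr, Clause):
        return {p: {expr.label} for p in expr.selector.matches(graph)}
    if isinstance(expr, AnyOf):
        out: dict[Curie, set[str]] = {}
        for child in expr.children:
            for p, labels in _eval(child, graph).items():
                out.setdefault(p, set()).update(labels)
        return out
    if isinstance(expr, AllOf):
        if not expr.children:
            return {}
        parts = [_eval(child, graph) for child in expr.children]
        common = set(parts[0])
        for part in parts[1:]:
            common &= set(part)
        return {p: set().union(*(part[p] for part in parts)) for p in common}
    raise QueryError(f"malformed expression node {expr!r}")


def evaluate(template: QueryTemplate, graph: KnowledgeGraph) -> list[CandidateResult]:
    """Evaluate a template; deterministic, sorted by protein Curie.

    Every Curie the template references must resolve in *graph*.
    """
    for curie in sorted(_referenced_curies(template.expression), key=str):
        if curie not in graph.nodes:
            raise QueryError(
                f"template {template.name!r} references {curie}, which is not "
                f"in graph {graph.name!r}")
    if template.taxon is not None and template.taxon not in graph.nodes:
        raise QueryError(
            f"template {template.name!r} taxon filter {template.taxon} is not "
            f"in graph {graph.name!r}")
    hits = _eval(template.expression, graph)
    if template.taxon is not None:
        in_taxon = {st.subject for st in graph.by_predicate(IN_TAXON)
                    if st.object == template.taxon}
        hits = {p: labels for p, labels in hits.items() if p in in_taxon}
    return [
        CandidateResult(p, frozenset(hits[p]))
        for p in sorted(hits, key=str)
    ]


def candidate_set(results: Iterable[CandidateResult]) -> set[Curie]:
    return {r.protein for r in results}


# --------------------------------------------------------------------------
# Built-in templates
# --------------------------------------------------------------------------

#: role -> published default identifier.
DEFAULT_TARGET_IDS: Mapping[str, Curie] = {
    "creb1": Curie("UniProtKB", "P16220"),
    "tcf7l2": Curie("UniProtKB", "Q9NQB0"),
    "pos_reg_creb_activity": Curie("GO", "0032793"),
    "neg_reg_creb_activity": Curie("GO", "0032792"),
    "pos_reg_dbtf_activity": Curie("GO", "0051091"),
    "neg_reg_dbtf_activity": Curie("GO", "0043433"),
    "reg_dbtf_activity": Curie("GO", "0051090"),
    "creb_binding_function": Curie("GO", "0008140"),
    "histone_acetyltransferase": Curie("GO", "0004402"),
    "histone_deacetylase": Curie("GO", "0004407"),
    "neg_reg_nfkb_activity": Curie("GO", "0032088"),
    "ubiquitin_ligase_complex": Curie("GO", "0000151"),
    "ubiquitin_binding": Curie("GO", "0043130"),
    "ubiquitination_reaction": Curie("MI", "0220"),
    "ubiquitin_proteolysis_pathway": Curie("KEGG", "ko04120"),
    "direct_interaction": Curie("MI", "0407"),
    "physical_association": Curie("MI", "0914"),
}

BUILTIN_TEMPLATE_NAMES = ("Q1", "Q2", "Q3", "Q4", "Q5")


def builtin_templates(target_ids: Mapping[str, Curie] | None = None, *,
                      taxon: Curie | None = None,
                      q2_with_interaction: bool = True,
                      q4_pure_union: bool = False,
                      ) -> dict[str, QueryTemplate]:
    """The five built-in candidate-regulator templates, fully parameterized.

    *target_ids* overrides any subset of :data:`DEFAULT_TARGET_IDS` roles;
    unknown or null roles are an error.  ``q2_with_interaction`` controls
    the interaction conjunct on Q2's broad term; ``q4_pure_union`` turns
    Q4 into a plain union of its central and degradation terms instead of
    the central-term-AND-degradation reading.
    """
    ids = dict(DEFAULT_TARGET_IDS)
    for role, curie in (target_ids or {}).items():
        if role not in ids:
            raise QueryError(f"unknown template role {role!r}")
        if curie is None:
            raise QueryError(f"template role {role!r} must not be null")
        ids[role] = curie

    def term(label, predicate, role):
        return Clause(label, TermSelector(predicate, ids[role],
                                          use_descendants=False))

    def inter(label, partner_role, type_role=None):
        return Clause(label, InteractionSelector(
            ids[partner_role] if partner_role else None,
            ids[type_role] if type_role else None))

    q1 = QueryTemplate("Q1", AnyOf((
        term("A:pos_reg_creb_activity", PARTICIPATES_IN, "pos_reg_creb_activity"),
        term("D:creb_binding_function", HAS_FUNCTION, "creb_binding_function"),
        inter("C:direct_interaction_creb1", "creb1", "direct_interaction"),
        AllOf((
            term("B:pos_reg_dbtf_activity", PARTICIPATES_IN, "pos_reg_dbtf_activity"),
            inter("B:physical_association_creb1", "creb1", "physical_association"),
        )),
    )), taxon)

    broad_neg = term("neg_reg_dbtf_activity", PARTICIPATES_IN,
                     "neg_reg_dbtf_activity")
    if q2_with_interaction:
        second = AllOf((broad_neg, inter("interacts_creb1", "creb1")))
    else:
        second = broad_neg
    q2 = QueryTemplate("Q2", AnyOf((
        term("neg_reg_creb_activity", PARTICIPATES_IN, "neg_reg_creb_activity"),
        second,
    )), taxon)

    q3 = QueryTemplate("Q3", AllOf((
        AnyOf((
            term("histone_acetyltransferase", HAS_FUNCTION,
                 "histone_acetyltransferase"),
            term("histone_deacetylase", HAS_FUNCTION, "histone_deacetylase"),
        )),
        term("reg_dbtf_activity", PARTICIPATES_IN, "reg_dbtf_activity"),
        inter("interacts_creb1", "creb1"),
    )), taxon)

    degradation = AnyOf((
        term("ubiquitin_ligase_complex", LOCATED_IN, "ubiquitin_ligase_complex"),
        term("ubiquitin_binding", HAS_FUNCTION, "ubiquitin_binding"),
        inter("ubiquitination_reaction", None, "ubiquitination_reaction"),
        term("ubiquitin_proteolysis_pathway", MEMBER_OF_PATHWAY,
             "ubiquitin_proteolysis_pathway"),
    ))
    central = term("neg_reg_nfkb_activity", PARTICIPATES_IN,
                   "neg_reg_nfkb_activity")
    if q4_pure_union:
        q4 = QueryTemplate("Q4", AnyOf((central, degradation)), taxon)
    else:
        q4 = QueryTemplate("Q4", AllOf((central, degradation)), taxon)

    q5 = QueryTemplate("Q5", AllOf((
        inter("interacts_tcf7l2", "tcf7l2"),
        term("neg_reg_dbtf_activity", PARTICIPATES_IN, "neg_reg_dbtf_activity"),
        term("pos_reg_dbtf_activity", PARTICIPATES_IN, "pos_reg_dbtf_activity"),
    )), taxon)

    return {t.name: t for t in (q1, q2, q3, q4, q5)}


# --------------------------------------------------------------------------
# DbTF filtering and shared targets
# --------------------------------------------------------------------------

def filter_dbtf(candidates: set[Curie], catalog: set[Curie]) -> set[Curie]:
    """Keep only candidates present in the DbTF catalog."""
    return set(candidates) & set(catalog)


@dataclass(frozen=True)
class SharedTarget:
    novel: Curie
    mode: str
    core: Curie
    target_gene: str
    sources: tuple[str, ...] = ()


def shared_targets(novel_dbtfs: set[Curie], core_dbtfs: set[Curie],
                   edges: Sequence[RegulatoryEdge]) -> list[SharedTarget]:
    """Target genes shared between novel and core DbTFs.

    One row per (novel, core, target) triple such that some edge
    ``novel -> target`` and some edge ``core -> target`` exist; the mode is
    taken from the novel edge.  Rows contributed by several source
    databases collapse to one with the sources concatenated.  Deterministic
    ordering: (novel, core, target).
    """
    edges = list(edges)
    if not edges:
        raise QueryError("shared_targets requires a non-empty edge list")
    novel_by_target: dict[str, dict[Curie, tuple[str, set[str]]]] = {}
    core_by_target: dict[str, set[Curie]] = {}
    for e in edges:
        if e.regulator in novel_dbtfs:
            slot = novel_by_target.setdefault(e.target_gene, {})
            mode, sources = slot.get(e.regulator, (e.mode, set()))
            if mode == "unknown" and e.mode != "unknown":
                mode = e.mode
            sources.add(e.source_db)
            slot[e.regulator] = (mode, sources)
        if e.regulator in core_dbtfs:
            core_by_target.setdefault(e.target_gene, set()).add(e.regulator)

    rows: list[SharedTarget] = []
    for target, novel_slot in novel_by_target.items():
        for core in core_by_target.get(target, ()):
            for novel, (mode, sources) in novel_slot.items():
                rows.append(SharedTarget(novel, mode, core, target,
                                         tuple(sorted(sources))))
    rows.sort(key=lambda r: (str(r.novel), str(r.core), r.target_gene))
    return rows


# --------------------------------------------------------------------------
# Provenance partition
# --------------------------------------------------------------------------

@dataclass
class ProvenancePartition:
    """Query hits split by the provenance needed to retrieve them."""

    asserted_only: set[Curie] = field(default_factory=set)
    inferred_only: set[Curie] = field(default_factory=set)
    both: set[Curie] = field(default_factory=set)

    @property
    def total(self) -> int:
        return len(self.asserted_only) + len(self.inferred_only) + len(self.both)

    def counts(self) -> dict[str, int]:
        return {
            "asserted_only": len(self.asserted_only),
            "inferred_only": len(self.inferred_only),
            "both": len(self.both),
            "total": self.total,
        }

    def classify(self, protein: Curie) -> str | None:
        for label in ("asserted_only", "inferred_only", "both"):
            if protein in getattr(self, label):
                return label
        return None


def provenance_partition(template: QueryTemplate,
                         asserted_graph: KnowledgeGraph,
                         closed_graph: KnowledgeGraph) -> ProvenancePartition:
    """Partition the closure hits of *template* by provenance.

    * ``asserted_only`` — retrievable from asserted statements but not
      from the inferred layer alone;
    * ``inferred_only`` — missed on the asserted graph, found on the
      closure;
    * ``both`` — retrievable from either layer alone.

    The three classes are disjoint and sum to the closure hit count.
    *closed_graph* must carry closure provenance (inferred statements)
    whenever it asserts more than *asserted_graph* does.
    """
    asserted_keys = asserted_graph.statement_keys()
    closed_asserted = {s.key for s in closed_graph.statements
                       if s.provenance == "asserted"}
    if not asserted_keys <= closed_asserted | {
            s.key for s in closed_graph.statements}:
        raise QueryError("closed_graph does not contain the asserted graph")
    has_inferred = any(s.provenance == "inferred" for s in closed_graph.statements)
    if not has_inferred and closed_graph.statement_keys() != asserted_keys:
        raise QueryError(
            "closed_graph carries extra statements but no closure provenance")

    full = candidate_set(evaluate(template, closed_graph))
    on_asserted = candidate_set(evaluate(template, asserted_graph))
    inferred_view = closed_graph.filter_provenance("inferred")
    on_inferred = candidate_set(evaluate(template, inferred_view))

    return ProvenancePartition(
        asserted_only=(on_asserted - on_inferred) & full,
        inferred_only=full - on_asserted,
        both=(on_asserted & on_inferred) & full,
    )
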