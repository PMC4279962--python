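"""Shared fixtures: small hand-built graphs and seeded random rule graphs."""

from __future__ import annotations

import random

import pytest

from gexkg.model import (
    IS_A,
    Curie,
    KnowledgeGraph,
    RelationType,
    default_relation_types,
)


def C(text: str) -> Curie:
    return Curie.parse(text)


@pytest.fixture
def chain_graph() -> KnowledgeGraph:
    """A is_a chain: C -> B -> A."""
    g = KnowledgeGraph("chain", default_relation_types())
    for t in ("X:A", "X:B", "X:C"):
        g.add_node(C(t))
    g.assert_triple(C("X:B"), IS_A, C("X:A"))
    g.assert_triple(C("X:C"), IS_A, C("X:B"))
    return g


# relation vocabulary for random rule graphs: one relation per rule kind
def rule_relations() -> dict[Curie, RelationType]:
    t = Curie("R", "t")       # transitive
    g = Curie("R", "g")       # plain
    a = Curie("R", "a")       # superrelation of g, composes with t into g
    p = Curie("R", "p")       # priority over subsumption
    f = Curie("R", "f")       # reflexive
    rels = {
        IS_A: RelationType(IS_A, "is_a", transitive=True),
        t: RelationType(t, "t", transitive=True),
        g: RelationType(g, "g"),
        a: RelationType(a, "a", superrelations=frozenset({g}),
                        compositions=((t, g),)),
        p: RelationType(p, "p", priority_over_subsumption=True),
        f: RelationType(f, "f", reflexive=True),
    }
    return rels


def random_rule_graph(seed: int, max_nodes: int = 200,
                      max_statements: int = 600) -> KnowledgeGraph:
    """A seeded random graph exercising every rule kind.

    Statements are spread across six relations so transitive closures stay
    tractable for the exhaustive oracle.
    """
    rng = random.Random(seed)
    n_nodes = rng.randint(8, max_nodes)
    n_stmts = rng.randint(n_nodes // 2, min(max_statements, 2 * n_nodes))
    rels = rule_relations()
    g = KnowledgeGraph(f"rand-{seed}", rels)
    nodes = [Curie("N", f"{i:03d}") for i in range(n_nodes)]
    for n in nodes:
        g.add_node(n)
    rel_ids = list(rels)
    for _ in range(n_stmts):
        s, o = rng.choice(nodes), rng.choice(nodes)
        g.assert_triple(s, rng.choice(rel_ids), o)
    return g


def naive_closure_oracle(graph: KnowledgeGraph) -> set[tuple]:
    """Exhaustive naive fixpoint: every round recomputes every rule over
    the full statement set (no deltas, no provenance)."""
    rels = graph.relations
    comp = {rid: dict(r.compositions) for rid, r in rels.items()}
    stmts = {(s.subject, s.predicate, s.object) for s in graph.statements}
    while True:
        new = set()
        by_pred: dict[Curie, list[tuple[Curie, Curie]]] = {}
        for s, p, o in stmts:
            by_pred.setdefault(p, []).append((s, o))
        for p, pairs in by_pred.items():
            r = rels[p]
            if r.reflexive:
                for s, o in pairs:
                    new.add((s, p, s))
                    new.add((o, p, o))
            for sup in r.superrelations:
                for s, o in pairs:
                    new.add((s, sup, o))
            if r.transitive:
                succ: dict[Curie, set[Curie]] = {}
                for s, o in pairs:
                    succ.setdefault(s, set()).add(o)
                for s, o in pairs:
                    for z in succ.get(o, ()):
                        new.add((s, p, z))
            for second, target in comp[p].items():
                succ2: dict[Curie, set[Curie]] = {}
                for s, o in by_pred.get(second, ()):
                    succ2.setdefault(s, set()).add(o)
                for s, o in pairs:
                    for z in succ2.get(o, ()):
                        new.add((s, target, z))
            if r.priority_over_subsumption and p != IS_A:
                isa = by_pred.get(IS_A, [])
                up: dict[Curie, set[Curie]] = {}
                down: dict[Curie, set[Curie]] = {}
                for s, o in isa:
                    up.setdefault(s, set()).add(o)
                    down.setdefault(o, set()).add(s)
                for s, o in pairs:
                    for z in up.get(o, ()):
                        new.add((s, p, z))
                    for w in down.get(s, ()):
                        new.add((w, p, o))
        if new <= stmts:
            return stmts
        stmts |= new
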