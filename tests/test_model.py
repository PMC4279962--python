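"""Data model, OBO I/O, ULO assembly, extraction, merging."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from gexkg.model import (
    DEFAULT_ULO_SPEC,
    IS_A,
    PART_OF,
    Curie,
    GraphError,
    KnowledgeGraph,
    OboParseError,
    RelationType,
    assemble_ulo,
    default_relation_types,
    extract_subdomain,
    find_by_label,
    link_to_ulo,
    merge_graphs,
    parse_obo,
    serialize_obo,
    to_ntriples,
)
from conftest import C, random_rule_graph


# -------------------------------------------------------------- identifiers

class TestCurie:
    def test_dialects_round_trip(self):
        c = Curie("GO", "0010467")
        assert str(c) == "GO:0010467"
        assert c.triple_form == "GO_0010467"
        assert Curie.parse(str(c)) == c
        assert Curie.parse(c.triple_form) == c

    @settings(derandomize=True, max_examples=200)
    @given(ns=st.from_regex(r"[A-Za-z][A-Za-z0-9.-]{0,9}", fullmatch=True),
           local=st.from_regex(r"[A-Za-z0-9][A-Za-z0-9_.:-]{0,14}", fullmatch=True))
    def test_round_trip_property(self, ns, local):
        c = Curie(ns, local)
        assert Curie.parse(str(c)) == c
        assert Curie.parse(c.triple_form) == c

    def test_whitespace_replaced_by_underscores(self):
        # modified-residue style ids built from names with spaces
        c = Curie("SSB", "Phosphoserine 133")
        assert c.local_id == "Phosphoserine_133"

    def test_invalid(self):
        with pytest.raises(GraphError):
            Curie("", "x")
        with pytest.raises(GraphError):
            Curie("A_B", "x")

    def test_category_mapping(self):
        cases = {"UniProtKB:P16220": "protein", "KEGG:ko04120": "pathway",
                 "NCBIGene:3778": "gene", "NCBITaxon:9606": "taxon",
                 "SSB:Phospho": "modified_residue", "intact:EBI-1": "interaction",
                 "GO:0010467": "ontology_class", "MI:0407": "ontology_class"}
        for text, cat in cases.items():
            assert Curie.parse(text).category == cat


class TestRelationType:
    def test_self_superrelation_rejected(self):
        r = Curie("R", "r")
        with pytest.raises(GraphError):
            RelationType(r, superrelations=frozenset({r}))


class TestStatements:
    def test_closure_under_reference(self, chain_graph):
        with pytest.raises(GraphError):
            chain_graph.assert_triple(C("X:A"), IS_A, C("X:missing"))

    def test_asserted_wins_over_inferred(self, chain_graph):
        from gexkg.model import Statement
        st_ = Statement(C("X:C"), IS_A, C("X:A"), "inferred", "rule")
        chain_graph.add_statement(st_)
        chain_graph.assert_triple(C("X:C"), IS_A, C("X:A"))
        kept = [s for s in chain_graph.statements
                if s.key == (C("X:C"), IS_A, C("X:A"))]
        assert len(kept) == 1 and kept[0].provenance == "asserted"
        # and never the other way around
        chain_graph.add_statement(st_)
        assert kept[0].provenance == "asserted"


# -------------------------------------------------------------------- OBO

MINI_OBO = """\
format-version: 1.2

[Term]
id: X:A
name: alpha

[Term]
id: X:B
name: beta
is_a: X:A ! alpha

[Term]
id: X:C
name: gamma
is_a: X:B
"""


class TestParseObo:
    def test_minimal_chain(self):
        g = parse_obo(MINI_OBO)
        assert len(g.nodes) == 3
        assert g.n_statements() == 2
        assert g.has_statement(C("X:B"), IS_A, C("X:A"))
        assert all(s.provenance == "asserted" for s in g.statements)

    def test_empty_file(self):
        g = parse_obo("")
        assert len(g.nodes) == 0 and g.n_statements() == 0

    def test_missing_id_is_error(self):
        with pytest.raises(OboParseError, match="line"):
            parse_obo("[Term]\nname: orphan\n")

    def test_undeclared_relation_is_error(self):
        with pytest.raises(OboParseError, match="undeclared relation"):
            parse_obo("[Term]\nid: X:A\nrelationship: regulates X:B\n")

    def test_unknown_tags_ignored(self, caplog):
        g = parse_obo("[Term]\nid: X:A\ndef: something\nxref: Y:1\n")
        assert len(g.nodes) == 1

    def test_stanza_counts_match_line_count_oracle(self):
        """12-stanza fixture: node/statement counts equal a line-by-line
        tally of stanzas and is_a/relationship lines."""
        rng = random.Random(5)
        lines = ["format-version: 1.2", "", "[Typedef]", "id: part_of",
                 "name: part_of", "is_transitive: true", ""]
        terms = [f"X:{i:02d}" for i in range(12)]
        for i, t in enumerate(terms):
            lines += ["[Term]", f"id: {t}", f"name: term {i}"]
            for parent in rng.sample(terms[:i], min(i, rng.randint(0, 2))):
                if rng.random() < 0.5:
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: part_of {parent}")
            lines.append("")
        text = "\n".join(lines)

        # independent oracle: count stanzas and statement lines
        n_terms = sum(1 for ln in text.splitlines() if ln == "[Term]")
        n_links = sum(1 for ln in text.splitlines()
                      if ln.startswith("is_a:") or ln.startswith("relationship:"))

        g = parse_obo(text)
        assert len(g.nodes) == n_terms
        assert g.n_statements() == n_links

    def test_agrees_with_obonet(self, tmp_path):
        import obonet

        path = tmp_path / "mini.obo"
        path.write_text(MINI_OBO)
        ref = obonet.read_obo(path)
        g = parse_obo(MINI_OBO)
        assert set(map(str, g.nodes)) == set(ref.nodes)
        ref_edges = {(u, v) for u, v, k in ref.edges(keys=True) if k == "is_a"}
        ours = {(str(s.subject), str(s.object)) for s in g.statements
                if s.predicate == IS_A}
        assert ours == ref_edges


class TestOboRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_parse_of_serialize_reproduces_graph(self, seed):
        g = random_rule_graph(seed, max_nodes=40, max_statements=80)
        back = parse_obo(serialize_obo(g), relations=g.relations)
        assert set(back.nodes) == set(g.nodes)
        assert back.statement_keys() == {
            s.key for s in g.statements if s.provenance == "asserted"}

    def test_labels_survive(self, chain_graph):
        chain_graph.add_node(C("X:A"), label="alpha")
        back = parse_obo(serialize_obo(chain_graph))
        assert back.nodes[C("X:A")].label in ("alpha", "")  # label kept if set
        assert back.statement_keys() == chain_graph.statement_keys()


# ---------------------------------------------------------------- assemble

class TestAssembleUlo:
    def test_default_spec(self):
        ulo = assemble_ulo()
        assert 14 <= len(ulo.nodes) <= 17
        bp = find_by_label(ulo, "biological process")
        root = find_by_label(ulo, "entity")
        # every non-root has an is_a path to the root
        for n in ulo.nodes:
            if n == root:
                continue
            assert root in ulo.ancestors(n, (IS_A,))
        assert bp in ulo.nodes

    def test_singleton(self):
        g = assemble_ulo([("U:1", "only", None)])
        assert len(g.nodes) == 1 and g.n_statements() == 0

    def test_cycle_rejected(self):
        with pytest.raises(GraphError, match="cycle"):
            assemble_ulo([("U:1", "a", "U:2"), ("U:2", "b", "U:1"),
                          ("U:0", "root", None)])

    def test_multiple_roots_rejected(self):
        with pytest.raises(GraphError, match="root"):
            assemble_ulo([("U:1", "a", None), ("U:2", "b", None)])


class TestExtractSubdomain:
    def test_no_descendants_gives_singleton(self, chain_graph):
        sub = extract_subdomain(chain_graph, C("X:C"))
        assert set(sub.nodes) == {C("X:C")} and sub.n_statements() == 0

    def test_missing_root_names_curie(self, chain_graph):
        with pytest.raises(GraphError, match="X:nope"):
            extract_subdomain(chain_graph, C("X:nope"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reverse_bfs_oracle(self, seed):
        import networkx as nx

        g = random_rule_graph(seed, max_nodes=30, max_statements=60)
        root = sorted(g.nodes, key=str)[0]
        sub = extract_subdomain(g, root, (IS_A, PART_OF))

        dag = nx.DiGraph()
        dag.add_nodes_from(g.nodes)
        for s in g.statements:
            if s.predicate in (IS_A, PART_OF):
                dag.add_edge(s.subject, s.object)
        expected = set(nx.ancestors(dag, root)) | {root}
        assert set(sub.nodes) == expected
        # all statements among the kept node set are retained
        expected_statements = {s.key for s in g.statements
                               if s.subject in expected and s.object in expected}
        assert sub.statement_keys() == expected_statements

    def test_nested_roots_give_nested_statement_sets(self, chain_graph):
        g = chain_graph
        for i in range(6):
            g.add_node(C(f"X:D{i}"))
            g.assert_triple(C(f"X:D{i}"), IS_A, C("X:C" if i % 2 else "X:B"))
        subs = [extract_subdomain(g, C(r)) for r in ("X:A", "X:B", "X:C")]
        assert subs[2].statement_keys() <= subs[1].statement_keys()
        assert subs[1].statement_keys() <= subs[0].statement_keys()


class TestLinkAndMerge:
    def test_link_adds_exactly_one_statement(self):
        ulo = assemble_ulo()
        frag = KnowledgeGraph("frag", default_relation_types())
        frag.add_node(C("GO:1"), label="fragment root")
        anchor = find_by_label(ulo, "biological process")
        merged = link_to_ulo(ulo, frag, C("GO:1"), anchor)
        assert len(merged.nodes) == len(ulo.nodes) + 1
        assert merged.n_statements() == ulo.n_statements() + 1
        # idempotent: re-linking adds nothing
        again = link_to_ulo(merged, frag, C("GO:1"), anchor)
        assert again.n_statements() == merged.n_statements()

    def test_link_missing_anchor(self):
        ulo = assemble_ulo()
        frag = KnowledgeGraph("frag", default_relation_types())
        frag.add_node(C("GO:1"))
        with pytest.raises(GraphError):
            link_to_ulo(ulo, frag, C("GO:1"), C("ULO:9999999"))

    def test_merge_idempotent(self, chain_graph):
        m = merge_graphs([chain_graph, chain_graph], "m")
        assert set(m.nodes) == set(chain_graph.nodes)
        assert m.statement_keys() == chain_graph.statement_keys()

    def test_merge_disjoint_counts_add(self):
        a = KnowledgeGraph("a", default_relation_types())
        b = KnowledgeGraph("b", default_relation_types())
        for i in range(5):
            a.add_node(C(f"A:{i}"))
            b.add_node(C(f"B:{i}"))
        for i in range(4):
            a.assert_triple(C(f"A:{i+1}"), IS_A, C(f"A:{i}"))
            b.assert_triple(C(f"B:{i+1}"), IS_A, C(f"B:{i}"))
        m = merge_graphs([a, b], "m")
        assert len(m.nodes) == 10
        assert m.n_statements() == a.n_statements() + b.n_statements()

    @pytest.mark.parametrize("seed", range(4))
    def test_merge_equals_set_union_oracle(self, seed):
        g1 = random_rule_graph(seed, max_nodes=25, max_statements=50)
        g2 = random_rule_graph(seed + 100, max_nodes=25, max_statements=50)
        m = merge_graphs([g1, g2], "m")
        assert m.statement_keys() == g1.statement_keys() | g2.statement_keys()
        # associative and commutative up to statement-set equality
        m2 = merge_graphs([g2, g1], "m2")
        assert m.statement_keys() == m2.statement_keys()
        m3 = merge_graphs([merge_graphs([g1, g2]), g1], "m3")
        assert m3.statement_keys() == m.statement_keys()

    def test_conflicting_relation_metadata_is_error(self):
        r = Curie("R", "t")
        g1 = KnowledgeGraph("g1", {r: RelationType(r, "t", transitive=True)})
        g2 = KnowledgeGraph("g2", {r: RelationType(r, "t", transitive=False)})
        with pytest.raises(GraphError, match="conflicting"):
            merge_graphs([g1, g2])


class TestNTriples:
    def test_deterministic_and_underscore_dialect(self, chain_graph):
        chain_graph.add_node(C("X:A"), label="alpha")
        nt = to_ntriples(chain_graph, base_iri="http://kb.test/")
        assert nt == to_ntriples(chain_graph, base_iri="http://kb.test/")
        assert "<http://kb.test/X_B>" in nt
        assert '"alpha"' in nt

    def test_provenance_filter(self, chain_graph):
        from gexkg.inference import compute_closure

        closed = compute_closure(chain_graph).graph
        inferred_nt = to_ntriples(closed, provenance="inferred")
        assert "X_C" in inferred_nt  # C is_a A is inferred by transitivity
        asserted_nt = to_ntriples(closed, provenance="asserted")
        assert len(asserted_nt.splitlines()) < len(
            to_ntriples(closed).splitlines())
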