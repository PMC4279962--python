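"""Readers, ID-mapping filter, protein selection, graph population."""

from __future__ import annotations

import io
import random

import pytest

from gexkg.integration import (
    AnnotationRecord,
    IdMapping,
    InteractionRecord,
    OrthologyPair,
    PathwayMembership,
    ProteinInfo,
    RegulatoryEdge,
    apply_id_mapping,
    extend_by_association,
    populate_graph,
    read_gaf,
    read_mitab,
    read_table,
    select_core_proteins,
)
from gexkg.model import (
    Curie,
    GraphError,
    KnowledgeGraph,
    default_relation_types,
)
from conftest import C


def gaf_line(protein="P00001", go="GO:0000001", aspect="P", db="UniProtKB",
             taxon="taxon:9606"):
    cols = [db, protein, protein, "", go, "REF:1", "IEA", "", aspect,
            "", "", "protein", taxon, "20140101", "SYN", "", ""]
    return "\t".join(cols)


class TestReadGaf:
    def test_comments_skipped(self):
        text = "!gaf-version: 2.1\n! comment\n" + "\n".join(
            gaf_line(protein=f"P{i:05d}") for i in range(4))
        recs = read_gaf(text)
        assert len(recs) == 4 and recs.skipped == 0
        assert recs[0].protein == C("UniProtKB:P00000") or recs[0].protein
        assert recs[0].taxon == C("NCBITaxon:9606")

    def test_mixed_validity_matches_row_validator_oracle(self):
        """Accepted count equals an independent per-row validator."""
        rng = random.Random(11)
        rows = []
        for i in range(50):
            kind = rng.random()
            if kind < 0.6:
                rows.append(gaf_line(protein=f"P{i:05d}"))
            elif kind < 0.75:
                rows.append(gaf_line(go="XX:123"))       # non-GO term
            elif kind < 0.9:
                rows.append(gaf_line(aspect="Z"))        # bad aspect
            else:
                rows.append("too\tfew\tcolumns")
        text = "\n".join(rows)

        def row_valid(line: str) -> bool:  # independent validator
            cols = line.split("\t")
            return (len(cols) >= 15 and cols[4].startswith("GO:")
                    and cols[8] in ("P", "F", "C"))

        expected = sum(row_valid(r) for r in rows)
        recs = read_gaf(text)
        assert len(recs) == expected
        assert recs.skipped == 50 - expected


class TestReadMitab:
    def test_interaction_type_curie_extracted(self):
        row = "\t".join([
            "uniprotkb:P11111", "uniprotkb:P16220", "-", "-", "-", "-", "-",
            "-", "-", "-", "-", 'psi-mi:"MI:0407"(direct interaction)', "-",
            "intact:EBI-000001", "-"])
        recs = read_mitab("#header\n" + row)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.interaction_type == C("MI:0407")
        assert rec.interaction_id == C("intact:EBI-000001")
        assert rec.participant_a == C("UniProtKB:P11111")

    def test_malformed_rows_counted(self):
        recs = read_mitab("a\tb\tc\n")
        assert len(recs) == 0 and recs.skipped == 1


class TestReadTable:
    def test_missing_columns_named(self):
        stream = io.StringIO("protein\tfoo\nUniProtKB:P1\tx\n")
        with pytest.raises(GraphError, match="pathway"):
            read_table(stream, ["protein", "pathway"])


class TestIdMapping:
    def make_records(self, n):
        return [AnnotationRecord(C(f"UniProtKB:P{i:03d}"), C("GO:0000001"), "P")
                for i in range(n)]

    def test_empty_mapping_drops_all(self):
        kept, dropped = apply_id_mapping(self.make_records(5), IdMapping())
        assert kept == [] and dropped == 5

    def test_full_mapping_drops_none(self):
        recs = self.make_records(5)
        mapping = IdMapping.identity([r.protein for r in recs])
        kept, dropped = apply_id_mapping(recs, mapping)
        assert len(kept) == 5 and dropped == 0

    def test_partial_mapping_matches_scan_oracle(self):
        rng = random.Random(3)
        recs = self.make_records(20)
        mapped = set(rng.sample(range(20), 13))
        mapping = IdMapping.identity(
            [C(f"UniProtKB:P{i:03d}") for i in mapped])
        kept, dropped = apply_id_mapping(recs, mapping)
        # brute-force scan oracle
        expected_kept = [r for i, r in enumerate(recs) if i in mapped]
        assert kept == expected_kept
        assert dropped == 7

    def test_interaction_needs_both_participants(self):
        rec = InteractionRecord(C("intact:EBI-1"), C("UniProtKB:A"),
                                C("UniProtKB:B"), C("MI:0407"))
        mapping = IdMapping.identity([C("UniProtKB:A")])
        kept, dropped = apply_id_mapping([rec], mapping)
        assert kept == [] and dropped == 1

    def test_canonicalization_substitutes(self):
        rec = PathwayMembership(C("ensembl:E1"), C("KEGG:ko1"))
        mapping = IdMapping({("ensembl", "E1"): C("UniProtKB:P1")})
        kept, _ = apply_id_mapping([rec], mapping)
        assert kept[0].protein == C("UniProtKB:P1")


class TestSelectCore:
    def seed_graph(self, terms):
        g = KnowledgeGraph("seed", default_relation_types())
        for t in terms:
            g.add_node(C(t))
        return g

    def test_no_p_aspect_gives_empty(self):
        seed = self.seed_graph(["GO:1"])
        annots = [AnnotationRecord(C("UniProtKB:P1"), C("GO:1"), "F")]
        assert select_core_proteins(annots, seed) == set()

    def test_matches_nested_loop_oracle(self):
        seed = self.seed_graph(["GO:1", "GO:2"])
        all_terms = ["GO:1", "GO:2", "GO:3", "GO:4", "GO:5"]
        rng = random.Random(9)
        annots = [
            AnnotationRecord(C(f"UniProtKB:P{i % 4}"), C(rng.choice(all_terms)),
                             rng.choice("PPF"))
            for i in range(6)
        ]
        expected = set()
        for a in annots:  # nested-loop membership oracle
            for t in seed.nodes:
                if a.aspect == "P" and a.go_term == t:
                    expected.add(a.protein)
        assert select_core_proteins(annots, seed) == expected

    def test_monotone_in_seed(self):
        narrow = self.seed_graph(["GO:1"])
        wide = self.seed_graph(["GO:1", "GO:2"])
        annots = [AnnotationRecord(C(f"UniProtKB:P{i}"), C(f"GO:{1 + i % 2}"), "P")
                  for i in range(6)]
        assert select_core_proteins(annots, narrow) <= \
            select_core_proteins(annots, wide)


class TestExtendByAssociation:
    def test_empty_core(self):
        assert extend_by_association(set()) == set()

    def test_single_round_stops_at_direct_partners(self):
        a, b, c = (C(f"UniProtKB:{x}") for x in "ABC")
        inter = [InteractionRecord(C("intact:1"), a, b, C("MI:0407")),
                 InteractionRecord(C("intact:2"), b, c, C("MI:0407"))]
        assert extend_by_association({a}, inter) == {a, b}
        assert extend_by_association({a}, inter, rounds=2) == {a, b, c}

    def test_matches_one_round_neighborhood_oracle(self):
        rng = random.Random(21)
        prots = [C(f"UniProtKB:P{i:02d}") for i in range(30)]
        inter = [InteractionRecord(C(f"intact:{i}"), *rng.sample(prots, 2),
                                   C("MI:0407")) for i in range(25)]
        pw = [PathwayMembership(rng.choice(prots), C(f"KEGG:pw{i % 4}"))
              for i in range(20)]
        orth = []
        for i in range(10):
            x, y = rng.sample(prots, 2)
            orth.append(OrthologyPair(x, y))
        core = set(rng.sample(prots, 5))

        expected = set(core)  # brute-force one-round union
        for p in prots:
            for rec in inter:
                if {rec.participant_a, rec.participant_b} & core and \
                        p in (rec.participant_a, rec.participant_b):
                    expected.add(p)
            for m in pw:
                if m.protein == p:
                    for m2 in pw:
                        if m2.pathway == m.pathway and m2.protein in core:
                            expected.add(p)
            for o in orth:
                if o.as_frozenset() & core and p in o.as_frozenset():
                    expected.add(p)
        assert extend_by_association(core, inter, pw, orth) == expected


class TestPopulateGraph:
    def seed(self):
        g = KnowledgeGraph("seed", default_relation_types())
        for t in ("GO:1", "GO:2", "GO:3"):
            g.add_node(C(t))
        return g

    def test_single_annotation(self):
        p = C("UniProtKB:P1")
        graph, report = populate_graph(
            self.seed(), {p},
            annotations=[AnnotationRecord(p, C("GO:1"), "P")])
        assert report.statements_added == {"participates_in": 1}
        from gexkg.model import PARTICIPATES_IN
        assert graph.has_statement(p, PARTICIPATES_IN, C("GO:1"))

    def test_interaction_reified_with_three_statements(self):
        p1, p2 = C("UniProtKB:P1"), C("UniProtKB:P2")
        rec = InteractionRecord(C("intact:EBI-1"), p1, p2, C("MI:0914"))
        graph, report = populate_graph(self.seed(), {p1, p2},
                                       interactions=[rec])
        assert report.statements_added == {"has_participant": 2,
                                           "has_interaction_type": 1}
        assert graph.nodes[C("intact:EBI-1")].category == "interaction"

    def test_full_fixture_matches_per_record_tally(self):
        rng = random.Random(31)
        prots = [C(f"UniProtKB:P{i:02d}") for i in range(30)]
        seed = self.seed()
        annots = [AnnotationRecord(rng.choice(prots),
                                   C(f"GO:{rng.randint(1, 4)}"),
                                   rng.choice("PFC")) for _ in range(60)]
        inter = [InteractionRecord(C(f"intact:{i}"), *rng.sample(prots, 2),
                                   C("MI:0407")) for i in range(10)]
        pw = [PathwayMembership(rng.choice(prots), C(f"KEGG:pw{i % 3}"))
              for i in range(15)]
        infos = [ProteinInfo(p, C(f"NCBIGene:{i}") if i % 2 else None,
                             f"S{i}", ("Phosphoserine 1",) if i % 5 == 0 else (),
                             C("NCBITaxon:9606"))
                 for i, p in enumerate(prots)]
        edges = [RegulatoryEdge(rng.choice(prots), f"TG{i % 4}",
                                rng.choice(("activator", "repressor", "unknown")),
                                "TFactS") for i in range(12)]
        graph, report = populate_graph(seed, set(prots), annots, inter, pw,
                                       infos, edges)

        # independent per-record tallies (dedup on the statement key)
        seen = set()
        tally: dict[str, int] = {}
        aspect_pred = {"P": "participates_in", "F": "has_function",
                       "C": "located_in"}
        for a in annots:
            if a.go_term.local_id in "123":  # GO:4 is outside the seed
                key = (a.protein, aspect_pred[a.aspect], a.go_term)
                if key not in seen:
                    seen.add(key)
                    tally[aspect_pred[a.aspect]] = \
                        tally.get(aspect_pred[a.aspect], 0) + 1
        for r in inter:
            tally["has_participant"] = tally.get("has_participant", 0) + (
                1 if r.participant_a == r.participant_b else 2)
            tally["has_interaction_type"] = tally.get("has_interaction_type", 0) + 1
        pw_seen = set()
        for m in pw:
            if (m.protein, m.pathway) not in pw_seen:
                pw_seen.add((m.protein, m.pathway))
                tally["member_of_pathway"] = tally.get("member_of_pathway", 0) + 1
        for i, info in enumerate(infos):
            if info.gene is not None:
                tally["encoded_by"] = tally.get("encoded_by", 0) + 1
            tally["has_modified_residue"] = (
                tally.get("has_modified_residue", 0) + len(info.modified_residues))
            tally["in_taxon"] = tally.get("in_taxon", 0) + 1
        edge_pred = {"activator": "activates", "repressor": "represses",
                     "unknown": "regulates"}
        edge_seen = set()
        for e in edges:
            key = (e.regulator, edge_pred[e.mode], e.target_gene)
            if key not in edge_seen:
                edge_seen.add(key)
                tally[edge_pred[e.mode]] = tally.get(edge_pred[e.mode], 0) + 1

        assert report.statements_added == tally
        assert report.annotations_outside_seed == sum(
            1 for a in annots if a.go_term.local_id == "4")

    def test_gene_nodes_never_exceed_protein_nodes(self):
        graph, _ = populate_graph(
            self.seed(), {C("UniProtKB:P1"), C("UniProtKB:P2")},
            infos=[ProteinInfo(C("UniProtKB:P1"), C("NCBIGene:1"), "S1")])
        genes = sum(1 for n in graph.nodes.values() if n.category == "gene")
        prots = sum(1 for n in graph.nodes.values() if n.category == "protein")
        assert genes <= prots

    def test_regulatory_edge_targets_resolve_or_stay_symbolic(self):
        p = C("UniProtKB:P1")
        graph, _ = populate_graph(
            self.seed(), {p},
            infos=[ProteinInfo(p, C("NCBIGene:7"), "JUN")],
            edges=[RegulatoryEdge(p, "jun", "activator", "TFactS"),
                   RegulatoryEdge(p, "MYST", "repressor", "PAZAR")])
        from gexkg.model import ACTIVATES, REPRESSES
        assert graph.has_statement(p, ACTIVATES, C("NCBIGene:7"))
        assert graph.has_statement(p, REPRESSES, C("SYMBOL:MYST"))
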