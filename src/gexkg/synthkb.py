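"""Synthetic knowledge-base fixtures with planted ground truth.

The generator emits the same standard formats the readers consume — an OBO
ontology, a GAF annotation file, a PSI-MI TAB interaction file and the TSV
side tables — describing a random single-rooted term DAG, a protein
population annotated to it, interactions, pathway memberships, orthology
pairs and regulatory edges.

The query-term anchors (the GO / MI / KEGG identifiers and the CREB1 /
TCF7L2 accessions the built-in templates reference) are injected with
their real identifiers so the templates run unmodified; every other
synthetic term lives in the reserved ``SYN`` namespace and can never
collide with them.  A configurable number of *planted* regulators is
constructed to satisfy a chosen template; with probability
``p_inferred_only`` a plant's qualifying annotations are placed on strict
``is_a`` descendants of the query terms, so that only the computed closure
(annotation propagation across subsumption) retrieves it.  The plant
ledger is exact ground truth for recall/precision tests.

:func:`shared_targets_fixture` loads the packaged worked example: the
twenty published shared-target rows between five novel DbTFs (CREM, FOXP3,
TCF7L2, SMAD3, PARP1) and the two core DbTFs (CREB1, NFkB1), with the
AR42J expression / gastrin responsiveness calls, plus the expression flags
of the regulators themselves (CREM, TCF7L2 and PARP1 are expressed).
"""

from __future__ import annotations

import importlib.resources
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .integration import (
    AnnotationRecord,
    IdMapping,
    InteractionRecord,
    OrthologyPair,
    PathwayMembership,
    ProteinInfo,
    RegulatoryEdge,
)
from .model import (
    Curie,
    GraphError,
    KnowledgeGraph,
    IS_A,
    PART_OF,
    default_relation_types,
    dump_relation_metadata,
    serialize_obo,
)
from .prioritize import ExpressionEvidence, LiteratureEvidence
from .query import BUILTIN_TEMPLATE_NAMES, DEFAULT_TARGET_IDS


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic KB.  Same seed, same config -> byte-identical
    output files."""

    seed: int = 0
    n_terms: int = 40            # background biological-process terms
    n_proteins: int = 30         # background proteins
    dag_branching: float = 1.3   # mean parents drawn per background term
    n_interactions: int = 25
    n_pathways: int = 3
    n_regulatory_edges: int = 20
    n_planted_regulators: int = 5
    planting_mode: str = "Q1"    # which builtin template the plants satisfy
    p_inferred_only: float = 0.5
    taxon: str = "NCBITaxon:9606"

    def __post_init__(self) -> None:
        for f in ("n_terms", "n_proteins", "n_interactions", "n_pathways",
                  "n_regulatory_edges", "n_planted_regulators"):
            if getattr(self, f) < 0:
                raise GraphError(f"{f} must be >= 0")
        if self.planting_mode not in BUILTIN_TEMPLATE_NAMES:
            raise GraphError(
                f"planting_mode must be one of {BUILTIN_TEMPLATE_NAMES}, "
                f"got {self.planting_mode!r}")
        if not 0.0 <= self.p_inferred_only <= 1.0:
            raise GraphError("p_inferred_only must be in [0, 1]")


@dataclass(frozen=True)
class PlantLedger:
    """Exact ground truth about the planted regulators."""

    template: str
    planted: tuple[Curie, ...]
    inferred_only: frozenset[Curie]

    @property
    def asserted_visible(self) -> frozenset[Curie]:
        return frozenset(self.planted) - self.inferred_only


# the identifiers the builtin templates reference
_ANCHOR = dict(DEFAULT_TARGET_IDS)

#: the three nested sub-domain roots, widest to narrowest
SUBDOMAIN_ROOTS: tuple[Curie, ...] = (
    Curie("GO", "0010467"),  # gene expression
    Curie("GO", "0010468"),  # regulation of gene expression
    Curie("GO", "0006355"),  # regulation of transcription, DNA-dependent
)
SUBDOMAIN_NAMES = ("GeXO", "ReXO", "ReTO")

ROOT = Curie("SYN", "0000000")
MF_ROOT = Curie("SYN", "0000002")
CC_ROOT = Curie("SYN", "0000003")
PW_ROOT = Curie("SYN", "0000004")
MI_ROOT = Curie("MI", "0190")

_BP_ANCHORS = ("pos_reg_creb_activity", "neg_reg_creb_activity",
               "pos_reg_dbtf_activity", "neg_reg_dbtf_activity",
               "reg_dbtf_activity", "neg_reg_nfkb_activity")
_MF_ANCHORS = ("creb_binding_function", "histone_acetyltransferase",
               "histone_deacetylase", "ubiquitin_binding")
_CC_ANCHORS = ("ubiquitin_ligase_complex",)
_MI_ANCHORS = ("direct_interaction", "physical_association",
               "ubiquitination_reaction")


@dataclass
class SyntheticKB:
    """The generated fixture bundle, in memory."""

    config: SynthConfig
    ontology: KnowledgeGraph
    annotations: list[AnnotationRecord]
    interactions: list[InteractionRecord]
    pathways: list[PathwayMembership]
    orthology: list[OrthologyPair]
    protein_infos: list[ProteinInfo]
    regulatory_edges: list[RegulatoryEdge]
    dbtf_catalog: set[Curie]
    id_mapping: IdMapping
    expression: ExpressionEvidence
    regulator_expression: ExpressionEvidence
    membership: set[Curie]
    literature: LiteratureEvidence
    ledger: PlantLedger
    reserved_descendants: dict[Curie, list[Curie]] = field(default_factory=dict)

    # ---------------------------------------------------------------- write
    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text files; returns path per role."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _p(role: str, filename: str) -> Path:
            paths[role] = out / filename
            return paths[role]

        _p("ontology", "ontology.obo").write_text(
            serialize_obo(self.ontology), encoding="utf-8")
        _p("annotations", "annotations.gaf").write_text(
            _gaf_text(self.annotations), encoding="utf-8")
        _p("interactions", "interactions.mitab").write_text(
            _mitab_text(self.interactions), encoding="utf-8")
        _p("pathways", "pathways.tsv").write_text(
            _tsv(("protein", "pathway"),
                 ((str(p.protein), str(p.pathway)) for p in self.pathways)),
            encoding="utf-8")
        _p("orthology", "orthology.tsv").write_text(
            _tsv(("protein_a", "protein_b"),
                 ((str(p.protein_a), str(p.protein_b)) for p in self.orthology)),
            encoding="utf-8")
        _p("protein_info", "proteins.tsv").write_text(
            _tsv(("accession", "gene", "symbol", "modified_residues", "taxon"),
                 ((str(i.accession), str(i.gene) if i.gene else "",
                   i.symbol, "|".join(i.modified_residues),
                   str(i.taxon) if i.taxon else "")
                  for i in self.protein_infos)),
            encoding="utf-8")
        _p("regulatory_edges", "regulatory_edges.tsv").write_text(
            _tsv(("regulator", "target_gene", "mode", "source_db"),
                 ((str(e.regulator), e.target_gene, e.mode, e.source_db)
                  for e in self.regulatory_edges)),
            encoding="utf-8")
        _p("dbtf_catalog", "dbtf_catalog.tsv").write_text(
            _tsv(("protein",), ((str(c),) for c in sorted(self.dbtf_catalog, key=str))),
            encoding="utf-8")
        _p("id_mapping", "id_mapping.tsv").write_text(
            _tsv(("source_namespace", "source_id", "canonical"),
                 ((ns, local, str(canon)) for (ns, local), canon
                  in sorted(self.id_mapping.entries.items()))),
            encoding="utf-8")
        _p("expression", "expression.tsv").write_text(
            _expression_tsv(self.expression), encoding="utf-8")
        _p("regulator_expression", "regulator_expression.tsv").write_text(
            _expression_tsv(self.regulator_expression), encoding="utf-8")
        _p("membership", "membership.tsv").write_text(
            _tsv(("protein",), ((str(c),) for c in sorted(self.membership, key=str))),
            encoding="utf-8")
        _p("literature", "literature.tsv").write_text(
            _tsv(("entity",), ((e,) for e in sorted(self.literature.entities))),
            encoding="utf-8")
        _p("relations", "relations.yaml")
        dump_relation_metadata(default_relation_types(), paths["relations"])
        _p("ledger", "ledger.json").write_text(json.dumps({
            "template": self.ledger.template,
            "planted": [str(c) for c in self.ledger.planted],
            "inferred_only": sorted(str(c) for c in self.ledger.inferred_only),
        }, indent=2) + "\n", encoding="utf-8")

        runconfig = {
            "seed": self.config.seed,
            "inputs": {role: str(path.name) for role, path in paths.items()},
            "subdomain_roots": [str(c) for c in SUBDOMAIN_ROOTS],
            "graph_names": list(SUBDOMAIN_NAMES),
            "fragments": [
                {"root": str(MF_ROOT), "anchor": "molecular function"},
                {"root": str(CC_ROOT), "anchor": "cellular component"},
                {"root": str(PW_ROOT), "anchor": "pathway"},
                {"root": str(MI_ROOT), "anchor": "interaction type"},
            ],
            "template": self.config.planting_mode,
        }
        _p("runconfig", "runconfig.yaml")
        with open(paths["runconfig"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(runconfig, fh, sort_keys=True)
        return paths


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def generate_kb(config: SynthConfig) -> SyntheticKB:
    """Generate a synthetic knowledge base with planted regulators."""
    rng = random.Random(config.seed)
    taxon = Curie.parse(config.taxon)

    graph = KnowledgeGraph("SYN-source", default_relation_types())

    def node(curie: Curie, label: str = "") -> Curie:
        graph.add_node(curie, label=label)
        return curie

    def isa(child: Curie, parent: Curie) -> None:
        graph.assert_triple(child, IS_A, parent, source="synth")

    node(ROOT, "entity")
    node(MF_ROOT, "molecular function")
    node(CC_ROOT, "cellular component")
    node(PW_ROOT, "pathway")
    node(MI_ROOT, "interaction type")
    for r in (MF_ROOT, CC_ROOT, PW_ROOT, MI_ROOT):
        isa(r, ROOT)

    prev = ROOT
    for root_curie in SUBDOMAIN_ROOTS:
        node(root_curie)
        isa(root_curie, prev)
        prev = root_curie
    narrow = SUBDOMAIN_ROOTS[-1]

    # anchors + reserved descendant terms (planting targets)
    reserved: dict[Curie, list[Curie]] = {}

    def add_anchor(role: str, parent: Curie, n_desc: int = 2) -> Curie:
        anchor = _ANCHOR[role]
        node(anchor, role)
        isa(anchor, parent)
        desc = []
        for j in range(n_desc):
            # annotation targets must live in the GO namespace (GAF);
            # the SYN- marker keeps them collision-free with real GO ids
            d = node(Curie("GO", f"SYN-{role}-sub{j}"), f"{role} subtype {j}")
            isa(d, anchor)
            desc.append(d)
        # one grandchild for depth
        g = node(Curie("GO", f"SYN-{role}-sub0-leaf"), f"{role} leaf")
        isa(g, desc[0])
        desc.append(g)
        reserved[anchor] = desc
        return anchor

    for role in _BP_ANCHORS:
        add_anchor(role, narrow)
    for role in _MF_ANCHORS:
        add_anchor(role, MF_ROOT)
    for role in _CC_ANCHORS:
        add_anchor(role, CC_ROOT)
    for role in _MI_ANCHORS:
        anchor = _ANCHOR[role]
        node(anchor, role)
        isa(anchor, MI_ROOT)
    bg_mi_type = node(Curie("MI", "9999"), "synthetic interaction type")
    isa(bg_mi_type, MI_ROOT)

    pw_anchor = node(_ANCHOR["ubiquitin_proteolysis_pathway"],
                     "ubiquitin mediated proteolysis")
    isa(pw_anchor, PW_ROOT)

    # background BP DAG: each term picks parents uniformly from the pool,
    # seeded with the three chain roots so the DAG stays single-rooted
    bp_pool = list(SUBDOMAIN_ROOTS)
    bp_background: list[Curie] = []
    p_extra = max(0.0, min(0.9, config.dag_branching - 1.0))
    for i in range(config.n_terms):
        t = node(Curie("GO", f"SYN-B{i:04d}"), f"synthetic process {i}")
        parents = {rng.choice(bp_pool)}
        if rng.random() < p_extra:
            parents.add(rng.choice(bp_pool))
        for p in sorted(parents, key=str):
            isa(t, p)
        bp_pool.append(t)
        bp_background.append(t)

    # narrow-attached background terms are present in all three sub-domains
    narrow_terms = [t for t in bp_background
                    if narrow in graph.ancestors(t, (IS_A,))]
    if not narrow_terms:
        t = node(Curie("GO", "SYN-Bnarrow"), "synthetic narrow process")
        isa(t, narrow)
        bp_background.append(t)
        narrow_terms = [t]

    mf_background: list[Curie] = []
    for i in range(max(2, config.n_terms // 4)):
        t = node(Curie("GO", f"SYN-F{i:04d}"), f"synthetic function {i}")
        isa(t, MF_ROOT)
        mf_background.append(t)
    cc_background: list[Curie] = []
    for i in range(max(2, config.n_terms // 4)):
        t = node(Curie("GO", f"SYN-C{i:04d}"), f"synthetic component {i}")
        isa(t, CC_ROOT)
        cc_background.append(t)
    # a little partonomy among components so the composition rule has work
    for i in range(1, len(cc_background)):
        if rng.random() < 0.5:
            graph.assert_triple(cc_background[i], PART_OF,
                                cc_background[rng.randrange(i)], source="synth")

    # ---------------------------------------------------------------- data
    creb1 = _ANCHOR["creb1"]
    tcf7l2 = _ANCHOR["tcf7l2"]
    background_proteins = [Curie("UniProtKB", f"SYNP{i:04d}")
                           for i in range(config.n_proteins)]
    planted_proteins = [Curie("UniProtKB", f"SYNT{i:04d}")
                        for i in range(config.n_planted_regulators)]
    all_proteins = background_proteins + planted_proteins + [creb1, tcf7l2]

    annotations: list[AnnotationRecord] = []

    # background annotations avoid every anchor subtree
    for p in background_proteins:
        for term in rng.sample(bp_background, min(len(bp_background),
                                                  rng.randint(2, 4))):
            _annotate_go(annotations, p, term, "P", taxon)
        if mf_background and rng.random() < 0.8:
            _annotate_go(annotations, p, rng.choice(mf_background), "F", taxon)
        if cc_background and rng.random() < 0.5:
            _annotate_go(annotations, p, rng.choice(cc_background), "C", taxon)
    # the query target proteins are core in every sub-domain
    for p in (creb1, tcf7l2):
        _annotate_go(annotations, p, rng.choice(narrow_terms), "P", taxon)

    # interactions among background proteins (never the query targets)
    interactions: list[InteractionRecord] = []
    interaction_counter = 0

    def add_interaction(a: Curie, b: Curie, itype: Curie) -> None:
        nonlocal interaction_counter
        interactions.append(InteractionRecord(
            Curie("intact", f"EBI-{interaction_counter:06d}"), a, b, itype))
        interaction_counter += 1

    bg_types = [Curie("MI", "9999"), _ANCHOR["direct_interaction"],
                _ANCHOR["physical_association"], _ANCHOR["ubiquitination_reaction"]]
    for _ in range(config.n_interactions):
        if len(background_proteins) < 2:
            break
        a, b = rng.sample(background_proteins, 2)
        add_interaction(a, b, rng.choice(bg_types))

    # pathways: background pathways plus the reserved degradation pathway
    pathways: list[PathwayMembership] = []
    bg_pathways = [Curie("KEGG", f"syn{i:05d}") for i in range(config.n_pathways)]
    for pw in bg_pathways:
        for p in rng.sample(background_proteins,
                            min(len(background_proteins), rng.randint(2, 5))):
            pathways.append(PathwayMembership(p, pw))

    orthology: list[OrthologyPair] = []
    for _ in range(max(0, config.n_proteins // 5)):
        if len(background_proteins) < 2:
            break
        a, b = rng.sample(background_proteins, 2)
        if not any(o.as_frozenset() == frozenset((a, b)) for o in orthology):
            orthology.append(OrthologyPair(a, b))

    # ------------------------------------------------------------- planting
    inferred_only: set[Curie] = set()
    mode = config.planting_mode

    def target_term(role: str, inferred: bool) -> Curie:
        anchor = _ANCHOR[role]
        if inferred:
            return rng.choice(reserved[anchor])
        return anchor

    for plant in planted_proteins:
        inferred = rng.random() < config.p_inferred_only
        if inferred:
            inferred_only.add(plant)
        if mode == "Q1":
            _annotate_go(annotations, plant,
                         target_term("pos_reg_creb_activity", inferred), "P", taxon)
        elif mode == "Q2":
            _annotate_go(annotations, plant,
                         target_term("neg_reg_creb_activity", inferred), "P", taxon)
        elif mode == "Q3":
            mf_role = rng.choice(("histone_acetyltransferase",
                                  "histone_deacetylase"))
            _annotate_go(annotations, plant, target_term(mf_role, inferred),
                         "F", taxon)
            _annotate_go(annotations, plant,
                         target_term("reg_dbtf_activity", inferred), "P", taxon)
            add_interaction(plant, creb1, _ANCHOR["physical_association"])
        elif mode == "Q4":
            _annotate_go(annotations, plant,
                         target_term("neg_reg_nfkb_activity", inferred), "P", taxon)
            second = rng.choice(("pathway", "function", "component"))
            if second == "pathway":
                pathways.append(PathwayMembership(
                    plant, _ANCHOR["ubiquitin_proteolysis_pathway"]))
            elif second == "function":
                _annotate_go(annotations, plant,
                             target_term("ubiquitin_binding", False), "F", taxon)
            else:
                _annotate_go(annotations, plant,
                             target_term("ubiquitin_ligase_complex", False),
                             "C", taxon)
        elif mode == "Q5":
            add_interaction(plant, tcf7l2, rng.choice(
                (_ANCHOR["physical_association"], _ANCHOR["direct_interaction"])))
            _annotate_go(annotations, plant,
                         target_term("neg_reg_dbtf_activity", inferred), "P", taxon)
            _annotate_go(annotations, plant,
                         target_term("pos_reg_dbtf_activity", inferred), "P", taxon)

    ledger = PlantLedger(mode, tuple(planted_proteins), frozenset(inferred_only))

    # -------------------------------------------------- side tables
    gene_counter = 1000
    infos: list[ProteinInfo] = []
    for i, p in enumerate(all_proteins):
        gene = None
        if rng.random() < 0.7:
            gene = Curie("NCBIGene", str(gene_counter))
            gene_counter += 1
        residues = ()
        if rng.random() < 0.3:
            residues = (f"Phosphoserine {rng.randint(1, 400)}",)
        infos.append(ProteinInfo(p, gene, f"SYM{i:04d}", residues, taxon))

    dbtf_catalog = set(planted_proteins) | {creb1, tcf7l2} | set(
        sorted(background_proteins, key=str)[: max(1, config.n_proteins // 4)])

    symbols = [f"TG{i:03d}" for i in range(10)]
    regulatory_edges: list[RegulatoryEdge] = []
    dbtf_list = sorted(dbtf_catalog, key=str)
    for _ in range(config.n_regulatory_edges):
        reg = rng.choice(dbtf_list)
        tg = rng.choice(symbols)
        regulatory_edges.append(RegulatoryEdge(
            reg, tg, rng.choice(("activator", "repressor", "unknown")),
            rng.choice(("TFactS", "PAZAR", "HTRI"))))

    id_mapping = IdMapping.identity(all_proteins)

    expr_pairs = {}
    for p in all_proteins:
        expressed = rng.random() < 0.6
        responsive = expressed and rng.random() < 0.5
        expr_pairs[p.local_id] = (expressed, responsive)
    for s in symbols:
        expressed = rng.random() < 0.6
        responsive = expressed and rng.random() < 0.5
        expr_pairs[s] = (expressed, responsive)
    expression = ExpressionEvidence.from_pairs(expr_pairs)
    regulator_expression = ExpressionEvidence.from_pairs(
        {p.local_id: expr_pairs[p.local_id] for p in all_proteins})

    membership = set(rng.sample(background_proteins,
                                min(len(background_proteins), 5)))
    literature = LiteratureEvidence.from_entities(
        p for p in all_proteins if rng.random() < 0.4)

    return SyntheticKB(
        config=config,
        ontology=graph,
        annotations=annotations,
        interactions=interactions,
        pathways=pathways,
        orthology=orthology,
        protein_infos=infos,
        regulatory_edges=regulatory_edges,
        dbtf_catalog=dbtf_catalog,
        id_mapping=id_mapping,
        expression=expression,
        regulator_expression=regulator_expression,
        membership=membership,
        literature=literature,
        ledger=ledger,
        reserved_descendants=reserved,
    )


def _annotate_go(annotations: list, protein: Curie, term: Curie, aspect: str,
                 taxon: Curie) -> None:
    if term.namespace != "GO":
        raise GraphError(f"cannot annotate to non-GO term {term}")
    annotations.append(AnnotationRecord(protein, term, aspect, "IEA", taxon))


# --------------------------------------------------------------------------
# Serialization helpers
# --------------------------------------------------------------------------

def _tsv(header: tuple[str, ...], rows) -> str:
    lines = ["\t".join(header)]
    lines.extend("\t".join(row) for row in rows)
    return "\n".join(lines) + "\n"


def _gaf_text(records) -> str:
    lines = ["!gaf-version: 2.1", "! synthetic gene-association fixture"]
    for r in records:
        taxon = f"taxon:{r.taxon.local_id}" if r.taxon else ""
        lines.append("\t".join([
            r.protein.namespace, r.protein.local_id, r.protein.local_id, "",
            str(r.go_term), "SYN:0000", r.evidence_code, "", r.aspect,
            "", "", "protein", taxon, "20140101", "SYN", "", "",
        ]))
    return "\n".join(lines) + "\n"


def _mitab_text(records) -> str:
    header = ("#ID(s) interactor A\tID(s) interactor B\tAlt. ID(s) interactor A\t"
              "Alt. ID(s) interactor B\tAlias(es) interactor A\t"
              "Alias(es) interactor B\tInteraction detection method(s)\t"
              "Publication 1st author(s)\tPublication Identifier(s)\t"
              "Taxid interactor A\tTaxid interactor B\tInteraction type(s)\t"
              "Source database(s)\tInteraction identifier(s)\tConfidence value(s)")
    lines = [header]
    for r in records:
        lines.append("\t".join([
            f"uniprotkb:{r.participant_a.local_id}",
            f"uniprotkb:{r.participant_b.local_id}",
            "-", "-", "-", "-", "-", "-", "-", "-", "-",
            f'psi-mi:"{r.interaction_type}"(synthetic)',
            "-", f"intact:{r.interaction_id.local_id}", "-",
        ]))
    return "\n".join(lines) + "\n"


def _expression_tsv(evidence: ExpressionEvidence) -> str:
    rows = (
        (entity, "yes" if flags[0] else "no", "yes" if flags[1] else "no")
        for entity, flags in sorted(evidence.flags.items())
    )
    return _tsv(("entity", "expressed", "responsive"), rows)


# --------------------------------------------------------------------------
# The packaged worked example (shared-target table)
# --------------------------------------------------------------------------

CORE_DBTFS = (Curie("UniProtKB", "CREB1"), Curie("UniProtKB", "NFkB1"))
NOVEL_DBTFS = tuple(Curie("UniProtKB", s)
                    for s in ("CREM", "FOXP3", "TCF7L2", "SMAD3", "PARP1"))
EXPRESSED_REGULATORS = ("CREM", "TCF7L2", "PARP1")


def shared_targets_fixture() -> tuple[list[RegulatoryEdge], ExpressionEvidence,
                                      ExpressionEvidence]:
    """Load the packaged shared-target worked example.

    Returns the regulatory edges (one novel-DbTF edge and one core-DbTF
    edge per table row), the expression/responsiveness evidence for the
    target genes, and the expression evidence for the novel regulators
    themselves.  The regulator identifiers use their gene symbols as
    accession placeholders.
    """
    ref = importlib.resources.files("gexkg").joinpath(
        "data/shared_targets_table.tsv")
    lines = ref.read_text(encoding="utf-8").strip().splitlines()
    header = lines[0].split("\t")
    edges: list[RegulatoryEdge] = []
    seen: set[tuple] = set()
    expr: dict[str, tuple[bool, bool]] = {}
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        novel = Curie("UniProtKB", row["novel_dbtf"])
        core = Curie("UniProtKB", row["core_dbtf"])
        mode = row["function"].lower()
        target = row["target_gene"]
        for reg, m in ((novel, mode), (core, "unknown")):
            key = (reg, target.upper())
            if key not in seen:
                seen.add(key)
                edges.append(RegulatoryEdge(reg, target, m, "TFactS"))
        flags = (row["ar42j_expressed"] == "Yes", row["gastrin_responsive"] == "Yes")
        prev = expr.get(target.upper())
        if prev is not None and prev != flags:
            raise GraphError(f"inconsistent expression flags for {target}")
        expr[target.upper()] = flags
    expression = ExpressionEvidence.from_pairs(expr)
    regulator_expression = ExpressionEvidence.from_pairs({
        c.local_id: (c.local_id in EXPRESSED_REGULATORS, False)
        for c in NOVEL_DBTFS
    })
    return edges, expression, regulator_expression


# backwards-friendly alias used in docs/examples
table2_fixture = shared_targets_fixture
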