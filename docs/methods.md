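# Methods

## The graph model

The store (`gexkg.model.KnowledgeGraph`) holds typed nodes and
relation-typed statements (triples). A node's category is a pure function
of its identifier namespace: `UniProtKB` → protein, `KEGG` → pathway,
`NCBIGene` → gene, `NCBITaxon` → taxon, `SSB` → modified residue,
`intact` → reified interaction, anything else → ontology class. Compact
identifiers render as `namespace:local_id` in OBO output and
`namespace_local_id` in exported URIs; both dialects round-trip because a
namespace may contain neither `:` nor `_`, and whitespace in local ids
(modified-residue names) is replaced by underscores at construction.

Two invariants are enforced at mutation time: every statement's subject,
object and predicate resolve to declared nodes and relations (closure
under reference), and `(subject, predicate, object)` is unique — on a
collision an asserted statement replaces an inferred one, never the
reverse. This makes graph merging a plain set union with
asserted-preferred deduplication, and makes `merge` associative,
commutative and idempotent up to statement-set equality.

The triple store is an in-process object with OBO 1.2 and N-Triples
serialization rather than a hosted SPARQL endpoint: the substance of the
method is the content and the closure, not the server. N-Triples export
places every node under a single configurable base IRI using the
underscore dialect; a provenance filter exports the asserted or inferred
layer separately.

## Building the nested application graphs

A concise upper-level ontology (~16 terms: entity, material entity,
process, attribute, …, with anchors "biological process", "molecular
function", "cellular component", "interaction type", "pathway") is
assembled from an (id, label, parent) spec, which must be acyclic with a
single root. Sub-domain fragments are extracted as a root term plus every
node from which the root is reachable along `is_a` / `part_of` (both
edge kinds by default; configurable), with all statements among the kept
nodes. Three nested Biological Process roots (gene expression ⊇
regulation of gene expression ⊇ regulation of transcription) give three
nested graphs; each fragment root is subordinated under its ULO anchor by
exactly one added `is_a` statement. When a wider fragment contains a
narrower sub-domain root, that root is linked to the anchor as well — all
three roots are biological processes — which keeps the three graphs'
statement sets strictly nested, a property the test suite asserts.

Population is protein-centric. Core proteins are those with at least one
Biological Process annotation (GAF aspect P) to a seed-ontology term;
they are extended by exactly one association round — interaction
partners, co-members of a KEGG pathway, orthologs. A single round keeps
growth bounded and reproducible; a `rounds` parameter exposes deeper
expansion for exploration. All evidence codes are accepted (an exclusion
list can be applied upstream); identifiers must pass the canonical ID
mapping or the whole record is dropped and counted — an unmapped entity
is never assigned a fabricated id. Annotations to terms outside the seed
ontology are skipped and counted: the seed defines each graph's
ontological scope, and this skip rule is also what keeps the narrow
graph's statements a subset of the wide graph's. Interactions are
reified (one `intact` node, two `has_participant`, one
`has_interaction_type`) so that the interaction *type* is queryable —
the templates must distinguish direct interaction (MI:0407) from
physical association (MI:0914). Gene nodes exist only when the protein
record carries an NCBI gene reference, so gene nodes never outnumber
protein nodes. Regulatory-edge targets are gene symbols normalized to
upper case, resolved to gene nodes through the symbol index when
possible and kept as `SYMBOL:` placeholders otherwise.

## The closure

Five rule kinds, driven entirely by declared relation metadata
(YAML-configurable; the shipped defaults are in
`gexkg.model.default_relation_types`):

| rule | semantics |
|---|---|
| reflexivity | for reflexive `r`, every node touching an `r` statement gains `x r x` |
| transitivity | `x r y`, `y r z` ⟹ `x r z` |
| superrelation | `x r y` ⟹ `x s y` for `s` a declared superrelation of `r` |
| composition | `x r y`, `y s z` ⟹ `x t z` when `r`'s table maps `s` to `t` |
| priority over subsumption | flagged `r` propagates across `is_a`: `x r y`, `y is_a z` ⟹ `x r z`; `w is_a x`, `x r y` ⟹ `w r y` |

Design choices where the attribute semantics were open:

* *Priority over subsumption* is implemented in both directions — object
  generalization and subject specialization — each independently
  toggleable and both on by default. This reproduces true-path-style
  propagation of protein annotations up the ontology, which is exactly
  what lets a query on a general term retrieve proteins annotated only
  to its descendants.
* *Reflexivity* is domain-restricted (only nodes already touching the
  relation), not universal: universal reflexivity is quadratic in the
  node count and adds nothing retrievable.
* The *composition* table ships small (`part_of ∘ part_of → part_of`,
  `located_in ∘ part_of → located_in`) and is fully config-driven.
* Default flags: `is_a`, `part_of` transitive; `part_of` reflexive;
  `participates_in`, `has_function`, `located_in` priority-over-
  subsumption; `activates`/`represses` have superrelation `regulates`.

`compute_closure` applies the rules in the fixed order (reflexivity,
superrelation, priority, transitivity, composition) in repeated sweeps
until a full sweep adds nothing. The statement space is finite (node and
relation sets are fixed), so this terminates; because every rule is
monotone over a set, the fixpoint is independent of application order —
the test suite checks the engine against an order-free exhaustive oracle
on seeded random graphs. Each inferred statement records the first rule
that produced it (ties broken by the fixed order), the result graph is
named `<input>-tc`, and asserted statements are never modified, so both
the asserted-only and inferred-only views remain recoverable through the
provenance flag. The fold increase, (asserted + inferred) / asserted, is
reported per graph; its magnitude is entirely data-dependent and is not
asserted as an invariant.

## Queries and provenance partition

Templates are finite boolean trees (union / intersection) of labelled
clauses. A term selector matches proteins with a given predicate
statement to a given term; an interaction selector matches proteins
co-participating in a reified interaction with a given partner (or any
interaction of a given MI type when no partner is set). Evaluation is
pure and deterministic (results sorted by protein identifier), validates
that every referenced identifier resolves, reports which clauses matched,
and can filter by taxon via `in_taxon`.

`TermSelector` defaults to descendant-aware matching (the term plus its
`is_a` descendants) for ad-hoc use on un-closed graphs. The built-in
templates deliberately switch this off and match direct statements only:
the closure's priority-over-subsumption rule performs the
generalization, which is what makes the asserted / inferred provenance
partition meaningful — with descendant expansion on, evaluation of the
asserted graph would silently replicate the inference and no hit could
ever be inferred-only.

The partition evaluates the template three times — on the asserted
graph, on the inferred-only view, and on the full closure:
`inferred_only` = closure hits missed on the asserted graph;
`asserted_only` / `both` split the asserted hits by whether the inferred
layer alone would also retrieve them. The three classes are disjoint and
sum to the closure hit count. (The published per-query tallies from the
original 2014-era database releases do not reconcile with a simple union
identity and are not targeted; the partition identity above is the
artifact's contract.)

Template specifics where the source material was ambiguous: Q4 is read
as central-term AND (union of the four degradation clauses), following
the use-case prose ("retrieve proteins that contribute to NFκB
down-regulation **and at the same time** have functions related to
proteasomal degradation"); a `q4_pure_union` flag exposes the plain
union. Q2 is the specific negative-regulation term unioned with the
broad term restricted to CREB1 interactors, mirroring Q1's
false-positive-reduction pattern; `q2_with_interaction=False` gives the
pure two-term union.

The shared-target join returns one row per (novel DbTF, core DbTF,
shared target gene) triple, mode taken from the novel edge, rows from
multiple source databases collapsed with sources concatenated,
deterministically ordered.

## Prioritization

Candidates: membership in the curated network map wins (**a**);
otherwise responsiveness in the model-system time series defines **b1**,
split into **b1i** / **b1j** by literature evidence of responsiveness to
other stimuli; non-responsive candidates are **b_other**. Priorities are
explicit integers (a=0, b1i=1, b1j=2, b_other=3) so downstream sorting
is total and stable. Differential-expression calling is out of scope:
"responsive" and "expressed" are boolean input columns, matched
case-insensitively between gene symbols and evidence tables. A shared
target is a *candidate* iff expressed ∧ responsive, *dual-supported* iff
additionally its novel regulator is expressed.

## The synthetic generator

`generate_kb(SynthConfig)` emulates the structure the pipeline consumes:
a single-rooted `is_a` DAG of background process terms hung under the
three nested sub-domain roots (each new term draws its parent(s)
uniformly from the existing pool; `dag_branching` − 1 is the chance of a
second parent), molecular-function and cellular-component branches with
a little partonomy (so composition fires), an interaction-type branch,
background proteins with 2–4 process annotations plus function /
component annotations, interactions, pathway memberships, orthology
pairs, protein records (~70% with gene references), regulatory edges and
a DbTF catalog, and boolean expression / membership / literature tables.
Defaults (40 background terms, 30 proteins, 25 interactions, 5 plants,
`p_inferred_only` 0.5) keep a full build-close-query cycle well under a
second while leaving every rule and reader with real work.

The query-term anchors are injected with their real identifiers (the GO,
MI and KEGG terms and the CREB1 / TCF7L2 accessions the templates use)
so the built-in templates run unmodified; every other term is synthetic.
Annotation targets must live in the GO namespace (the GAF format and the
annotation-record invariant require it), so synthetic annotatable terms
use `GO:SYN-…` local ids — collision-free with real, purely numeric GO
ids — while structural roots use the `SYN` namespace proper. Planted
regulators receive exactly the statements their template needs; with
probability `p_inferred_only` the term-clause annotations land on strict
descendants of the query terms, making the plant retrievable only after
closure. Background data never touches an anchor, its reserved
descendants, the degradation pathway, or an interaction with the target
proteins, so template evaluation on the closure returns exactly the
ledger — recall and precision 1.0 by construction, which the acceptance
suite verifies across templates and seeds.

What the generator does **not** emulate: realistic ontology depth or
term-frequency distributions, annotation evidence-code structure,
multi-species content, expression dynamics (boolean calls only), or the
scale of real releases. Passing tests therefore demonstrate the
correctness of the machinery — closure semantics, provenance accounting,
query algebra, classification rules — not the biological yield of any
particular database snapshot; the published ontology sizes, query
tallies and ≈7-fold triple growth depend on 2014-era releases and are
out of scope (the measured fold increase on the default synthetic KB is
typically ≈3).

## Numerical / procedural choices

* Determinism: one `random.Random(seed)` drives the generator; files are
  written with sorted iteration orders, so equal seeds give
  byte-identical bundles. Pipeline stages are pure functions of their
  inputs; re-running overwrites outputs byte-identically.
* Serialization: OBO terms and statement lines sorted lexicographically;
  N-Triples lines sorted; only asserted statements are written to OBO
  (the closure is recomputed, not persisted, by the pipeline).
* Degenerate inputs: empty OBO parses to an empty graph; an empty
  expression evaluates to no hits; an empty edge list is an error for
  the shared-target join (it indicates a wiring mistake, not an empty
  result); records failing ID mapping are dropped and counted.
* Stage outputs are staged in memory and written only after the stage
  has fully succeeded, so failures never leave partial outputs.

## Known limitations

* No OWL semantics beyond the five rules: no negation, no retraction /
  truth maintenance, no entailment regimes.
* The OBO reader covers the tag subset the pipeline uses (`id`, `name`,
  `is_a`, `relationship`, `is_transitive`, `is_reflexive`); other tags
  are ignored with a warning. Relation metadata beyond the two OBO flags
  (superrelations, compositions, priority) travels in the YAML sidecar.
* Orthology is consumed, not predicted; differential expression is
  consumed, not called; literature flags are inputs, not mined.
* The association extension is one round by default; whether a deeper
  expansion is appropriate is a modelling decision left to the caller.
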