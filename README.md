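# gexkg

Protein-centric gene-expression knowledge graphs for regulatory-network
extension: build nested application ontologies from annotation, interaction,
pathway, orthology and regulatory sources, compute a rule-based inference
closure, run candidate-regulator query templates, and prioritize candidates
and shared target genes against expression evidence.

## Who this is for

Systems biologists who want to extend a curated signaling / transcription
network — for example the CCK2R gastrin-response network around the
DNA-binding transcription factors (DbTFs) CREB1, NFkB1 and TCF7L2 — with
new candidate regulators supported by ontology annotations, protein
interactions and curated transcription-factor–target-gene resources, and
who then need a principled way to rank those candidates against
expression data from their model system.

## What it does

1. **Build.** A concise upper-level ontology glues together a Biological
   Process sub-domain fragment (extracted as a root term plus all of its
   `is_a` / `part_of` descendants), the molecular-function,
   cellular-component and interaction-type fragments, and the data-facing
   term types. Three nested graphs of increasing specificity are built
   from three nested sub-domain roots (gene expression ⊇ regulation of
   gene expression ⊇ regulation of transcription). *Core* proteins —
   those with a Biological Process annotation to a seed term — are
   extended one round by association (interaction partners, shared KEGG
   pathways, orthologs), and the selected data are written in as typed
   statements: `participates_in`, `has_function`, `located_in`,
   `member_of_pathway`, `encoded_by`, reified interactions with
   `has_participant` / `has_interaction_type`, and
   `activates` / `represses` / `regulates` edges from regulatory
   resources. Entities that fail the canonical ID mapping are dropped,
   never invented.

2. **Close.** Forward chaining of five relation-attribute rules to
   fixpoint produces the total closure (the "-tc" graph): *reflexivity*,
   *transitivity*, *superrelations*, *compositions*, and *priority over
   subsumption* — the last propagating annotation statements across the
   `is_a` hierarchy (true-path-style), in both the object-generalization
   and subject-specialization directions. Every inferred statement is
   tagged with the first rule that produced it.

3. **Query.** Five built-in templates (Q1–Q5) expressed in a small
   selector algebra (unions / intersections of term selectors and
   reified-interaction selectors) retrieve candidate regulators of CREB1,
   NFkB1/RELA and TCF7L2; all identifiers are parameters with the
   published defaults (e.g. Q1 = positive regulation of CREB TF activity
   ∪ CREB-binding function ∪ direct interaction `MI:0407` with CREB1 ∪
   (positive regulation of DNA-binding TF activity ∩ physical association
   `MI:0914` with CREB1)). Hits are partitioned by provenance:
   retrievable from asserted statements, only via inferred statements, or
   both. A shared-target join (Q6-style) finds genes regulated by both a
   novel DbTF and a core-network DbTF.

4. **Prioritize.** Candidates are classified **a** (documented network
   member), **b1i** (responsive in the model system, with literature
   support for other stimuli — the most promising), **b1j** (responsive,
   no such support) or **b_other**. Shared target genes are *candidates*
   when expressed and responsive in the model system, and
   *dual-supported* when their novel regulator is itself expressed.

A synthetic fixture generator (`gexkg.synthkb`) emits the same standard
formats the readers consume (OBO 1.2, GAF 2.x, PSI-MI TAB 2.5, TSV) with
*planted* regulators whose ground truth is recorded in a ledger, including
plants retrievable only through the closure.

## Worked example

Generate a synthetic bundle with five regulators planted to satisfy the
chromatin-modifier template Q3, close the graphs, and query:

```python
from gexkg.cli import run_simulate, run_close, run_query

run_simulate("demo", seed=11, planting_mode="Q3", p_inferred_only=0.5)
closures = run_close("demo/runconfig.yaml", "demo/out")
for name, c in closures.items():
    print(f"{name}-tc: {c.asserted_count} asserted + "
          f"{c.inferred_count} inferred (x{c.fold_increase:.2f})")
result = run_query("demo/runconfig.yaml", "demo/out", "Q3")
print([str(r.protein) for r in result["candidates"]])
print(result["partition"].counts())
```

prints

```
GeXO-tc: 492 asserted + 1202 inferred (x3.44)
ReXO-tc: 487 asserted + 1101 inferred (x3.26)
ReTO-tc: 307 asserted + 561 inferred (x2.83)
['UniProtKB:SYNT0000', 'UniProtKB:SYNT0001', 'UniProtKB:SYNT0002',
 'UniProtKB:SYNT0003', 'UniProtKB:SYNT0004']
{'asserted_only': 2, 'inferred_only': 3, 'both': 0, 'total': 5}
```

The query recovers exactly the five planted regulators; three of them are
invisible on the asserted graph and found only through the closure —
matching the bundle's plant ledger. The three closure lines show the
triple growth of the nested graphs (the fold increase is data-dependent).

The packaged shared-target worked example joins the twenty
novel-DbTF / core-DbTF regulatory rows and assesses them against the
AR42J expression calls:

```python
from gexkg.cli import run_prioritize
run_prioritize(None, "demo/wx", worked_example=True)
```

`demo/wx/summary.json` then reports 20 shared-target rows over 19 unique
genes, the five candidate genes `ALOX5AP, BRCA2, IER3, JUN, NFKB1`
(expressed *and* gastrin-responsive), and the two dual-supported genes
`BRCA2, JUN` (their regulators PARP1 and CREM are themselves expressed).

The same stages are available on the command line:

```bash
gexkg simulate --seed 11 --planting-mode Q3 --out demo
gexkg build  --config demo/runconfig.yaml --out demo/out
gexkg close  --config demo/runconfig.yaml --out demo/out
gexkg query  --config demo/runconfig.yaml --out demo/out --template Q3
gexkg prioritize --worked-example --out demo/wx
```

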