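# Methods

## What the toolkit models

`varkg` turns the output of a clinical variant-interpretation run — an
annotated VCF with per-transcript consequence annotations and a five-level
pathogenicity classification (P, LP, VUS, LB, B), plus a sample sheet mapping
patient ids to Human Phenotype Ontology (HPO) terms — into an RDF knowledge
graph, and answers graph-analytic questions over it. The emitted graph has a
fixed shape: a patient node carries `rdfs:label` and links to HPO phenotype
IRIs (`hasPhenotype`) and to variant nodes (`hasVariant`); variants link to
transcripts (`hasTranscript`), transcripts to genes (`inGene`) and consequence
terms (`hasConsequence`); the classification is a string literal on the
variant node (`hasClassification`). Labels for phenotype and consequence IRIs
are copied in from small ontology fragments. Class declarations
(`owl:Class` plus labels) are emitted for the four node types so the graph is
self-describing.

Two modelling choices were genuinely open and are made explicit:

* **Where the classification lives.** A classification could equally attach
  to a per-patient variant *call*. The default attaches it to the variant
  node (one classification per variant, matching single-pipeline output);
  `SchemaConfig(classification_on="call")` switches to a reified call node
  `patient → call → variant` carrying the classification, for multi-caller
  or per-sample use.
* **Sample-sheet layout.** There is no standard column contract for pipeline
  sample sheets; ours is a TSV/CSV with an `individual_id` column and an
  `hpo_ids` column of semicolon-separated `HP:#######` CURIEs (column names
  configurable). Malformed CURIEs go to a warning list rather than being
  dropped silently, and duplicate ids are hard errors.

All minted IRIs are deterministic: `base + "variant/" + chrom-pos-ref-alt`,
`base + "patient/" + id`, and so on. Coordinates stay 1-based as in VCF and
are typed `xsd:integer`; no interval arithmetic is performed. Converting the
same inputs twice yields byte-identical sorted N-Triples.

## RDF core

Triples are immutable values held in Python sets, partitioned into a default
graph plus named graphs; within a graph, inserting a triple twice is a no-op
and the store's size is the sum of per-graph set sizes. Pattern matching is
a filter over these sets — there is deliberately no query planner; every
scenario operation is defined as joins over `match` results, which keeps the
semantics auditable against brute-force enumeration.

Parsing and serialization go through rdflib. Two serialization rules matter
for reproducibility: N-Triples output is sorted lexicographically by
(subject, predicate, object), so equal graphs give bit-identical files; and
graphs *emitted* by this toolkit never contain blank nodes (deterministic
IRIs instead), though blank nodes are accepted on read. Literals with no
declared datatype are normalized to `xsd:string` (the Turtle default), so
round-trips compare equal.

The namespace table preloads the prefixes used by the drug sources,
including the deliberate quirk that `sio` and `cheminf` share one base IRI
(`http://semanticscience.org/resource/`), as the source vocabularies do.
Compaction tie-breaks on the local name (`SIO_*` → `sio`, `CHEMINF_*` →
`cheminf`). `HP:0000505`-style CURIEs expand to OBO PURLs
(`…/obo/HP_0000505`).

### The role linter

RDF exports from relational systems sometimes reuse one URI as a class, an
individual *and* a predicate — a malformation that confuses downstream
tools without being a syntax error. `lint_roles` operationalizes the check
with a minimal role taxonomy: *predicate* = occurs in predicate position;
*class* = object of `rdf:type`, participant in `rdfs:subClassOf`, or typed
`owl:Class`/`rdfs:Class`; *individual* = subject of `rdf:type` with a
non-meta-class object. Any IRI holding ≥ 2 roles is a conflict. The report
also lists node IRIs without `rdfs:label` (core RDF/RDFS/OWL/XSD IRIs are
exempt). A stricter, off-by-default rule additionally treats subjects of
`rdfs:domain`/`rdfs:range` as declared predicates; it is configurable
because domain/range modelling styles vary legitimately.

## Drug-source linking

Three sources are bridged locally, in memory, rather than through federated
SPARQL endpoints — the join semantics per sub-pattern are identical and the
results are deterministic and testable at desk scale:

1. `generate_atc_sameas` emits one `owl:sameAs` link per subject typed
   `owl:Class` whose IRI starts with the UATC base, rewriting the prefix to
   the bio2rdf ATC base (`…/UATC/B01AC06` ↔ `…/atc:B01AC06`). It is
   injective on ATC codes and idempotent: its own output contains no
   `owl:Class` subjects, so re-application adds nothing.
2. `extract_depositor_links` finds attribute nodes typed as DrugBank
   identifiers (`CHEMINF_000406`) connected to a compound via SIO
   "is attribute of" (`SIO_000011`) and carrying a value via "has value"
   (`SIO_000300`). CAS-number nodes (`CHEMINF_000446`) on the same compound
   attach optionally; a compound with only a CAS node yields nothing, since
   the DrugBank pattern is mandatory. Results are ordered by DrugBank id and
   truncated to a configurable limit (default 10 — the cap needed against
   the full-size source, where unlimited queries time out; pass `None` for
   all). CAS strings are opaque; no checksum validation.
3. `bridge_sources(drugbank, atc, pubchem, "DB00945")` joins the three
   sub-patterns on shared variables and emits the CONSTRUCT template:
   drug → identifier, drug → `x-atc` → ATC IRI, drug label, UATC `sameAs`
   ATC, compound ↔ depositor ↔ id literal, optional CAS. When the ATC graph
   carries no explicit `sameAs` triples the alignment is derived on the fly
   (the INSERT-then-query pipeline collapsed into one call); explicit
   triples take precedence. If any mandatory sub-pattern fails the result is
   empty. In the bridged graph the compound reaches the ATC code node within
   four undirected edges (compound – depositor – id literal – drug entry –
   ATC code).

## Scenario queries

*Clustering* groups patients by a key entity: genes reached via
patient → variant → transcript → gene, or phenotype terms reached directly.
The support threshold defaults to 2 (a "cluster" of one is not a cluster);
it is exposed because use cases disagree on whether "more than two" or
"at least two" is intended. Gene clustering optionally filters by
classification (`{"P","LP"}` reproduces a diagnostic short-list view).
Raising the threshold never adds clusters nor enlarges one (monotonicity,
property-tested).

*Closed loops* retain a gene–disease association only when it closes the
cycle patient → phenotype → disease → association → gene → variant →
patient. The implementation builds per-predicate indexes and joins them;
its contract is equality with brute-force enumeration of all candidate
6-tuples, which the test suite enforces on every instance (≈700 loops per
acceptance run). A patient qualifying through two phenotypes for the same
association yields two loops — no deduplication, because the enumeration
semantics are unambiguous. Evidence nodes attach when present. The six edge
predicates live in a `GdaVocab` configuration: association sources do not
share a standard vocabulary, so the defaults match the synthetic fixture and
real extracts are mapped by configuration.

*Catalogue patterns* cover metadata graphs of cohort studies: depth-1 class
hierarchy roots (`rdfs:subClassOf owl:Thing`, labels optional), resources
linked to a topic via a keyword predicate, and the harmonization path
variable-mapping → target-variable → keyword joined with mapping →
source-variable → dataset → cohort. Predicates are configurable
(`CatalogueVocab`) for the same reason as above.

## Synthetic data and what passing tests show

The generators are first-class, seeded (Python `random.Random`; same seed →
byte-identical files), and every planted structure is written to a JSON
`TruthLedger` *by the generator's own bookkeeping* — downstream oracles read
the ledger, never the generated files.

* **Cohorts** (default 20 patients, 5 planted gene clusters of 2–5 patients,
  ~2 background variants per patient): each cluster is realized as shared
  heterozygous carrier status of one causal variant classified P or LP.
  Every patient carries HP:0000505 ("Visual impairment"), emulating a cohort
  selected on that phenotype, plus a per-cluster marker phenotype and random
  extras from a ~30-term synthetic HPO subset. Background variants emulate
  population-common variation: they live in a disjoint decoy-gene pool and
  are classified B/LB only, so they can never mimic a causal cluster once
  classifications are filtered — deliberately, since their role is to test
  that filtering, not allele-frequency realism. Sites are biallelic; the
  multi-allelic split rule is covered by hand-written VCF fixtures instead.
* **GDA graphs** (default 40 candidates): exactly
  `round(n_candidates × loop_fraction)` associations are closable; the rest
  are broken by an unobserved phenotype, an uncarried gene, or a missing
  gene edge, using fresh IRIs so no decoy can close accidentally.
* **Drug fixtures**: bridgeable synthetic drugs plus the aspirin worked
  example (DB00945 / B01AC06 / CAS 50-78-2) and decoys for each failure mode
  of the join. The packaged Turtle files under `src/varkg/data/` are this
  generator's seed-0 output.
* **Catalogue graphs**: planted topic and keyword maps, optional injected
  URI-role conflicts for linter sensitivity tests. `demo_catalogue()` is a
  deterministic synthetic snapshot of a small cohort catalogue used for the
  worked examples (topic "Tobacco" → two cohorts; harmonized keyword
  "blood pressure" → three cohorts).

What the synthetic data does **not** emulate: realistic allele frequencies
or linkage, HPO semantics beyond labels and a flat subclass layer, real
DisGeNET/Drugbank/PubChem vocabularies (predicates are configurable
precisely because of this), or the scale of the real sources. Passing tests
therefore demonstrate correctness of the graph constructions and query
semantics, not robustness to the noise and schema drift of production
exports.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 5–50 patients,
GDA graphs of ≤ 40 candidates (≈ 5 000 triples total per pair), and
10-seed linter sweeps; at these sizes every query result is verified against
exhaustive enumeration, and the full suite completes in seconds. There is no
floating-point numerics anywhere — all comparisons are exact set equalities —
so no tolerances apply. Ties are broken lexicographically on IRIs
throughout, and all output orderings are sorted.

## Known limitations

* No SPARQL engine: queries are fixed-shape operations, not a general query
  language. Arbitrary patterns require writing a new operation.
* No endpoint client: all sources must be local files or in-memory graphs.
* RDF/XML is read but not written; blank-node-heavy inputs round-trip only
  up to label renaming.
* The linter's role taxonomy is intentionally minimal; OWL punning, which
  *legitimately* reuses an IRI as class and individual, is flagged as a
  conflict and must be whitelisted by the caller.
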