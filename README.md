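# varkg

Semantic knowledge graphs from variant-interpretation pipeline output, with
drug-source linking and graph-analytic scenario queries.

Genome diagnostics ends with a short-list of annotated DNA variants: each
one carries per-transcript consequence annotations and a five-level
pathogenicity classification — Pathogenic (P), Likely Pathogenic (LP),
Variant of Unknown Significance (VUS), Likely Benign (LB), Benign (B).
Interpreting a *cohort* of such patients means connecting layers: which
patients share affected genes, which share phenotypes, and which of their
genes are independently associated with diseases matching those phenotypes.
`varkg` makes those connections explicit by converting pipeline output into
an RDF knowledge graph and running the relevant graph patterns over it. It
is written for bioinformaticians who have annotated VCFs and patient
phenotype sheets and want reproducible, queryable RDF rather than a triple
store deployment.

The toolkit provides:

* **rdf_core** — a minimal triple store: named graphs with set semantics,
  CURIE expansion/compaction, Turtle/N-Triples/RDF-XML I/O (N-Triples
  output is sorted for byte-stable files), and a linter that flags URIs
  used simultaneously as class, individual and predicate — a real-world
  export malformation.
* **variant_kg** — annotated VCF + sample sheet → RDF: patient →
  phenotype (HPO IRIs), patient → variant → transcript → gene, with the
  classification on the variant node and labels copied from ontology
  fragments. Deterministic IRI minting: same input, byte-identical output.
* **scenario_queries** — patient clusters per gene or phenotype (minimum
  support ≥ 2 by default), **closed gene–disease loops** (a gene–disease
  association is kept only if it closes the cycle patient → phenotype →
  disease → association → gene → variant → patient), catalogue pattern
  queries (class-hierarchy roots, resources by topic, cohorts by harmonized
  keyword).
* **drug_link** — bridges a UATC-style ATC ontology, a Drugbank-style graph
  and a PubChem-style graph: `owl:sameAs` generation between ATC IRI
  schemes, depositor-identifier extraction (SIO/CHEMINF pattern), and the
  three-way join around one DrugBank id.
* **synthetic_data** — seeded generators for all of the above with
  machine-readable truth ledgers, so every query operation is testable
  against planted ground truth.
* **cli** — `varkg convert | link | query | simulate | lint`.

## Worked example

Generate a 10-patient cohort with three planted gene clusters, convert it
to RDF, and ask which genes are shared by ≥ 2 patients with P/LP variants:

```
$ varkg simulate cohort --seed 7 --patients 10 --genes 3 --out sim
$ varkg convert --vcf sim/cohort.vcf --samples sim/samples.tsv --out kg
$ varkg query genes --graph kg/variants.ttl --min 2 --classifications P,LP
key                                label  n  members
https://w3id.org/varkg/gene/GENE1  GENE1  4  .../patient/P001;.../patient/P003;.../patient/P007;.../patient/P008
https://w3id.org/varkg/gene/GENE2  GENE2  2  .../patient/P001;.../patient/P006
https://w3id.org/varkg/gene/GENE3  GENE3  3  .../patient/P001;.../patient/P002;.../patient/P007
```

Each row is one gene-sharing cluster: `n` patients carry a P/LP-classified
variant in that gene (members abbreviated here; the command prints full
IRIs). The clusters match `sim/cohort.truth.json`, the generator's ledger.
Background benign variants in the cohort never surface at the P/LP level.
Phenotype clustering works the same way (`varkg query phenotypes --min 5`
shows, e.g., all ten patients sharing "Visual impairment" — every patient
carries HP:0000505, emulating a cohort selected on it).

Bridge the three packaged drug sources around aspirin:

```
$ varkg simulate drugs --seed 0 --out drugs
$ varkg link bridge --drugbank drugs/drugbank.ttl --atc drugs/atc.ttl \
      --pubchem drugs/pubchem.ttl --drug DB00945 --out bridge.ttl
# bridge triples: 8
```

The resulting graph connects the Drugbank entry to its ATC code in both
ontologies and to the chemical compound record with its CAS number:

```
drugbank:DB00945 rdfs:label "Aspirin" ;
    bio2rdf:identifier "DB00945" ;
    drugbank_vocabulary:x-atc atc:B01AC06 .

uatc:B01AC06 owl:sameAs atc:B01AC06 .

compound:CID2244_cas_attr sio:SIO_000011 compound:CID2244 ;
    sio:SIO_000300 "50-78-2" .

compound:CID2244 sio:SIO_000011 compound:CID2244_drugbank_attr .

compound:CID2244_drugbank_attr sio:SIO_000300 "DB00945" .
```

The key statement is `drugbank:DB00945 drugbank_vocabulary:x-atc
atc:B01AC06` — aspirin's DrugBank entry has ATC code B01AC06 — plus the
`owl:sameAs` link aligning the two ATC IRI schemes and the depositor
pattern tying the compound record to the same DrugBank id.

From Python the same operations are plain functions:

```python
from varkg import parse_vcf, parse_sample_sheet, build_variant_graph
from varkg import cluster_patients_by_gene, find_closed_loops

kg = build_variant_graph(parse_sample_sheet("samples.tsv").records,
                         parse_vcf("cohort.vcf").observations)
clusters = cluster_patients_by_gene(kg, min_patients=2, classifications={"P", "LP"})
```

See `docs/methods.md` for the graph schema, the loop semantics, the linter's
role taxonomy, and what the synthetic generators do and do not emulate.

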