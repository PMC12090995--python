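"""Seeded generators for every input the toolkit consumes, with truth ledgers.

Each generator emulates one of the real data sources at desk scale:

* :func:`make_cohort` — a multi-patient annotated VCF plus sample sheet with
  *planted* gene clusters (patients sharing a causal P/LP variant in one
  gene), overlapping HPO phenotype assignments, and benign background
  variants emulating population-common noise a pipeline would filter;
* :func:`make_gda_graph` — a gene–disease-association graph shaped like a
  DisGeNET extract, with a controlled fraction of associations closable into
  patient loops against a companion cohort;
* :func:`make_drug_fixture` — three small drug/chemical graphs (UATC-style
  ATC ontology, Drugbank-style, PubChem-style) including the aspirin worked
  example (DB00945 / B01AC06) and decoys that must not join;
* :func:`make_catalogue_graph` — a catalogue-shaped metadata graph with a
  depth-1 class hierarchy, topic links and harmonized variable mappings, and
  optional injected URI-role conflicts for linter tests.

Every generator is a pure function of its seed (same seed → byte-identical
outputs) and emits a machine-readable :class:`TruthLedger` describing every
planted structure, so downstream tests never have to re-derive the truth
from the generated files themselves.

The HPO subset and consequence glossary here are synthetic fixtures: the
identifiers follow the real ontologies' conventions but only ~30 terms ship.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from random import Random

from .rdf_core import (
    OWL_CLASS,
    OWL_THING,
    RDF_TYPE,
    RDFS_LABEL,
    RDFS_SUBCLASSOF,
    KnowledgeGraph,
    Triple,
    iri,
    literal,
)
from .scenario_queries import (
    DEFAULT_CATALOGUE_VOCAB,
    DEFAULT_GDA_VOCAB,
    CatalogueVocab,
    GdaVocab,
)
from .variant_kg import DEFAULT_SCHEMA, OntologyFragment, SchemaConfig

__all__ = [
    "CohortSpec",
    "TruthLedger",
    "CohortResult",
    "DrugFixture",
    "make_cohort",
    "make_gda_graph",
    "make_drug_fixture",
    "make_catalogue_graph",
    "demo_catalogue",
    "hpo_fragment",
    "glossary_fragment",
    "HPO_TERMS",
]

OBO_HP = "http://purl.obolibrary.org/obo/HP_"

# Synthetic HPO subset (~30 terms). The two visual-impairment terms mirror
# the cohort-filter phenotypes; the HP:09xxxxx block is filler.
HPO_TERMS: dict[str, str] = {
    "HP:0000505": "Visual impairment",
    "HP:0100704": "Cerebral visual impairment",
    "HP:0000618": "Blindness",
    "HP:0000486": "Strabismus",
    "HP:0000365": "Hearing impairment",
    "HP:0001250": "Seizure",
    "HP:0001263": "Global developmental delay",
    "HP:0001249": "Intellectual disability",
    "HP:0001252": "Hypotonia",
    "HP:0000252": "Microcephaly",
    "HP:0000256": "Macrocephaly",
    "HP:0001631": "Atrial septal defect",
    "HP:0002650": "Scoliosis",
    "HP:0001382": "Joint hypermobility",
    "HP:0004322": "Short stature",
    "HP:0001508": "Failure to thrive",
    "HP:0002119": "Ventriculomegaly",
    "HP:0001344": "Absent speech",
    "HP:0002360": "Sleep abnormality",
    "HP:0000750": "Delayed speech and language development",
    **{f"HP:09000{i:02d}": f"Synthetic phenotype {i}" for i in range(1, 11)},
}

_CONSEQUENCES = [
    ("missense_variant", "missense variant"),
    ("stop_gained", "stop gained"),
    ("frameshift_variant", "frameshift variant"),
    ("splice_donor_variant", "splice donor variant"),
    ("synonymous_variant", "synonymous variant"),
    ("intron_variant", "intron variant"),
]


def hpo_fragment() -> OntologyFragment:
    """The synthetic HPO subset as an ontology fragment (labels + hierarchy)."""
    root = OBO_HP + "0000001"
    abnormality = OBO_HP + "0000118"
    terms = {OBO_HP + c.split(":")[1]: label for c, label in HPO_TERMS.items()}
    terms[root] = "All"
    terms[abnormality] = "Phenotypic abnormality"
    edges = {(abnormality, root)}
    edges |= {(t, abnormality) for t in terms if t not in (root, abnormality)}
    return OntologyFragment(terms=terms, subclass_edges=frozenset(edges))


def glossary_fragment(schema: SchemaConfig = DEFAULT_SCHEMA) -> OntologyFragment:
    """Consequence-term glossary fragment keyed by the schema's minted IRIs."""
    return OntologyFragment(
        terms={schema.consequence_iri(term).value: label for term, label in _CONSEQUENCES}
    )


# Truth ledger ---------------------------------------------------------------


@dataclass
class TruthLedger:
    """Machine-readable ground truth emitted alongside every generated dataset."""

    seed: int | None = None
    params: dict = field(default_factory=dict)
    clusters_by_gene: dict[str, list[str]] = field(default_factory=dict)
    phenotypes: dict[str, list[str]] = field(default_factory=dict)
    observations: list[dict] = field(default_factory=list)
    expected_loops: list[list[str]] = field(default_factory=list)
    closable_gdas: list[str] = field(default_factory=list)
    sameas_pairs: list[list[str]] = field(default_factory=list)
    depositor_links: list[dict] = field(default_factory=list)
    bridgeable_drugs: list[str] = field(default_factory=list)
    topic_map: dict[str, list[str]] = field(default_factory=dict)
    keyword_map: dict[str, list[str]] = field(default_factory=dict)
    injected_conflicts: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


# Cohort generator -----------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic rare-disease cohort.

    ``gene_clusters`` plants the ground-truth structure: each entry maps a
    gene symbol to the patients sharing a causal variant in it.  When left
    ``None``, ``n_genes`` clusters of 2–5 patients are drawn at random.
    ``background_rate`` is the mean number of benign (B/LB) background
    variants per patient, emulating population-common variation; background
    variants never receive P/LP labels.
    """

    n_patients: int = 20
    n_genes: int = 5
    gene_clusters: Mapping[str, Sequence[str]] | None = None
    phenotypes_per_patient: int = 3
    background_rate: float = 2.0
    causal_classifications: tuple[str, ...] = ("P", "LP")
    seed: int = 0

    def patient_ids(self) -> list[str]:
        return [f"P{i:03d}" for i in range(1, self.n_patients + 1)]

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_genes < 0:
            raise ValueError("n_patients and n_genes must be non-negative")
        if self.gene_clusters is not None:
            ids = set(self.patient_ids())
            for gene, members in self.gene_clusters.items():
                extra = set(members) - ids
                if extra:
                    raise ValueError(
                        f"cluster for {gene} references patients outside the cohort: {sorted(extra)}"
                    )
                if len(set(members)) > self.n_patients:
                    raise ValueError(f"cluster for {gene} larger than the cohort")


@dataclass(frozen=True)
class CohortResult:
    vcf_path: Path
    sheet_path: Path
    ledger: TruthLedger
    ledger_path: Path


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=248956422>
##contig=<ID=2,length=242193529>
##contig=<ID=3,length=198295559>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|SYMBOL|Feature|Consequence|VIPC">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_BASES = ("A", "C", "G", "T")


def _draw_clusters(rng: Random, spec: CohortSpec) -> dict[str, list[str]]:
    if spec.gene_clusters is not None:
        return {g: sorted(set(m)) for g, m in spec.gene_clusters.items()}
    patients = spec.patient_ids()
    clusters: dict[str, list[str]] = {}
    for gi in range(1, spec.n_genes + 1):
        if not patients:
            break
        size = min(len(patients), rng.randint(2, 5))
        clusters[f"GENE{gi}"] = sorted(rng.sample(patients, size))
    return clusters


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortResult:
    """Write a synthetic annotated VCF, sample sheet and truth ledger.

    Every planted cluster is realized as shared 0/1 carrier status for one
    causal P/LP variant in the cluster's gene; background variants sit in a
    disjoint decoy-gene pool and are classified B or LB only, so they can
    never mimic a causal cluster once classifications are filtered.
    """
    spec.validate()
    rng = Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    patients = spec.patient_ids()
    clusters = _draw_clusters(rng, spec)

    hpo_curies = sorted(HPO_TERMS)
    phenotypes: dict[str, set[str]] = {p: set() for p in patients}
    # cohort filter phenotype shared by everyone, mirroring a visual-impairment
    # selected cohort; each cluster additionally shares one marker phenotype
    for p in patients:
        phenotypes[p].add("HP:0000505")
    marker_pool = [c for c in hpo_curies if c != "HP:0000505"]
    for gene in sorted(clusters):
        marker = marker_pool[rng.randrange(len(marker_pool))]
        for p in clusters[gene]:
            phenotypes[p].add(marker)
    for p in patients:
        while len(phenotypes[p]) < min(spec.phenotypes_per_patient, len(hpo_curies)):
            phenotypes[p].add(marker_pool[rng.randrange(len(marker_pool))])

    # -- variant sites
    sites: list[dict] = []  # chrom,pos,ref,alt,gene,transcript,consequence,classification,carriers
    pos_counter = 10_000
    for gi, gene in enumerate(sorted(clusters), start=1):
        pos_counter += rng.randint(50, 500)
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        sites.append(
            dict(
                chrom="1",
                pos=pos_counter,
                ref=ref,
                alt=alt,
                gene=gene,
                transcript=f"ENST{gi:08d}",
                consequence=rng.choice(_CONSEQUENCES[:4])[0],
                classification=rng.choice(spec.causal_classifications),
                carriers=clusters[gene],
            )
        )
    bg_counter = 0
    for p in patients:
        n_bg = min(int(rng.expovariate(1.0 / spec.background_rate)) if spec.background_rate > 0 else 0, 8)
        for _ in range(n_bg):
            bg_counter += 1
            pos_counter += rng.randint(50, 500)
            ref = rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            sites.append(
                dict(
                    chrom="2",
                    pos=pos_counter,
                    ref=ref,
                    alt=alt,
                    gene=f"BGGENE{rng.randint(1, max(3, spec.n_patients // 2))}",
                    transcript=f"ENST9{bg_counter:07d}",
                    consequence=rng.choice(_CONSEQUENCES[4:])[0],
                    classification=rng.choice(("B", "LB")),
                    carriers=[p],
                )
            )
    sites.sort(key=lambda s: (s["chrom"], s["pos"]))

    # -- VCF
    lines = [_VCF_HEADER.rstrip("\n")]
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *patients]
    lines.append("\t".join(header_cols))
    for s in sites:
        csq = "|".join([s["alt"], s["gene"], s["transcript"], s["consequence"], s["classification"]])
        gts = ["0/1" if p in s["carriers"] else "0/0" for p in patients]
        lines.append(
            "\t".join(
                [s["chrom"], str(s["pos"]), ".", s["ref"], s["alt"], ".", "PASS", f"CSQ={csq}", "GT", *gts]
            )
        )
    vcf_path = out_dir / "cohort.vcf"
    vcf_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # -- sample sheet
    sheet_lines = ["individual_id\thpo_ids\taffected"]
    for p in patients:
        sheet_lines.append(f"{p}\t{';'.join(sorted(phenotypes[p]))}\ttrue")
    sheet_path = out_dir / "samples.tsv"
    sheet_path.write_text("\n".join(sheet_lines) + "\n", encoding="utf-8")

    ledger = TruthLedger(
        seed=spec.seed,
        params={
            "n_patients": spec.n_patients,
            "n_genes": len(clusters),
            "background_rate": spec.background_rate,
        },
        clusters_by_gene={g: list(m) for g, m in sorted(clusters.items())},
        phenotypes={p: sorted(phenotypes[p]) for p in patients},
        observations=[
            dict(
                key=f"{s['chrom']}-{s['pos']}-{s['ref']}-{s['alt']}",
                gene=s["gene"],
                classification=s["classification"],
                carriers=list(s["carriers"]),
            )
            for s in sites
        ],
    )
    ledger_path = ledger.to_json(out_dir / "cohort.truth.json")
    return CohortResult(vcf_path=vcf_path, sheet_path=sheet_path, ledger=ledger, ledger_path=ledger_path)


# GDA generator --------------------------------------------------------------

_GDA_BASE = "https://w3id.org/varkg/gda/"


def make_gda_graph(
    cohort: TruthLedger,
    n_candidates: int = 40,
    loop_fraction: float = 0.3,
    evidence_fraction: float = 0.5,
    seed: int = 0,
    vocab: GdaVocab = DEFAULT_GDA_VOCAB,
    schema: SchemaConfig = DEFAULT_SCHEMA,
) -> tuple[KnowledgeGraph, TruthLedger]:
    """A gene–disease-association graph with a controlled closable fraction.

    Exactly ``round(n_candidates * loop_fraction)`` association nodes can be
    closed into patient loops against the companion cohort; the remainder are
    broken in one of three ways (unobserved phenotype, uncarried gene, or a
    missing association→gene edge).  The ledger's ``expected_loops`` lists
    every closable 6-tuple of IRIs, enumerated from the cohort's own truth
    ledger, never from the generated graph.
    """
    if not 0.0 <= loop_fraction <= 1.0:
        raise ValueError("loop_fraction must lie in [0, 1]")
    rng = Random(seed)
    kg = KnowledgeGraph()
    ledger = TruthLedger(
        seed=seed,
        params={"n_candidates": n_candidates, "loop_fraction": loop_fraction},
    )

    # cohort-side truth: which patients carry variants in which gene, and
    # which phenotypes each patient has
    carriers_by_gene: dict[str, dict[str, list[str]]] = {}
    for obs in cohort.observations:
        for p in obs["carriers"]:
            carriers_by_gene.setdefault(obs["gene"], {}).setdefault(p, []).append(obs["key"])
    planted_genes = sorted(cohort.clusters_by_gene)
    n_closable = round(n_candidates * loop_fraction)
    if n_closable > 0 and not planted_genes:
        raise ValueError("cohort has no planted gene clusters to close loops against")

    hp_iri = lambda curie: iri(OBO_HP + curie.split(":")[1])

    expected: list[list[str]] = []
    for i in range(n_candidates):
        gda = iri(_GDA_BASE + f"gda/{i}")
        disease = iri(_GDA_BASE + f"disease/{i}")
        kg.add(Triple(disease, RDFS_LABEL, literal(f"Disease {i}")))
        closable = i < n_closable
        if closable:
            gene = planted_genes[rng.randrange(len(planted_genes))]
            members = sorted(cohort.clusters_by_gene[gene])
            anchor = members[rng.randrange(len(members))]
            anchor_phenos = [c for c in cohort.phenotypes[anchor]]
            phenotype = anchor_phenos[rng.randrange(len(anchor_phenos))]
            kg.add(Triple(disease, iri(vocab.disease_phenotype), hp_iri(phenotype)))
            kg.add(Triple(gda, iri(vocab.gda_disease), disease))
            kg.add(Triple(gda, iri(vocab.gda_gene), iri(schema.gene_iri(gene).value)))
            ledger.closable_gdas.append(gda.value)
        else:
            mode = rng.choice(("phenotype", "gene", "no_gene_edge"))
            if mode == "phenotype":
                # phenotype no patient has
                kg.add(Triple(disease, iri(vocab.disease_phenotype), iri(OBO_HP + f"99000{i:02d}")))
                gene = planted_genes[rng.randrange(len(planted_genes))] if planted_genes else f"DECOY{i}"
                kg.add(Triple(gda, iri(vocab.gda_disease), disease))
                kg.add(Triple(gda, iri(vocab.gda_gene), iri(schema.gene_iri(gene).value)))
            elif mode == "gene":
                phenotype = sorted(HPO_TERMS)[rng.randrange(len(HPO_TERMS))]
                kg.add(Triple(disease, iri(vocab.disease_phenotype), hp_iri(phenotype)))
                kg.add(Triple(gda, iri(vocab.gda_disease), disease))
                kg.add(Triple(gda, iri(vocab.gda_gene), iri(schema.gene_iri(f"DECOYGENE{i}").value)))
            else:
                phenotype = sorted(HPO_TERMS)[rng.randrange(len(HPO_TERMS))]
                kg.add(Triple(disease, iri(vocab.disease_phenotype), hp_iri(phenotype)))
                kg.add(Triple(gda, iri(vocab.gda_disease), disease))
        if rng.random() < evidence_fraction:
            ev = iri(_GDA_BASE + f"evidence/{i}")
            kg.add(Triple(gda, iri(vocab.evidence), ev))
            kg.add(Triple(ev, RDFS_LABEL, literal(f"Evidence source {i}")))
        if closable:
            # enumerate every loop this association closes, from the cohort ledger
            for patient, phenos in sorted(cohort.phenotypes.items()):
                if phenotype not in phenos:
                    continue
                for variant_key in carriers_by_gene.get(gene, {}).get(patient, ()):
                    expected.append(
                        [
                            schema.patient_iri(patient).value,
                            hp_iri(phenotype).value,
                            disease.value,
                            gda.value,
                            schema.gene_iri(gene).value,
                            schema.base + "variant/" + variant_key,
                        ]
                    )
    ledger.expected_loops = sorted(expected)
    return kg, ledger


# Drug fixture ---------------------------------------------------------------

UATC_BASE = "http://purl.bioontology.org/ontology/UATC/"
ATC_BASE = "http://bio2rdf.org/atc:"
DRUGBANK_BASE = "http://bio2rdf.org/drugbank:"
DRUGBANK_VOCAB = "http://bio2rdf.org/drugbank_vocabulary:"
BIO2RDF_VOCAB = "http://bio2rdf.org/bio2rdf_vocabulary:"
SIO = "http://semanticscience.org/resource/"
COMPOUND_BASE = "http://rdf.ncbi.nlm.nih.gov/pubchem/compound/"


@dataclass(frozen=True)
class DrugFixture:
    drugbank: KnowledgeGraph
    atc: KnowledgeGraph
    pubchem: KnowledgeGraph
    ledger: TruthLedger


def make_drug_fixture(
    seed: int = 0,
    include_aspirin: bool = True,
    n_drugs: int = 4,
    n_decoys: int = 3,
) -> DrugFixture:
    """Three-source drug graphs around the aspirin worked example.

    ``n_drugs`` fully-bridgeable synthetic drugs are generated (plus aspirin
    DB00945 / ATC B01AC06 / CAS 50-78-2 when requested).  Decoys exercise the
    join's failure modes: a UATC class with no drug, a non-UATC class that
    must not yield a sameAs link, a drug whose ATC code has no UATC
    counterpart, and a compound carrying only a CAS-typed attribute node.
    """
    rng = Random(seed)
    drugbank, atc, pubchem = KnowledgeGraph(), KnowledgeGraph(), KnowledgeGraph()
    ledger = TruthLedger(seed=seed, params={"n_drugs": n_drugs, "n_decoys": n_decoys})

    def add_drug(db_id: str, code: str, name: str, cas: str | None, cid: int, bridge: bool = True) -> None:
        drug = iri(DRUGBANK_BASE + db_id)
        drugbank.add(Triple(drug, iri(BIO2RDF_VOCAB + "identifier"), literal(db_id)))
        drugbank.add(Triple(drug, iri(DRUGBANK_VOCAB + "x-atc"), iri(ATC_BASE + code)))
        drugbank.add(Triple(drug, RDFS_LABEL, literal(name)))
        if bridge:
            uatc = iri(UATC_BASE + code)
            atc.add(Triple(uatc, RDF_TYPE, OWL_CLASS))
            atc.add(Triple(uatc, RDFS_LABEL, literal(name)))
            ledger.sameas_pairs.append([uatc.value, ATC_BASE + code])
        compound = iri(COMPOUND_BASE + f"CID{cid}")
        attr = iri(COMPOUND_BASE + f"CID{cid}_drugbank_attr")
        pubchem.add(Triple(attr, iri(SIO + "SIO_000011"), compound))
        pubchem.add(Triple(attr, iri(SIO + "SIO_000300"), literal(db_id)))
        pubchem.add(Triple(attr, RDF_TYPE, iri(SIO + "CHEMINF_000406")))
        ledger.depositor_links.append(
            dict(value=db_id, compound=compound.value, attribute=attr.value, cas=cas)
        )
        if cas:
            cattr = iri(COMPOUND_BASE + f"CID{cid}_cas_attr")
            pubchem.add(Triple(cattr, iri(SIO + "SIO_000011"), compound))
            pubchem.add(Triple(cattr, iri(SIO + "SIO_000300"), literal(cas)))
            pubchem.add(Triple(cattr, RDF_TYPE, iri(SIO + "CHEMINF_000446")))
        if bridge:
            ledger.bridgeable_drugs.append(db_id)

    if include_aspirin:
        add_drug("DB00945", "B01AC06", "Aspirin", "50-78-2", 2244)
    for i in range(1, n_drugs + 1):
        code = f"A{rng.randint(1, 9):02d}B{chr(65 + rng.randrange(6))}{i:02d}"
        cas = f"{rng.randint(100, 99999)}-{rng.randint(10, 99)}-{rng.randint(0, 9)}" if rng.random() < 0.7 else None
        add_drug(f"DB1{i:04d}", code, f"Synthdrug {i}", cas, 10_000 + i)

    # decoys -----------------------------------------------------------------
    for i in range(1, n_decoys + 1):
        # UATC class with no drug behind it: still yields a sameAs link
        code = f"Z99Z{chr(64 + i)}{i:02d}"
        uatc = iri(UATC_BASE + code)
        atc.add(Triple(uatc, RDF_TYPE, OWL_CLASS))
        atc.add(Triple(uatc, RDFS_LABEL, literal(f"Unused ATC class {i}")))
        ledger.sameas_pairs.append([uatc.value, ATC_BASE + code])
        # non-UATC owl:Class: must not produce a link
        atc.add(Triple(iri(f"http://example.org/notatc/{i}"), RDF_TYPE, OWL_CLASS))
        # drug whose ATC code lacks a UATC counterpart: not bridgeable
        add_drug(f"DB2{i:04d}", f"X00XX{i:02d}", f"Orphan drug {i}", None, 20_000 + i, bridge=False)
        # remove its pubchem depositor half? keep it: join fails on sameAs
        # compound with CAS-only attribute node: mandatory pattern fails
        compound = iri(COMPOUND_BASE + f"CID3{i:04d}")
        cattr = iri(COMPOUND_BASE + f"CID3{i:04d}_cas_attr")
        pubchem.add(Triple(cattr, iri(SIO + "SIO_000011"), compound))
        pubchem.add(Triple(cattr, iri(SIO + "SIO_000300"), literal(f"111-2{i}-3")))
        pubchem.add(Triple(cattr, RDF_TYPE, iri(SIO + "CHEMINF_000446")))

    ledger.sameas_pairs.sort()
    ledger.bridgeable_drugs.sort()
    return DrugFixture(drugbank=drugbank, atc=atc, pubchem=pubchem, ledger=ledger)


# Catalogue generator --------------------------------------------------------

_CAT_BASE = "https://w3id.org/varkg/catalogue/"


def make_catalogue_graph(
    n_cohorts: int = 6,
    topics: Sequence[str] = ("Tobacco", "Diet", "Air pollution"),
    keyword_maps: Mapping[str, int] | None = None,
    seed: int = 0,
    inject_conflicts: int = 0,
    vocab: CatalogueVocab = DEFAULT_CATALOGUE_VOCAB,
) -> tuple[KnowledgeGraph, TruthLedger]:
    """A catalogue-shaped metadata graph with planted topic and keyword maps.

    ``keyword_maps`` maps a harmonized-variable keyword to the number of
    cohorts reachable through its variable mappings.  ``inject_conflicts``
    plants that many URI-role conflicts (an IRI used both as a predicate and
    as a class) for linter sensitivity tests; with zero injections the graph
    lints clean.
    """
    if keyword_maps is None:
        keyword_maps = {"blood pressure": min(3, n_cohorts)}
    rng = Random(seed)
    kg = KnowledgeGraph()
    ledger = TruthLedger(seed=seed, params={"n_cohorts": n_cohorts, "inject_conflicts": inject_conflicts})

    areas = iri(_CAT_BASE + "class/AreasOfInformation")
    cohorts_cls = iri(_CAT_BASE + "class/Cohorts")
    mappings_cls = iri(_CAT_BASE + "class/VariableMappings")
    for cls, label in ((areas, "Areas of information"), (cohorts_cls, "Cohorts"), (mappings_cls, "Variable mappings")):
        kg.add(Triple(cls, RDFS_SUBCLASSOF, OWL_THING))
        kg.add(Triple(cls, RDFS_LABEL, literal(label)))

    cohort_iris = []
    for i in range(1, n_cohorts + 1):
        c = iri(_CAT_BASE + f"cohort/C{i:02d}")
        kg.add(Triple(c, RDF_TYPE, cohorts_cls))
        kg.add(Triple(c, RDFS_LABEL, literal(f"Cohort C{i:02d}")))
        cohort_iris.append(c)

    for topic in topics:
        t = iri(_CAT_BASE + "topic/" + topic.replace(" ", "_"))
        kg.add(Triple(t, RDF_TYPE, areas))
        kg.add(Triple(t, RDFS_LABEL, literal(topic)))
        chosen = sorted(rng.sample(cohort_iris, rng.randint(1, max(1, len(cohort_iris) // 2))), key=lambda x: x.value) if cohort_iris else []
        for c in chosen:
            kg.add(Triple(c, iri(vocab.keyword_link), t))
        ledger.topic_map[topic] = [c.value for c in chosen]

    for keyword, count in keyword_maps.items():
        slug = keyword.replace(" ", "_")
        target = iri(_CAT_BASE + f"variable/target/{slug}")
        kg.add(Triple(target, RDFS_LABEL, literal(f"Target variable: {keyword}")))
        kg.add(Triple(target, iri(vocab.variable_keyword), literal(keyword)))
        chosen = sorted(rng.sample(cohort_iris, min(count, len(cohort_iris))), key=lambda x: x.value)
        for j, c in enumerate(chosen):
            mapping = iri(_CAT_BASE + f"mapping/{slug}/{j}")
            source = iri(_CAT_BASE + f"variable/source/{slug}/{j}")
            dataset = iri(_CAT_BASE + f"dataset/{slug}/{j}")
            kg.add(Triple(mapping, RDF_TYPE, mappings_cls))
            kg.add(Triple(mapping, RDFS_LABEL, literal(f"Mapping {slug} {j}")))
            kg.add(Triple(mapping, iri(vocab.mapping_target), target))
            kg.add(Triple(mapping, iri(vocab.mapping_source), source))
            kg.add(Triple(source, RDFS_LABEL, literal(f"Source variable {slug} {j}")))
            kg.add(Triple(source, iri(vocab.in_dataset), dataset))
            kg.add(Triple(dataset, RDFS_LABEL, literal(f"Dataset {slug} {j}")))
            kg.add(Triple(dataset, iri(vocab.of_cohort), c))
        ledger.keyword_map[keyword] = [c.value for c in chosen]

    for k in range(inject_conflicts):
        bad = iri(_CAT_BASE + f"conflict/U{k}")
        kg.add(Triple(bad, RDF_TYPE, OWL_CLASS))  # class role
        kg.add(Triple(iri(_CAT_BASE + f"conflict/subj{k}"), bad, literal(f"v{k}")))  # predicate role
        ledger.injected_conflicts.append(bad.value)
    return kg, ledger


def demo_catalogue(vocab: CatalogueVocab = DEFAULT_CATALOGUE_VOCAB) -> tuple[KnowledgeGraph, TruthLedger]:
    """Synthetic stand-in for a small catalogue metadata snapshot.

    Deterministic (no seed) and shaped after the published worked examples:
    the topic "Tobacco" links to the DNBC and PSYCONN cohorts, and the
    harmonized keyword "blood pressure" reaches three cohorts (G21,
    ENVIRONAGE, GENR) through variable mappings.
    """
    kg = KnowledgeGraph()
    ledger = TruthLedger(params={"demo": True})

    areas = iri(_CAT_BASE + "class/AreasOfInformation")
    cohorts_cls = iri(_CAT_BASE + "class/Cohorts")
    mappings_cls = iri(_CAT_BASE + "class/VariableMappings")
    for cls, label in ((areas, "Areas of information"), (cohorts_cls, "Cohorts"), (mappings_cls, "Variable mappings")):
        kg.add(Triple(cls, RDFS_SUBCLASSOF, OWL_THING))
        kg.add(Triple(cls, RDFS_LABEL, literal(label)))

    def cohort(name: str):
        c = iri(_CAT_BASE + "cohort/" + name)
        kg.add(Triple(c, RDF_TYPE, cohorts_cls))
        kg.add(Triple(c, RDFS_LABEL, literal(name)))
        return c

    tobacco = iri(_CAT_BASE + "topic/Tobacco")
    kg.add(Triple(tobacco, RDF_TYPE, areas))
    kg.add(Triple(tobacco, RDFS_LABEL, literal("Tobacco")))
    dnbc, psyconn = cohort("DNBC"), cohort("PSYCONN")
    for c in (dnbc, psyconn):
        kg.add(Triple(c, iri(vocab.keyword_link), tobacco))
    ledger.topic_map["Tobacco"] = sorted([dnbc.value, psyconn.value])

    target = iri(_CAT_BASE + "variable/target/blood_pressure")
    kg.add(Triple(target, RDFS_LABEL, literal("Blood pressure (harmonized)")))
    kg.add(Triple(target, iri(vocab.variable_keyword), literal("blood pressure")))
    bp_cohorts = []
    for j, name in enumerate(("G21", "ENVIRONAGE", "GENR")):
        c = cohort(name)
        mapping = iri(_CAT_BASE + f"mapping/blood_pressure/{j}")
        source = iri(_CAT_BASE + f"variable/source/blood_pressure/{j}")
        dataset = iri(_CAT_BASE + f"dataset/blood_pressure/{j}")
        kg.add(Triple(mapping, RDF_TYPE, mappings_cls))
        kg.add(Triple(mapping, RDFS_LABEL, literal(f"BP mapping {name}")))
        kg.add(Triple(mapping, iri(vocab.mapping_target), target))
        kg.add(Triple(mapping, iri(vocab.mapping_source), source))
        kg.add(Triple(source, RDFS_LABEL, literal(f"Systolic BP ({name})")))
        kg.add(Triple(source, iri(vocab.in_dataset), dataset))
        kg.add(Triple(dataset, RDFS_LABEL, literal(f"Core dataset ({name})")))
        kg.add(Triple(dataset, iri(vocab.of_cohort), c))
        bp_cohorts.append(c.value)
    ledger.keyword_map["blood pressure"] = sorted(bp_cohorts)
    return kg, ledger
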