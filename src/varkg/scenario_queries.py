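"""Graph-analytic scenarios over a variant knowledge graph.

Four families of questions, each a deterministic query over the triple sets:

* patient clustering — group patients sharing variants in one gene
  (optionally restricted to a classification subset) or sharing one
  phenotype term, with a minimum-support threshold;
* closed gene–disease loops — cycles patient → phenotype → disease → GDA →
  gene → variant → patient, retaining only gene–disease associations that
  close such a cycle, with evidence attached where available;
* catalogue patterns — depth-1 class hierarchy roots, resources per topic,
  and cohorts reachable through harmonized variable mappings for a keyword.

Predicate IRIs for external sources (GDA graphs, catalogue snapshots) are
not standardized, so each operation takes a vocabulary configuration with
defaults matching the synthetic fixtures shipped with the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

from .rdf_core import (
    OWL_THING,
    RDF_TYPE,
    RDFS_LABEL,
    RDFS_SUBCLASSOF,
    KnowledgeGraph,
    Term,
    iri,
)
from .variant_kg import DEFAULT_SCHEMA, SchemaConfig

__all__ = [
    "Cluster",
    "GdaLoop",
    "GdaVocab",
    "CatalogueVocab",
    "VocabConfigError",
    "cluster_patients_by_gene",
    "cluster_patients_by_phenotype",
    "find_closed_loops",
    "class_hierarchy_roots",
    "resources_by_topic",
    "cohorts_by_harmonized_keyword",
]


class VocabConfigError(ValueError):
    """A vocabulary slot required by an operation is missing."""

    def __init__(self, slot: str):
        super().__init__(f"vocabulary configuration lacks predicate slot {slot!r}")
        self.slot = slot


@dataclass(frozen=True)
class Cluster:
    """Patients grouped under one key entity (gene or phenotype IRI)."""

    key: str
    members: frozenset[str]
    label: str | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GdaLoop:
    """One closed cycle patient→phenotype→disease→GDA→gene→variant→patient."""

    patient: str
    phenotype: str
    disease: str
    gda: str
    gene: str
    variant: str
    evidence: frozenset[str] = frozenset()

    def nodes(self) -> tuple[str, str, str, str, str, str]:
        return (self.patient, self.phenotype, self.disease, self.gda, self.gene, self.variant)


_GDA_BASE = "https://w3id.org/varkg/gda/vocab/"


@dataclass(frozen=True)
class GdaVocab:
    """Predicate IRIs for the six edges of the closed-loop template.

    The cohort-side predicates default to the converter's schema; the
    association-side predicates default to the synthetic GDA fixture shape
    (a disease links to a phenotype term, a GDA node links to its disease and
    gene, and optionally to evidence nodes).
    """

    has_phenotype: str = DEFAULT_SCHEMA.has_phenotype
    has_variant: str = DEFAULT_SCHEMA.has_variant
    has_transcript: str = DEFAULT_SCHEMA.has_transcript
    in_gene: str = DEFAULT_SCHEMA.in_gene
    disease_phenotype: str = _GDA_BASE + "associatedPhenotype"
    gda_disease: str = _GDA_BASE + "associatedDisease"
    gda_gene: str = _GDA_BASE + "associatedGene"
    evidence: str = _GDA_BASE + "hasEvidence"

    def require(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name):
                raise VocabConfigError(f.name)


DEFAULT_GDA_VOCAB = GdaVocab()


# Clustering ----------------------------------------------------------------


def _labels(kg: KnowledgeGraph) -> dict[str, str]:
    return {
        t.subject.value: t.object.value
        for t in kg.match(None, RDFS_LABEL, None)
        if t.subject.is_iri and t.object.is_literal
    }


def _variant_classifications(kg: KnowledgeGraph, schema: SchemaConfig) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for t in kg.match(None, iri(schema.has_classification), None):
        if t.object.is_literal:
            out.setdefault(t.subject.value, set()).add(t.object.value)
    # reified call nodes: classification sits on the call, variant behind it
    for call in kg.match(None, iri(schema.call_of_variant), None):
        for t in kg.match(call.subject, iri(schema.has_classification), None):
            if t.object.is_literal:
                out.setdefault(call.object.value, set()).add(t.object.value)
    return out


def _group(
    incidences: Iterable[tuple[str, str]],
    min_patients: int,
    labels: dict[str, str],
) -> tuple[Cluster, ...]:
    members: dict[str, set[str]] = {}
    for key, patient in incidences:
        members.setdefault(key, set()).add(patient)
    clusters = [
        Cluster(key=key, members=frozenset(pats), label=labels.get(key))
        for key, pats in members.items()
        if len(pats) >= min_patients
    ]
    return tuple(sorted(clusters, key=lambda c: c.key))


def cluster_patients_by_gene(
    kg: KnowledgeGraph,
    min_patients: int = 2,
    classifications: Iterable[str] | None = None,
    schema: SchemaConfig = DEFAULT_SCHEMA,
) -> tuple[Cluster, ...]:
    """Genes with at least ``min_patients`` distinct carrier patients.

    Traverses patient → variant → transcript → gene.  When
    ``classifications`` is given (e.g. ``{"P", "LP"}``), only variants
    carrying one of those pathogenicity labels contribute.  Ordered by gene
    IRI.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    allowed = frozenset(classifications) if classifications is not None else None
    variant_class = _variant_classifications(kg, schema) if allowed is not None else {}

    gene_of_transcript: dict[str, set[str]] = {}
    for t in kg.match(None, iri(schema.in_gene), None):
        gene_of_transcript.setdefault(t.subject.value, set()).add(t.object.value)
    transcripts_of_variant: dict[str, set[str]] = {}
    for t in kg.match(None, iri(schema.has_transcript), None):
        transcripts_of_variant.setdefault(t.subject.value, set()).add(t.object.value)

    incidences: list[tuple[str, str]] = []
    for t in kg.match(None, iri(schema.has_variant), None):
        patient, variant = t.subject.value, t.object.value
        if allowed is not None and not (variant_class.get(variant, set()) & allowed):
            continue
        for transcript in transcripts_of_variant.get(variant, ()):
            for gene in gene_of_transcript.get(transcript, ()):
                incidences.append((gene, patient))
    return _group(incidences, min_patients, _labels(kg))


def cluster_patients_by_phenotype(
    kg: KnowledgeGraph,
    min_patients: int = 2,
    schema: SchemaConfig = DEFAULT_SCHEMA,
) -> tuple[Cluster, ...]:
    """Phenotype terms shared by at least ``min_patients`` patients."""
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    incidences = [
        (t.object.value, t.subject.value)
        for t in kg.match(None, iri(schema.has_phenotype), None)
        if t.object.is_iri
    ]
    return _group(incidences, min_patients, _labels(kg))


# Closed loops ---------------------------------------------------------------


def find_closed_loops(
    patient_kg: KnowledgeGraph,
    gda_kg: KnowledgeGraph,
    vocab: GdaVocab = DEFAULT_GDA_VOCAB,
) -> frozenset[GdaLoop]:
    """All closed patient→phenotype→disease→GDA→gene→variant→patient cycles.

    A gene–disease association enters the result only when every mandatory
    edge of the cycle exists; associations that cannot close a loop are
    dropped.  A patient qualifying through two phenotypes for the same
    association yields two loops (no collapsing).  Evidence nodes attached to
    the association are carried along when present.
    """
    vocab.require()
    P = lambda value: iri(value)

    # cohort-side indexes
    phen_of_patient: dict[str, set[str]] = {}
    for t in patient_kg.match(None, P(vocab.has_phenotype), None):
        phen_of_patient.setdefault(t.subject.value, set()).add(t.object.value)
    variants_of_patient: dict[str, set[str]] = {}
    for t in patient_kg.match(None, P(vocab.has_variant), None):
        variants_of_patient.setdefault(t.subject.value, set()).add(t.object.value)
    transcripts_of_variant: dict[str, set[str]] = {}
    for t in patient_kg.match(None, P(vocab.has_transcript), None):
        transcripts_of_variant.setdefault(t.subject.value, set()).add(t.object.value)
    gene_of_transcript: dict[str, set[str]] = {}
    for t in patient_kg.match(None, P(vocab.in_gene), None):
        gene_of_transcript.setdefault(t.subject.value, set()).add(t.object.value)

    genes_of_variant: dict[str, set[str]] = {}
    for variant, transcripts in transcripts_of_variant.items():
        for tr in transcripts:
            genes_of_variant.setdefault(variant, set()).update(gene_of_transcript.get(tr, ()))

    # association-side indexes
    diseases_of_phenotype: dict[str, set[str]] = {}
    for t in gda_kg.match(None, P(vocab.disease_phenotype), None):
        diseases_of_phenotype.setdefault(t.object.value, set()).add(t.subject.value)
    gdas_of_disease: dict[str, set[str]] = {}
    for t in gda_kg.match(None, P(vocab.gda_disease), None):
        gdas_of_disease.setdefault(t.object.value, set()).add(t.subject.value)
    genes_of_gda: dict[str, set[str]] = {}
    for t in gda_kg.match(None, P(vocab.gda_gene), None):
        genes_of_gda.setdefault(t.subject.value, set()).add(t.object.value)
    evidence_of_gda: dict[str, frozenset[str]] = {}
    for t in gda_kg.match(None, P(vocab.evidence), None):
        evidence_of_gda.setdefault(t.subject.value, set())
        evidence_of_gda[t.subject.value] = frozenset(
            set(evidence_of_gda[t.subject.value]) | {t.object.value}
        )

    loops: set[GdaLoop] = set()
    for patient, phenotypes in phen_of_patient.items():
        patient_variants = variants_of_patient.get(patient, set())
        if not patient_variants:
            continue
        for phenotype in phenotypes:
            for disease in diseases_of_phenotype.get(phenotype, ()):
                for gda in gdas_of_disease.get(disease, ()):
                    for gene in genes_of_gda.get(gda, ()):
                        for variant in patient_variants:
                            if gene in genes_of_variant.get(variant, set()):
                                loops.add(
                                    GdaLoop(
                                        patient=patient,
                                        phenotype=phenotype,
                                        disease=disease,
                                        gda=gda,
                                        gene=gene,
                                        variant=variant,
                                        evidence=evidence_of_gda.get(gda, frozenset()),
                                    )
                                )
    return frozenset(loops)


# Catalogue patterns ---------------------------------------------------------

_CAT_BASE = "https://w3id.org/varkg/catalogue/vocab/"


@dataclass(frozen=True)
class CatalogueVocab:
    """Predicate IRIs for catalogue-shaped graphs (topics, harmonization)."""

    keyword_link: str = _CAT_BASE + "keyword"
    mapping_target: str = _CAT_BASE + "targetVariable"
    mapping_source: str = _CAT_BASE + "sourceVariable"
    variable_keyword: str = _CAT_BASE + "variableKeyword"
    in_dataset: str = _CAT_BASE + "inDataset"
    of_cohort: str = _CAT_BASE + "ofCohort"

    def require(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name):
                raise VocabConfigError(f.name)


DEFAULT_CATALOGUE_VOCAB = CatalogueVocab()


def class_hierarchy_roots(kg: KnowledgeGraph) -> tuple[tuple[str, str | None], ...]:
    """Depth-1 class hierarchy: subjects of ``rdfs:subClassOf owl:Thing``.

    Labels are attached when present and allowed to be absent, mirroring the
    catalogue starting query.  Ordered by IRI.
    """
    labels = _labels(kg)
    roots = {
        t.subject.value for t in kg.match(None, RDFS_SUBCLASSOF, OWL_THING) if t.subject.is_iri
    }
    return tuple((r, labels.get(r)) for r in sorted(roots))


def _resolve_topic(kg: KnowledgeGraph, topic: str) -> set[str]:
    if "://" in topic:
        return {topic}
    return {
        t.subject.value
        for t in kg.match(None, RDFS_LABEL, None)
        if t.object.is_literal and t.object.value.lower() == topic.lower() and t.subject.is_iri
    }


def resources_by_topic(
    kg: KnowledgeGraph,
    topic: str,
    vocab: CatalogueVocab = DEFAULT_CATALOGUE_VOCAB,
) -> frozenset[str]:
    """Resources (cohorts, databanks) linked to a topic via keyword links.

    ``topic`` may be an IRI or a label (matched case-insensitively).  An
    unknown topic yields the empty set.
    """
    vocab.require()
    topic_iris = _resolve_topic(kg, topic)
    return frozenset(
        t.subject.value
        for t in kg.match(None, iri(vocab.keyword_link), None)
        if t.object.is_iri and t.object.value in topic_iris
    )


def cohorts_by_harmonized_keyword(
    kg: KnowledgeGraph,
    keyword: str,
    vocab: CatalogueVocab = DEFAULT_CATALOGUE_VOCAB,
) -> tuple[str, ...]:
    """Cohorts whose source variables map onto a target variable for a keyword.

    Follows the harmonization path: variable-mapping → target variable →
    keyword, then variable-mapping → source variable → dataset → cohort.
    Returns cohort IRIs in deterministic (sorted) order.
    """
    vocab.require()
    # target variables carrying the keyword (literal match or label match)
    targets: set[str] = set()
    for t in kg.match(None, iri(vocab.variable_keyword), None):
        value = t.object.value if t.object.is_literal else None
        if value is not None and value.lower() == keyword.lower():
            targets.add(t.subject.value)
        elif t.object.is_iri and t.object.value in _resolve_topic(kg, keyword):
            targets.add(t.subject.value)

    cohorts: set[str] = set()
    for mapping_t in kg.match(None, iri(vocab.mapping_target), None):
        if mapping_t.object.value not in targets:
            continue
        mapping = mapping_t.subject
        for src_t in kg.match(mapping, iri(vocab.mapping_source), None):
            for ds_t in kg.match(src_t.object, iri(vocab.in_dataset), None):
                for cohort_t in kg.match(ds_t.object, iri(vocab.of_cohort), None):
                    if cohort_t.object.is_iri:
                        cohorts.add(cohort_t.object.value)
    return tuple(sorted(cohorts))
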