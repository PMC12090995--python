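"""Bridge drug/chemical RDF sources: ATC ontology, Drugbank-style, PubChem-style.

Three linking computations, each a local in-memory equivalent of a SPARQL
query over separately hosted sources:

* :func:`generate_atc_sameas` — aligns a UATC-style ATC ontology with
  bio2rdf ATC IRIs via ``owl:sameAs`` (both identify the same ATC code; only
  the IRI prefix differs).
* :func:`extract_depositor_links` — pulls depositor-identifier attribute
  nodes (SIO "is attribute of" / "has value") typed as DrugBank identifiers
  (CHEMINF_000406), optionally with CAS registry numbers (CHEMINF_000446).
* :func:`bridge_sources` — the three-way join around one DrugBank id,
  emitting the CONSTRUCT-style result graph that connects a drug entry, its
  ATC code in both ontologies, and the chemical compound record.

Federated SERVICE execution is replaced by joins over in-memory graphs; the
semantics per sub-pattern are unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .rdf_core import (
    OWL_CLASS,
    OWL_SAMEAS,
    RDF_TYPE,
    RDFS_LABEL,
    KnowledgeGraph,
    Term,
    Triple,
    iri,
    literal,
)

__all__ = [
    "DepositorLink",
    "SameAsLink",
    "DepositorExtraction",
    "generate_atc_sameas",
    "extract_depositor_links",
    "bridge_sources",
    "UATC_BASE",
    "ATC_BASE",
    "SIO_IS_ATTRIBUTE_OF",
    "SIO_HAS_VALUE",
    "CHEMINF_DRUGBANK_ID",
    "CHEMINF_CAS_NUMBER",
]

UATC_BASE = "http://purl.bioontology.org/ontology/UATC/"
ATC_BASE = "http://bio2rdf.org/atc:"
DRUGBANK_BASE = "http://bio2rdf.org/drugbank:"
DRUGBANK_VOCAB = "http://bio2rdf.org/drugbank_vocabulary:"
BIO2RDF_VOCAB = "http://bio2rdf.org/bio2rdf_vocabulary:"
SIO_BASE = "http://semanticscience.org/resource/"

SIO_IS_ATTRIBUTE_OF = iri(SIO_BASE + "SIO_000011")
SIO_HAS_VALUE = iri(SIO_BASE + "SIO_000300")
CHEMINF_DRUGBANK_ID = iri(SIO_BASE + "CHEMINF_000406")
CHEMINF_CAS_NUMBER = iri(SIO_BASE + "CHEMINF_000446")
X_ATC = iri(DRUGBANK_VOCAB + "x-atc")
BIO2RDF_IDENTIFIER = iri(BIO2RDF_VOCAB + "identifier")

_DRUGBANK_ID = re.compile(r"^DB\d{5}$")


@dataclass(frozen=True, order=True)
class SameAsLink:
    """One UATC-class ↔ bio2rdf-ATC alignment; the ATC code is shared."""

    uatc_iri: str
    atc_iri: str

    @property
    def code(self) -> str:
        return self.uatc_iri[len(UATC_BASE):]

    def triple(self) -> Triple:
        return Triple(iri(self.uatc_iri), OWL_SAMEAS, iri(self.atc_iri))


@dataclass(frozen=True, order=True)
class DepositorLink:
    """A depositor-identifier attribute node tying a compound to an external id."""

    value: str
    compound_iri: str
    attribute_iri: str
    attribute_type: str  # CHEMINF_000406 (DrugBank id) or CHEMINF_000446 (CAS)
    cas_numbers: tuple[str, ...] = ()


@dataclass(frozen=True)
class DepositorExtraction:
    links: tuple[DepositorLink, ...]
    warnings: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.links)

    def __len__(self):
        return len(self.links)


def generate_atc_sameas(atc_ontology: KnowledgeGraph) -> frozenset[SameAsLink]:
    """One ``owl:sameAs`` link per UATC-based ``owl:Class`` subject.

    The target IRI is the prefix rewrite of the source: the local ATC code is
    kept, the UATC base is replaced with the bio2rdf ATC base.  Idempotent and
    injective on codes; applying it to a graph of its own output adds nothing
    (sameAs subjects are not ``owl:Class`` instances).
    """
    links = set()
    for t in atc_ontology.match(None, RDF_TYPE, OWL_CLASS):
        if t.subject.is_iri and t.subject.value.startswith(UATC_BASE):
            code = t.subject.value[len(UATC_BASE):]
            links.add(SameAsLink(t.subject.value, ATC_BASE + code))
    return frozenset(links)


def sameas_graph(links: frozenset[SameAsLink], graph: str | None = None) -> KnowledgeGraph:
    """Materialize alignment links as owl:sameAs triples in a (named) graph."""
    kg = KnowledgeGraph()
    kg.add_all((link.triple() for link in links), graph=graph)
    return kg


def extract_depositor_links(
    pubchem_like: KnowledgeGraph,
    limit: int | None = 10,
) -> DepositorExtraction:
    """Every CHEMINF_000406-typed attribute node with its compound and value.

    CAS-number nodes (CHEMINF_000446) on the same compound are attached
    optionally — a compound with only a CAS node yields nothing, since the
    DrugBank-identifier pattern is mandatory.  Results are ordered by
    DrugBank id and truncated to ``limit`` (default 10, the desk-scale cap
    used against the full-size source; pass ``None`` for all).  Attribute
    nodes lacking a value are excluded and counted in the warnings.
    """
    kg = pubchem_like
    warnings: list[str] = []

    def attribute_nodes(type_iri: Term) -> list[Term]:
        return sorted(
            (t.subject for t in kg.match(None, RDF_TYPE, type_iri)),
            key=lambda s: s.value,
        )

    # CAS nodes indexed per compound for the optional attachment
    cas_by_compound: dict[str, list[str]] = {}
    for node in attribute_nodes(CHEMINF_CAS_NUMBER):
        values = sorted(
            o.value for o in kg.objects(node, SIO_HAS_VALUE) if o.is_literal
        )
        for t in kg.match(node, SIO_IS_ATTRIBUTE_OF, None):
            if t.object.is_iri:
                cas_by_compound.setdefault(t.object.value, []).extend(values)

    links: list[DepositorLink] = []
    for node in attribute_nodes(CHEMINF_DRUGBANK_ID):
        values = sorted(o.value for o in kg.objects(node, SIO_HAS_VALUE) if o.is_literal)
        if not values:
            warnings.append(f"depositor node without SIO_000300 value: {node.value}")
            continue
        compounds = sorted(
            t.object.value
            for t in kg.match(node, SIO_IS_ATTRIBUTE_OF, None)
            if t.object.is_iri
        )
        for compound in compounds:
            for value in values:
                links.append(
                    DepositorLink(
                        value=value,
                        compound_iri=compound,
                        attribute_iri=node.value,
                        attribute_type=CHEMINF_DRUGBANK_ID.value,
                        cas_numbers=tuple(sorted(set(cas_by_compound.get(compound, ())))),
                    )
                )
    links.sort()  # ORDER BY DrugBank id, then deterministic tie-breaks
    if limit is not None:
        links = links[:limit]
    return DepositorExtraction(links=tuple(links), warnings=tuple(warnings))


def bridge_sources(
    drugbank_kg: KnowledgeGraph,
    atc_kg: KnowledgeGraph,
    pubchem_kg: KnowledgeGraph,
    drug_id: str,
    ensure_sameas: bool = True,
) -> KnowledgeGraph:
    """Three-source CONSTRUCT around one DrugBank id (e.g. aspirin DB00945).

    Joins three local sub-matches on shared variables: the Drugbank-style
    graph supplies drug → identifier, drug → x-atc → ATC IRI and the drug
    label; the ATC graph supplies the UATC ``owl:sameAs`` alignment (derived
    on the fly from its UATC classes when no explicit sameAs triples exist
    and ``ensure_sameas`` is set); the PubChem-style graph supplies the
    depositor-identifier pattern, with CAS numbers attached optionally.  The
    result is empty whenever any mandatory sub-pattern fails to match.
    """
    if not _DRUGBANK_ID.match(drug_id):
        raise ValueError(f"malformed DrugBank id {drug_id!r} (expected DB#####)")

    out = KnowledgeGraph()

    # -- Drugbank sub-pattern (mandatory): identifier, x-atc, label
    drug_nodes = []
    for t in drugbank_kg.match(None, BIO2RDF_IDENTIFIER, None):
        if t.object.is_literal and t.object.value == drug_id:
            drug_nodes.append(t.subject)
    bindings = []  # (drug, atcUri, label)
    for drug in drug_nodes:
        atcs = [o for o in drugbank_kg.objects(drug, X_ATC) if o.is_iri]
        labels = [o for o in drugbank_kg.objects(drug, RDFS_LABEL) if o.is_literal]
        for atc in atcs:
            for label in labels:
                bindings.append((drug, atc, label))
    if not bindings:
        return out

    # -- ATC sub-pattern (mandatory): uatc sameAs atc
    sameas: dict[str, list[str]] = {}
    explicit = atc_kg.match(None, OWL_SAMEAS, None)
    if explicit:
        for t in explicit:
            if t.subject.is_iri and t.object.is_iri:
                sameas.setdefault(t.object.value, []).append(t.subject.value)
    elif ensure_sameas:
        for link in generate_atc_sameas(atc_kg):
            sameas.setdefault(link.atc_iri, []).append(link.uatc_iri)

    # -- PubChem sub-pattern (mandatory), CAS optional
    depositors = extract_depositor_links(pubchem_kg, limit=None)
    dep_by_value: dict[str, list[DepositorLink]] = {}
    for link in depositors:
        dep_by_value.setdefault(link.value, []).append(link)

    joined = False
    for drug, atc, label in bindings:
        uatcs = sameas.get(atc.value, [])
        deps = dep_by_value.get(drug_id, [])
        if not uatcs or not deps:
            continue
        joined = True
        out.add(Triple(drug, BIO2RDF_IDENTIFIER, literal(drug_id)))
        out.add(Triple(drug, X_ATC, atc))
        out.add(Triple(drug, RDFS_LABEL, label))
        for uatc in uatcs:
            out.add(Triple(iri(uatc), OWL_SAMEAS, atc))
        for dep in deps:
            compound = iri(dep.compound_iri)
            attribute = iri(dep.attribute_iri)
            # template as printed: compound → attribute for the id node,
            # attribute → compound for the CAS node
            out.add(Triple(compound, SIO_IS_ATTRIBUTE_OF, attribute))
            out.add(Triple(attribute, SIO_HAS_VALUE, literal(dep.value)))
            for cas_node in pubchem_kg.match(None, RDF_TYPE, CHEMINF_CAS_NUMBER):
                attached = pubchem_kg.match(cas_node.subject, SIO_IS_ATTRIBUTE_OF, compound)
                if not attached:
                    continue
                for v in pubchem_kg.objects(cas_node.subject, SIO_HAS_VALUE):
                    if v.is_literal:
                        out.add(Triple(cas_node.subject, SIO_IS_ATTRIBUTE_OF, compound))
                        out.add(Triple(cas_node.subject, SIO_HAS_VALUE, v))
    return out if joined else KnowledgeGraph()
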