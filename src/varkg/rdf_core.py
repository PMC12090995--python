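"""Minimal RDF data model with named graphs, CURIE handling and an export linter.

The in-memory model is deliberately small: immutable :class:`Term` and
:class:`Triple` values held in plain Python sets, partitioned into named
graphs by :class:`KnowledgeGraph`.  Set semantics are the contract — adding a
triple twice is a no-op, and every downstream query operation is defined as a
filter over these sets.  Parsing and serialization of the standard formats
(Turtle, N-Triples, RDF/XML) are delegated to :mod:`rdflib`; N-Triples output
is line-sorted so that identical graphs yield bit-identical files.

The linter (:func:`lint_roles`) operationalizes a malformation seen in
real-world RDF exports: one IRI used simultaneously as a class, an individual
and a predicate.  Exports produced by this toolkit are expected to lint clean.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import rdflib
from rdflib import BNode, Literal as RLiteral, URIRef

__all__ = [
    "Term",
    "Triple",
    "NamespaceTable",
    "KnowledgeGraph",
    "LintReport",
    "UnknownPrefixError",
    "RdfParseError",
    "iri",
    "literal",
    "bnode",
    "expand_curie",
    "compact_iri",
    "match",
    "read_rdf",
    "write_rdf",
    "lint_roles",
    "RDF_TYPE",
    "RDFS_LABEL",
    "RDFS_SUBCLASSOF",
    "OWL_CLASS",
    "OWL_THING",
    "OWL_SAMEAS",
    "XSD_STRING",
    "XSD_INTEGER",
]

# Well-known namespaces -----------------------------------------------------

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

XSD_STRING = XSD_NS + "string"
XSD_INTEGER = XSD_NS + "integer"
RDF_LANGSTRING = RDF_NS + "langString"


class UnknownPrefixError(KeyError):
    """Raised when a CURIE uses a prefix absent from the namespace table."""

    def __init__(self, prefix: str):
        super().__init__(prefix)
        self.prefix = prefix

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown CURIE prefix: {self.prefix!r}"


class RdfParseError(ValueError):
    """Raised when an RDF document cannot be parsed; carries the cause text."""


# Terms and triples ---------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Term:
    """One RDF term: an IRI, a literal, or a blank node.

    ``kind`` is one of ``"iri"``, ``"literal"``, ``"blank"``.  Literals carry
    an explicit datatype IRI (``xsd:string`` when undeclared, matching the
    Turtle default) or a language tag, never both.
    """

    kind: str
    value: str
    datatype: str | None = None
    language: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("iri", "literal", "blank"):
            raise ValueError(f"invalid term kind: {self.kind!r}")
        if self.kind == "iri" and ":" not in self.value:
            raise ValueError(f"IRI term must be absolute (no scheme): {self.value!r}")
        if self.kind != "literal" and (self.datatype or self.language):
            raise ValueError("datatype/language are only valid on literals")

    @property
    def is_iri(self) -> bool:
        return self.kind == "iri"

    @property
    def is_literal(self) -> bool:
        return self.kind == "literal"

    def n3(self) -> str:
        """N-Triples-style rendering, mainly for messages and sort keys."""
        return _term_to_rdflib(self).n3()


def iri(value: str) -> Term:
    return Term("iri", value)


def literal(value: str, datatype: str | None = None, language: str | None = None) -> Term:
    if language is not None:
        return Term("literal", str(value), datatype=RDF_LANGSTRING, language=language)
    return Term("literal", str(value), datatype=datatype or XSD_STRING)


def bnode(label: str) -> Term:
    return Term("blank", label)


RDF_TYPE = iri(RDF_NS + "type")
RDFS_LABEL = iri(RDFS_NS + "label")
RDFS_SUBCLASSOF = iri(RDFS_NS + "subClassOf")
RDFS_CLASS = iri(RDFS_NS + "Class")
RDFS_DOMAIN = iri(RDFS_NS + "domain")
RDFS_RANGE = iri(RDFS_NS + "range")
OWL_CLASS = iri(OWL_NS + "Class")
OWL_THING = iri(OWL_NS + "Thing")
OWL_SAMEAS = iri(OWL_NS + "sameAs")


@dataclass(frozen=True, slots=True)
class Triple:
    """A subject–predicate–object statement; equality is component-wise."""

    subject: Term
    predicate: Term
    object: Term

    def __post_init__(self) -> None:
        if self.subject.is_literal:
            raise ValueError("literal in subject position")
        if not self.predicate.is_iri:
            raise ValueError("predicate must be an IRI")

    def __iter__(self) -> Iterator[Term]:
        return iter((self.subject, self.predicate, self.object))

    def sort_key(self) -> tuple[str, str, str]:
        return (self.subject.n3(), self.predicate.n3(), self.object.n3())


# Namespace table -----------------------------------------------------------

_DEFAULT_PREFIXES: dict[str, str] = {
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "owl": OWL_NS,
    "xsd": XSD_NS,
    # sio and cheminf intentionally share one base IRI, as the source
    # vocabularies themselves do.
    "sio": "http://semanticscience.org/resource/",
    "cheminf": "http://semanticscience.org/resource/",
    "uatc": "http://purl.bioontology.org/ontology/UATC/",
    "atc": "http://bio2rdf.org/atc:",
    "drugbank": "http://bio2rdf.org/drugbank:",
    "drugbank_vocabulary": "http://bio2rdf.org/drugbank_vocabulary:",
    "bio2rdf": "http://bio2rdf.org/bio2rdf_vocabulary:",
    "obo": "http://purl.obolibrary.org/obo/",
    "HP": "http://purl.obolibrary.org/obo/HP_",
    "compound": "http://rdf.ncbi.nlm.nih.gov/pubchem/compound/",
}


class NamespaceTable:
    """Prefix → base-IRI mapping with expand/compact round-trip guarantees.

    ``sio`` and ``cheminf`` deliberately share one base IRI; compaction
    tie-breaks on the local name (``SIO_*`` → sio, ``CHEMINF_*`` → cheminf).
    """

    def __init__(self, extra: Mapping[str, str] | None = None, *, preload: bool = True):
        self._map: dict[str, str] = dict(_DEFAULT_PREFIXES) if preload else {}
        if extra:
            self._map.update(extra)

    def register(self, prefix: str, base: str) -> None:
        self._map[prefix] = base

    def __contains__(self, prefix: str) -> bool:
        return prefix in self._map

    def __getitem__(self, prefix: str) -> str:
        try:
            return self._map[prefix]
        except KeyError:
            raise UnknownPrefixError(prefix) from None

    def items(self):
        return self._map.items()

    def expand(self, curie: str) -> Term:
        """Expand ``prefix:local`` to an absolute IRI term.

        Absolute IRIs (anything with ``://`` or a ``urn:`` scheme) pass
        through unchanged.
        """
        if "://" in curie or curie.startswith("urn:"):
            return iri(curie)
        if ":" not in curie:
            raise ValueError(f"not a CURIE or absolute IRI: {curie!r}")
        prefix, local = curie.split(":", 1)
        return iri(self[prefix] + local)

    def compact(self, iri_value: str) -> str:
        """Compact an IRI to ``prefix:local`` when a registered base matches.

        The longest matching base wins; for the shared sio/cheminf base the
        prefix is chosen from the local name.  Unmatched IRIs are returned
        unchanged.
        """
        best: tuple[str, str] | None = None
        for prefix, base in self._map.items():
            if iri_value.startswith(base) and (best is None or len(base) > len(best[1])):
                best = (prefix, base)
        if best is None:
            return iri_value
        prefix, base = best
        local = iri_value[len(base):]
        if base == "http://semanticscience.org/resource/":
            prefix = "cheminf" if local.startswith("CHEMINF_") else "sio"
        return f"{prefix}:{local}"


DEFAULT_NAMESPACES = NamespaceTable()


def expand_curie(curie: str, ns: NamespaceTable | None = None) -> Term:
    """Module-level convenience for :meth:`NamespaceTable.expand`."""
    return (ns or DEFAULT_NAMESPACES).expand(curie)


def compact_iri(iri_value: str, ns: NamespaceTable | None = None) -> str:
    return (ns or DEFAULT_NAMESPACES).compact(iri_value)


# Knowledge graph -----------------------------------------------------------

_DEFAULT_GRAPH = object()  # sentinel: the (unnamed) default graph only


class KnowledgeGraph:
    """A set of triples partitioned into a default graph and named graphs.

    Within each graph, triples are a set (no duplicates); ``len`` is the sum
    of the per-graph set sizes, and the union over graphs is well-defined.
    """

    DEFAULT = _DEFAULT_GRAPH

    def __init__(self) -> None:
        self._default: set[Triple] = set()
        self._named: dict[str, set[Triple]] = {}

    # -- mutation

    def add(self, triple: Triple, graph: str | None = None) -> None:
        self._bucket(graph, create=True).add(triple)

    def add_all(self, triples: Iterable[Triple], graph: str | None = None) -> None:
        self._bucket(graph, create=True).update(triples)

    def discard(self, triple: Triple, graph: str | None = None) -> None:
        if graph is None:
            self._default.discard(triple)
            for bucket in self._named.values():
                bucket.discard(triple)
        else:
            self._named.get(graph, set()).discard(triple)

    def _bucket(self, graph: str | None, create: bool = False) -> set[Triple]:
        if graph is None or graph is _DEFAULT_GRAPH:
            return self._default
        if create:
            return self._named.setdefault(graph, set())
        return self._named.get(graph, set())

    # -- access

    @property
    def graph_names(self) -> tuple[str, ...]:
        return tuple(sorted(self._named))

    def triples(self, graph: str | None | object = None) -> frozenset[Triple]:
        """All triples — the union over graphs, or one graph when named.

        Pass ``KnowledgeGraph.DEFAULT`` to select the unnamed default graph.
        """
        if graph is None:
            out = set(self._default)
            for bucket in self._named.values():
                out |= bucket
            return frozenset(out)
        if graph is _DEFAULT_GRAPH:
            return frozenset(self._default)
        return frozenset(self._named.get(graph, set()))

    def __len__(self) -> int:
        return len(self._default) + sum(len(b) for b in self._named.values())

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._default or any(triple in b for b in self._named.values())

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples())

    def copy(self) -> "KnowledgeGraph":
        out = KnowledgeGraph()
        out._default = set(self._default)
        out._named = {name: set(bucket) for name, bucket in self._named.items()}
        return out

    def union(self, *others: "KnowledgeGraph") -> "KnowledgeGraph":
        out = self.copy()
        for other in others:
            out._default |= other._default
            for name, bucket in other._named.items():
                out._named.setdefault(name, set()).update(bucket)
        return out

    def match(
        self,
        subject: Term | None = None,
        predicate: Term | None = None,
        object: Term | None = None,
        graph: str | None | object = None,
    ) -> frozenset[Triple]:
        """Triples agreeing with every bound slot (``None`` = wildcard)."""
        return frozenset(
            t
            for t in self.triples(graph)
            if (subject is None or t.subject == subject)
            and (predicate is None or t.predicate == predicate)
            and (object is None or t.object == object)
        )

    def subjects(self, predicate: Term | None = None, object: Term | None = None):
        return frozenset(t.subject for t in self.match(None, predicate, object))

    def objects(self, subject: Term | None = None, predicate: Term | None = None):
        return frozenset(t.object for t in self.match(subject, predicate, None))


def match(
    kg: KnowledgeGraph,
    pattern: tuple[Term | None, Term | None, Term | None],
    graph: str | None | object = None,
) -> frozenset[Triple]:
    """Triple-pattern matching over a knowledge graph (``None`` = wildcard)."""
    s, p, o = pattern
    return kg.match(s, p, o, graph=graph)


# rdflib conversion ---------------------------------------------------------


def _term_to_rdflib(term: Term):
    if term.kind == "iri":
        return URIRef(term.value)
    if term.kind == "blank":
        return BNode(term.value)
    if term.language is not None:
        return RLiteral(term.value, lang=term.language)
    if term.datatype and term.datatype != XSD_STRING:
        return RLiteral(term.value, datatype=URIRef(term.datatype))
    return RLiteral(term.value)


def _term_from_rdflib(node) -> Term:
    if isinstance(node, URIRef):
        return iri(str(node))
    if isinstance(node, BNode):
        return bnode(str(node))
    if isinstance(node, RLiteral):
        if node.language:
            return literal(str(node), language=node.language)
        dt = str(node.datatype) if node.datatype else None
        return literal(str(node), datatype=dt)
    raise TypeError(f"unsupported rdflib node: {node!r}")


def to_rdflib(kg: KnowledgeGraph, graph: str | None | object = None, ns: NamespaceTable | None = None) -> rdflib.Graph:
    g = rdflib.Graph()
    for prefix, base in (ns or DEFAULT_NAMESPACES).items():
        # sio wins the shared base when binding prefixes for Turtle headers
        if prefix == "cheminf":
            continue
        g.bind(prefix, base, override=True, replace=True)
    for t in kg.triples(graph):
        g.add((_term_to_rdflib(t.subject), _term_to_rdflib(t.predicate), _term_to_rdflib(t.object)))
    return g


def from_rdflib(g: rdflib.Graph, into: KnowledgeGraph | None = None, graph: str | None = None) -> KnowledgeGraph:
    kg = into or KnowledgeGraph()
    kg.add_all(
        (Triple(_term_from_rdflib(s), _term_from_rdflib(p), _term_from_rdflib(o)) for s, p, o in g),
        graph=graph,
    )
    return kg


# I/O -----------------------------------------------------------------------

_FORMATS = {"turtle": "turtle", "ttl": "turtle", "ntriples": "nt", "nt": "nt", "rdfxml": "xml", "rdf": "xml", "xml": "xml"}

_EXT_FORMAT = {".ttl": "turtle", ".nt": "nt", ".rdf": "xml", ".owl": "xml", ".xml": "xml"}


def _resolve_format(path: Path, fmt: str | None, for_write: bool = False) -> str:
    if fmt is not None:
        key = fmt.lower()
        if key not in _FORMATS:
            raise ValueError(f"unknown RDF format: {fmt!r}")
        resolved = _FORMATS[key]
    else:
        resolved = _EXT_FORMAT.get(path.suffix.lower(), "turtle")
    if for_write and resolved == "xml":
        raise ValueError("RDF/XML writing is not supported (use turtle or ntriples)")
    return resolved


def read_rdf(path: str | Path, format: str | None = None, graph: str | None = None,
             into: KnowledgeGraph | None = None) -> KnowledgeGraph:
    """Read a Turtle / N-Triples / RDF-XML document into a knowledge graph.

    Duplicated statements collapse to one triple (set semantics).  Parse
    failures raise :class:`RdfParseError` carrying rdflib's message, which
    includes the offending line for Turtle/N-Triples sources.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    g = rdflib.Graph()
    try:
        g.parse(path, format=fmt)
    except Exception as exc:  # rdflib raises several parser-specific types
        raise RdfParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return from_rdflib(g, into=into, graph=graph)


def write_rdf(kg: KnowledgeGraph, path: str | Path, format: str | None = None,
              graph: str | None | object = None, ns: NamespaceTable | None = None) -> Path:
    """Write a graph (the union, or one named graph) as Turtle or N-Triples.

    N-Triples output is sorted lexicographically by (subject, predicate,
    object) so identical graphs produce byte-identical files; Turtle output
    carries the namespace table's prefixes in its header.
    """
    path = Path(path)
    fmt = _resolve_format(path, format, for_write=True)
    g = to_rdflib(kg, graph=graph, ns=ns)
    if fmt == "nt":
        lines = sorted(
            f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in g
        )
        path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    else:
        path.write_text(g.serialize(format=fmt), encoding="utf-8")
    return path


# Linter --------------------------------------------------------------------

_META_CLASSES = {OWL_CLASS, RDFS_CLASS}
_CORE_PREFIXES = (RDF_NS, RDFS_NS, OWL_NS, XSD_NS)


@dataclass(frozen=True)
class LintReport:
    """Outcome of the URI-role linter.

    ``conflicts`` maps each IRI used in two or more incompatible roles to the
    set of roles observed (subset of {"class", "individual", "predicate"});
    ``missing_labels`` lists node IRIs with no ``rdfs:label``.
    """

    conflicts: Mapping[str, frozenset[str]]
    missing_labels: frozenset[str]
    counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.conflicts


def lint_roles(kg: KnowledgeGraph, flag_domain_range: bool = False) -> LintReport:
    """Detect IRIs used simultaneously as class, individual and/or predicate.

    Role assignment: an IRI is a *predicate* if it occurs in predicate
    position; a *class* if it is the object of ``rdf:type``, participates in
    ``rdfs:subClassOf``, or is itself typed ``owl:Class``/``rdfs:Class``; an
    *individual* if it is the subject of ``rdf:type`` whose object is not a
    meta-class.  Any IRI holding two or more roles is a conflict.  When
    ``flag_domain_range`` is set, subjects of ``rdfs:domain``/``rdfs:range``
    additionally count as predicates (declared-property evidence).

    Deterministic for a given graph: output containers are sorted/frozen.
    """
    roles: dict[str, set[str]] = {}

    def mark(term: Term, role: str) -> None:
        if term.is_iri:
            roles.setdefault(term.value, set()).add(role)

    labeled: set[str] = set()
    node_iris: set[str] = set()
    for t in kg.triples():
        mark(t.predicate, "predicate")
        if t.predicate == RDF_TYPE:
            mark(t.object, "class")
            if t.object in _META_CLASSES:
                mark(t.subject, "class")
            else:
                mark(t.subject, "individual")
        elif t.predicate == RDFS_SUBCLASSOF:
            mark(t.subject, "class")
            mark(t.object, "class")
        elif flag_domain_range and t.predicate in (RDFS_DOMAIN, RDFS_RANGE):
            mark(t.subject, "predicate")
        if t.predicate == RDFS_LABEL and t.subject.is_iri:
            labeled.add(t.subject.value)
        for node in (t.subject, t.object):
            if node.is_iri and not node.value.startswith(_CORE_PREFIXES):
                node_iris.add(node.value)

    conflicts = {
        value: frozenset(rs) for value, rs in sorted(roles.items()) if len(rs) >= 2
    }
    missing = frozenset(v for v in node_iris if v not in labeled)
    counts = {
        "iris_in_roles": len(roles),
        "conflicts": len(conflicts),
        "missing_labels": len(missing),
    }
    return LintReport(conflicts=conflicts, missing_labels=missing, counts=counts)
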