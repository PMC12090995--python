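"""Independent brute-force oracles used to cross-check the query operations.

Everything here works on raw (subject, predicate, object) string tuples and
nested loops with set-membership tests — deliberately sharing no code with
the indexed implementations it checks.
"""

from __future__ import annotations

from itertools import product

from varkg.rdf_core import KnowledgeGraph, Triple


def raw(kg: KnowledgeGraph, graph=None) -> set[tuple]:
    """Triples as plain comparable tuples (kind-tagged for literals)."""
    out = set()
    for t in kg.triples(graph):
        out.add(
            (
                (t.subject.kind, t.subject.value),
                t.predicate.value,
                (t.object.kind, t.object.value, t.object.datatype, t.object.language),
            )
        )
    return out


def scan_match(kg: KnowledgeGraph, s=None, p=None, o=None) -> set[Triple]:
    """Exhaustive scan over the full triple list, no indexes."""
    hits = set()
    for t in list(kg.triples()):
        if s is not None and t.subject != s:
            continue
        if p is not None and t.predicate != p:
            continue
        if o is not None and t.object != o:
            continue
        hits.add(t)
    return hits


def _edges(kg: KnowledgeGraph, predicate: str) -> set[tuple[str, str]]:
    return {
        (t.subject.value, t.object.value)
        for t in kg.triples()
        if t.predicate.value == predicate and t.object.kind == "iri"
    }


def enumerate_loops(patient_kg: KnowledgeGraph, gda_kg: KnowledgeGraph, vocab) -> set[tuple]:
    """Brute-force 6-tuple enumeration of closed patient→…→variant cycles.

    Candidate sets come from predicate positions; each of the six cycle
    edges is checked by membership in the raw edge sets.
    """
    has_ph = _edges(patient_kg, vocab.has_phenotype)
    has_v = _edges(patient_kg, vocab.has_variant)
    has_tr = _edges(patient_kg, vocab.has_transcript)
    in_gene = _edges(patient_kg, vocab.in_gene)
    d_ph = _edges(gda_kg, vocab.disease_phenotype)
    g_d = _edges(gda_kg, vocab.gda_disease)
    g_gene = _edges(gda_kg, vocab.gda_gene)

    patients = {s for s, _ in has_ph} | {s for s, _ in has_v}
    phenotypes = {o for _, o in has_ph}
    diseases = {s for s, _ in d_ph}
    gdas = {s for s, _ in g_d}
    genes = {o for _, o in g_gene}
    variants = {o for _, o in has_v}

    loops = set()
    for pat, ph in product(sorted(patients), sorted(phenotypes)):
        if (pat, ph) not in has_ph:
            continue
        for d in diseases:
            if (d, ph) not in d_ph:
                continue
            for gda in gdas:
                if (gda, d) not in g_d:
                    continue
                for gene in genes:
                    if (gda, gene) not in g_gene:
                        continue
                    for v in variants:
                        if (pat, v) not in has_v:
                            continue
                        if any((v, tr) in has_tr and (tr, gene) in in_gene for tr in {t for _, t in has_tr}):
                            loops.add((pat, ph, d, gda, gene, v))
    return loops


def enumerate_depositors(pubchem: KnowledgeGraph) -> set[tuple[str, str, str]]:
    """All (drugbank-id value, compound, attribute-node) joins, exhaustively."""
    triples = [(t.subject, t.predicate.value, t.object) for t in pubchem.triples()]
    sio = "http://semanticscience.org/resource/"
    typed = {
        s.value
        for s, p, o in triples
        if p.endswith("22-rdf-syntax-ns#type") and o.kind == "iri" and o.value == sio + "CHEMINF_000406"
    }
    out = set()
    for node in typed:
        for s1, p1, o1 in triples:
            if s1.value != node or p1 != sio + "SIO_000011" or o1.kind != "iri":
                continue
            for s2, p2, o2 in triples:
                if s2.value == node and p2 == sio + "SIO_000300" and o2.kind == "literal":
                    out.add((o2.value, o1.value, node))
    return out


def enumerate_bridge(drugbank: KnowledgeGraph, atc: KnowledgeGraph, pubchem: KnowledgeGraph,
                     drug_id: str) -> set[tuple]:
    """Nested-loop three-way join mirroring the federated query's semantics.

    Returns the joined variable bindings (drug, atcUri, label, uatc,
    compound, depositor) — one tuple per successful mandatory join.
    """
    db = [(t.subject.value, t.predicate.value, t.object) for t in drugbank.triples()]
    ident = "http://bio2rdf.org/bio2rdf_vocabulary:identifier"
    xatc = "http://bio2rdf.org/drugbank_vocabulary:x-atc"
    label_p = "http://www.w3.org/2000/01/rdf-schema#label"
    sameas_p = "http://www.w3.org/2002/07/owl#sameAs"
    uatc_base = "http://purl.bioontology.org/ontology/UATC/"
    atc_base = "http://bio2rdf.org/atc:"

    drugs = {s for s, p, o in db if p == ident and o.kind == "literal" and o.value == drug_id}
    # sameAs: explicit triples, else derived from UATC owl:Class subjects
    sameas = {
        (t.subject.value, t.object.value)
        for t in atc.triples()
        if t.predicate.value == sameas_p
    }
    if not sameas:
        for t in atc.triples():
            if (
                t.predicate.value.endswith("22-rdf-syntax-ns#type")
                and t.object.value == "http://www.w3.org/2002/07/owl#Class"
                and t.subject.value.startswith(uatc_base)
            ):
                code = t.subject.value[len(uatc_base):]
                sameas.add((t.subject.value, atc_base + code))

    deps = enumerate_depositors(pubchem)

    rows = set()
    for drug in drugs:
        for s, p, o in db:
            if s != drug or p != xatc or o.kind != "iri":
                continue
            atc_uri = o.value
            for s2, p2, o2 in db:
                if s2 != drug or p2 != label_p or o2.kind != "literal":
                    continue
                for uatc, target in sameas:
                    if target != atc_uri:
                        continue
                    for value, compound, node in deps:
                        if value == drug_id:
                            rows.add((drug, atc_uri, o2.value, uatc, compound, node))
    return rows
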