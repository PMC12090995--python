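"""Convert annotated VCF output plus a patient sample sheet into RDF.

The converter mirrors the shape used by variant-interpretation pipelines:
each patient node links to its phenotype terms (HPO IRIs) and to the variant
nodes it carries; variants link to their transcripts, transcripts to genes
and to consequence terms; the pipeline's five-level pathogenicity
classification (P / LP / VUS / LB / B) hangs off the variant node.  Labels
for phenotype and consequence IRIs are copied in from small ontology
fragments (an HPO subset and an Ensembl-style consequence glossary).

All minted IRIs are deterministic functions of their inputs, so converting
the same cohort twice yields byte-identical sorted N-Triples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

from .rdf_core import (
    OWL_CLASS,
    RDF_TYPE,
    RDFS_LABEL,
    RDFS_SUBCLASSOF,
    XSD_INTEGER,
    KnowledgeGraph,
    Term,
    Triple,
    expand_curie,
    iri,
    literal,
    read_rdf,
)

__all__ = [
    "PatientRecord",
    "VariantObservation",
    "OntologyFragment",
    "SchemaConfig",
    "SampleSheetResult",
    "VcfParseResult",
    "SampleSheetError",
    "ReferentialIntegrityError",
    "CLASSIFICATIONS",
    "parse_sample_sheet",
    "parse_vcf",
    "build_variant_graph",
    "attach_labels",
]

CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B")

_HP_CURIE = re.compile(r"^HP:\d{7}$")


class SampleSheetError(ValueError):
    """Schema problem in a sample sheet (missing column, duplicate id)."""


class ReferentialIntegrityError(ValueError):
    """VCF carriers reference patient ids absent from the sample sheet."""

    def __init__(self, missing: Sequence[str]):
        super().__init__(f"carrier ids without a patient record: {sorted(missing)}")
        self.missing = tuple(sorted(missing))


@dataclass(frozen=True)
class PatientRecord:
    """One sample-sheet row: a patient id and its HPO phenotype CURIEs."""

    patient_id: str
    phenotypes: frozenset[str]
    sex: str | None = None
    affected: bool | None = None


@dataclass(frozen=True)
class VariantObservation:
    """One (site, alt allele, transcript) annotation row with carriers."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence: str
    classification: str
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be 1-based and >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"invalid classification {self.classification!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"


@dataclass(frozen=True)
class OntologyFragment:
    """Labels and subclass edges extracted from an ontology file."""

    terms: Mapping[str, str]
    subclass_edges: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_rdf(cls, path: str | Path, format: str | None = None) -> "OntologyFragment":
        kg = read_rdf(path, format=format)
        terms = {
            t.subject.value: t.object.value
            for t in kg.match(None, RDFS_LABEL, None)
            if t.subject.is_iri and t.object.is_literal
        }
        edges = frozenset(
            (t.subject.value, t.object.value)
            for t in kg.match(None, RDFS_SUBCLASSOF, None)
            if t.subject.is_iri and t.object.is_iri
        )
        return cls(terms=terms, subclass_edges=edges)


# Schema --------------------------------------------------------------------

_BASE = "https://w3id.org/varkg/"


@dataclass(frozen=True)
class SchemaConfig:
    """Predicate/type IRIs and minting rules for the emitted graph.

    Every predicate the builder emits is declared here (plus ``rdf:type`` and
    ``rdfs:label``); minting is a pure function of the input record, so the
    same cohort always receives the same IRIs.
    """

    base: str = _BASE
    patient_type: str = _BASE + "vocab/Patient"
    variant_type: str = _BASE + "vocab/Variant"
    transcript_type: str = _BASE + "vocab/Transcript"
    gene_type: str = _BASE + "vocab/Gene"
    has_phenotype: str = _BASE + "vocab/hasPhenotype"
    has_variant: str = _BASE + "vocab/hasVariant"
    has_transcript: str = _BASE + "vocab/hasTranscript"
    in_gene: str = _BASE + "vocab/inGene"
    has_consequence: str = _BASE + "vocab/hasConsequence"
    has_classification: str = _BASE + "vocab/hasClassification"
    at_position: str = _BASE + "vocab/atPosition"
    # "variant": classification on the variant node; "call": reified
    # per-patient call node carrying the classification.
    classification_on: str = "variant"
    has_call: str = _BASE + "vocab/hasVariantCall"
    call_of_variant: str = _BASE + "vocab/ofVariant"

    def patient_iri(self, patient_id: str) -> Term:
        return iri(self.base + "patient/" + patient_id)

    def variant_iri(self, obs: VariantObservation) -> Term:
        return iri(self.base + "variant/" + obs.key)

    def transcript_iri(self, transcript: str) -> Term:
        return iri(self.base + "transcript/" + transcript)

    def gene_iri(self, gene: str) -> Term:
        return iri(self.base + "gene/" + gene)

    def consequence_iri(self, term: str) -> Term:
        return iri(self.base + "vocab/consequence/" + term)

    def predicate_iris(self) -> frozenset[str]:
        return frozenset(
            {
                self.has_phenotype,
                self.has_variant,
                self.has_transcript,
                self.in_gene,
                self.has_consequence,
                self.has_classification,
                self.at_position,
                self.has_call,
                self.call_of_variant,
            }
        )


DEFAULT_SCHEMA = SchemaConfig()


def phenotype_iri(curie: str) -> Term:
    """HP:0000505 → the OBO PURL for that phenotype term."""
    return expand_curie(curie)


# Sample sheet --------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheetResult:
    records: tuple[PatientRecord, ...]
    warnings: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def parse_sample_sheet(
    path: str | Path,
    id_column: str = "individual_id",
    phenotype_column: str = "hpo_ids",
    sep: str | None = None,
) -> SampleSheetResult:
    """Parse a TSV/CSV sample sheet into patient records.

    The phenotype column holds semicolon-separated HPO CURIEs; entries not
    matching ``HP:#######`` are collected into the warning list rather than
    silently dropped.  A missing required column or a duplicated patient id
    is a :class:`SampleSheetError`.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    for col in (id_column, phenotype_column):
        if col not in df.columns:
            raise SampleSheetError(f"sample sheet is missing required column {col!r}")
    dupes = df[id_column][df[id_column].duplicated()].tolist()
    if dupes:
        raise SampleSheetError(f"duplicate patient ids: {sorted(set(dupes))}")

    warnings: list[str] = []
    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        pid = row[id_column].strip()
        phenos: set[str] = set()
        for token in filter(None, (t.strip() for t in row[phenotype_column].split(";"))):
            if _HP_CURIE.match(token):
                phenos.add(token)
            else:
                warnings.append(f"{pid}: malformed HPO CURIE {token!r}")
        sex = row.get("sex", "") or None
        affected_raw = str(row.get("affected", "")).strip().lower()
        affected = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}.get(affected_raw)
        records.append(PatientRecord(pid, frozenset(phenos), sex=sex, affected=affected))
    return SampleSheetResult(records=tuple(records), warnings=tuple(warnings))


# VCF -----------------------------------------------------------------------


@dataclass(frozen=True)
class VcfParseResult:
    observations: tuple[VariantObservation, ...]
    warnings: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.observations)

    def __len__(self):
        return len(self.observations)


def _csq_fields(vcf: VCF, csq_field: str) -> list[str]:
    header = vcf.get_header_type(csq_field)
    desc = header.get("Description", "")
    m = re.search(r"Format:\s*([^\"]+)", desc)
    if not m:
        raise ValueError(f"INFO/{csq_field} header does not declare a Format")
    return [f.strip() for f in m.group(1).split("|")]


def parse_vcf(
    path: str | Path,
    csq_field: str = "CSQ",
    classification_key: str = "VIPC",
    allele_key: str = "Allele",
    gene_key: str = "SYMBOL",
    transcript_key: str = "Feature",
    consequence_key: str = "Consequence",
) -> VcfParseResult:
    """Parse an annotated VCF into per-(site, alt, transcript) observations.

    Multi-allelic sites are split per alt allele; the carrier set of an
    observation is every sample whose genotype contains that alt.  Annotation
    entries whose classification falls outside P/LP/VUS/LB/B are rejected to
    the warning list.  The per-transcript annotation lives in the ``CSQ``
    INFO field (VEP convention) with configurable sub-field names.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read VCF {path}: {exc}") from exc
    try:
        fields = _csq_fields(vcf, csq_field)
    except Exception as exc:
        raise ValueError(
            f"VCF {path} lacks a usable INFO/{csq_field} annotation header: {exc}"
        ) from exc
    for key in (allele_key, classification_key, gene_key, transcript_key, consequence_key):
        if key not in fields:
            raise ValueError(f"INFO/{csq_field} Format lacks required key {key!r}")
    idx = {name: i for i, name in enumerate(fields)}
    samples = list(vcf.samples)

    observations: list[VariantObservation] = []
    warnings: list[str] = []
    for rec in vcf:
        raw = rec.INFO.get(csq_field)
        if raw is None:
            warnings.append(f"{rec.CHROM}:{rec.POS}: no {csq_field} annotation")
            continue
        # carriers per alt index (1-based allele codes in GT)
        carriers: dict[int, set[str]] = {i + 1: set() for i in range(len(rec.ALT))}
        for sample, gt in zip(samples, rec.genotypes):
            for allele in gt[:-1]:  # last element is phasing flag
                if isinstance(allele, int) and allele >= 1:
                    carriers[allele].add(sample)
        for entry in str(raw).split(","):
            parts = entry.split("|")
            if len(parts) != len(fields):
                warnings.append(f"{rec.CHROM}:{rec.POS}: malformed {csq_field} entry {entry!r}")
                continue
            allele = parts[idx[allele_key]]
            classification = parts[idx[classification_key]]
            if classification not in CLASSIFICATIONS:
                warnings.append(
                    f"{rec.CHROM}:{rec.POS}:{allele}: classification {classification!r} outside P/LP/VUS/LB/B"
                )
                continue
            try:
                alt_index = rec.ALT.index(allele) + 1
            except ValueError:
                warnings.append(f"{rec.CHROM}:{rec.POS}: {csq_field} allele {allele!r} not among ALTs")
                continue
            observations.append(
                VariantObservation(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=allele,
                    gene=parts[idx[gene_key]],
                    transcript=parts[idx[transcript_key]],
                    consequence=parts[idx[consequence_key]],
                    classification=classification,
                    carriers=frozenset(carriers[alt_index]),
                )
            )
    return VcfParseResult(observations=tuple(observations), warnings=tuple(warnings))


# Graph construction --------------------------------------------------------

_EMPTY_FRAGMENT = OntologyFragment(terms={})


def build_variant_graph(
    patients: Iterable[PatientRecord],
    observations: Iterable[VariantObservation],
    hpo: OntologyFragment = _EMPTY_FRAGMENT,
    glossary: OntologyFragment = _EMPTY_FRAGMENT,
    cfg: SchemaConfig = DEFAULT_SCHEMA,
) -> KnowledgeGraph:
    """Assemble the patient–phenotype–variant–transcript–gene RDF graph.

    Every carrier id in the observations must have a patient record
    (:class:`ReferentialIntegrityError` otherwise).  The output is purely a
    function of the inputs and lints clean: no IRI is reused across the
    class/individual/predicate roles.
    """
    patients = list(patients)
    observations = list(observations)
    known = {p.patient_id for p in patients}
    missing = {c for obs in observations for c in obs.carriers} - known
    if missing:
        raise ReferentialIntegrityError(sorted(missing))

    kg = KnowledgeGraph()

    def add(s: Term, p: Term, o: Term) -> None:
        kg.add(Triple(s, p, o))

    for type_iri, label in (
        (cfg.patient_type, "Patient"),
        (cfg.variant_type, "Variant"),
        (cfg.transcript_type, "Transcript"),
        (cfg.gene_type, "Gene"),
    ):
        add(iri(type_iri), RDF_TYPE, OWL_CLASS)
        add(iri(type_iri), RDFS_LABEL, literal(label))

    for patient in sorted(patients, key=lambda p: p.patient_id):
        p_iri = cfg.patient_iri(patient.patient_id)
        add(p_iri, RDF_TYPE, iri(cfg.patient_type))
        add(p_iri, RDFS_LABEL, literal(patient.patient_id))
        for curie in sorted(patient.phenotypes):
            hp = phenotype_iri(curie)
            add(p_iri, iri(cfg.has_phenotype), hp)
            if hp.value in hpo.terms:
                add(hp, RDFS_LABEL, literal(hpo.terms[hp.value]))

    for obs in observations:
        v_iri = cfg.variant_iri(obs)
        add(v_iri, RDF_TYPE, iri(cfg.variant_type))
        add(v_iri, RDFS_LABEL, literal(obs.key))
        add(v_iri, iri(cfg.at_position), literal(str(obs.pos), datatype=XSD_INTEGER))
        t_iri = cfg.transcript_iri(obs.transcript)
        g_iri = cfg.gene_iri(obs.gene)
        add(v_iri, iri(cfg.has_transcript), t_iri)
        add(t_iri, RDF_TYPE, iri(cfg.transcript_type))
        add(t_iri, RDFS_LABEL, literal(obs.transcript))
        add(t_iri, iri(cfg.in_gene), g_iri)
        c_iri = cfg.consequence_iri(obs.consequence)
        add(t_iri, iri(cfg.has_consequence), c_iri)
        if c_iri.value in glossary.terms:
            add(c_iri, RDFS_LABEL, literal(glossary.terms[c_iri.value]))
        else:
            add(c_iri, RDFS_LABEL, literal(obs.consequence.replace("_", " ")))
        add(g_iri, RDF_TYPE, iri(cfg.gene_type))
        add(g_iri, RDFS_LABEL, literal(obs.gene))
        if cfg.classification_on == "variant":
            add(v_iri, iri(cfg.has_classification), literal(obs.classification))
        for carrier in sorted(obs.carriers):
            p_iri = cfg.patient_iri(carrier)
            add(p_iri, iri(cfg.has_variant), v_iri)
            if cfg.classification_on == "call":
                call = iri(cfg.base + f"call/{carrier}-{obs.key}")
                add(p_iri, iri(cfg.has_call), call)
                add(call, iri(cfg.call_of_variant), v_iri)
                add(call, iri(cfg.has_classification), literal(obs.classification))
    return kg


def attach_labels(kg: KnowledgeGraph, *fragments: OntologyFragment) -> KnowledgeGraph:
    """Add ``rdfs:label`` for every unlabeled IRI covered by a fragment.

    Returns a new graph; applying the operation twice adds nothing the
    second time (idempotence).
    """
    out = kg.copy()
    labeled = {t.subject.value for t in out.match(None, RDFS_LABEL, None) if t.subject.is_iri}
    mentioned: set[str] = set()
    for t in out.triples():
        for node in (t.subject, t.object):
            if node.is_iri:
                mentioned.add(node.value)
        mentioned.add(t.predicate.value)
    for fragment in fragments:
        for value, label in fragment.terms.items():
            if value in mentioned and value not in labeled:
                out.add(Triple(iri(value), RDFS_LABEL, literal(label)))
                labeled.add(value)
    return out
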