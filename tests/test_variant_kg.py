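"""VCF + sample-sheet conversion into the patient–variant RDF shape."""

import pytest

from varkg.rdf_core import RDF_TYPE, RDFS_LABEL, iri, lint_roles, literal, write_rdf
from varkg.synthetic_data import CohortSpec, glossary_fragment, hpo_fragment, make_cohort
from varkg.variant_kg import (
    DEFAULT_SCHEMA,
    OntologyFragment,
    PatientRecord,
    ReferentialIntegrityError,
    SampleSheetError,
    SchemaConfig,
    VariantObservation,
    attach_labels,
    build_variant_graph,
    parse_sample_sheet,
    parse_vcf,
)

VCF_2SAMPLE = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=248956422>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|SYMBOL|Feature|Consequence|VIPC">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2
1\t1000\t.\tG\tA\t.\tPASS\tCSQ=A|GENE1|ENST01|missense_variant|P\tGT\t0/1\t0/0
"""

VCF_MULTIALLELIC = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=248956422>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|SYMBOL|Feature|Consequence|VIPC">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2
1\t2000\t.\tG\tA,T\t.\tPASS\tCSQ=A|GENE1|ENST01|missense_variant|P,T|GENE1|ENST01|stop_gained|LP\tGT\t0/1\t1/2
1\t3000\t.\tC\tG\t.\tPASS\tCSQ=G|GENE2|ENST02|missense_variant|XX\tGT\t0/1\t0/0
"""


class TestSampleSheet:
    def test_semicolon_separated_hpo_row(self, tmp_path):
        sheet = tmp_path / "s.tsv"
        sheet.write_text("individual_id\thpo_ids\nP1\tHP:0000505;HP:0100704\n")
        result = parse_sample_sheet(sheet)
        assert result.records == (
            PatientRecord("P1", frozenset({"HP:0000505", "HP:0100704"})),
        )
        assert result.warnings == ()

    def test_header_only_is_empty(self, tmp_path):
        sheet = tmp_path / "s.tsv"
        sheet.write_text("individual_id\thpo_ids\n")
        assert parse_sample_sheet(sheet).records == ()

    def test_malformed_curie_goes_to_warnings(self, tmp_path):
        sheet = tmp_path / "s.tsv"
        sheet.write_text("individual_id\thpo_ids\nP1\tHP:0000505;HP_BAD\n")
        result = parse_sample_sheet(sheet)
        assert result.records[0].phenotypes == frozenset({"HP:0000505"})
        assert any("HP_BAD" in w for w in result.warnings)

    def test_missing_column_names_the_column(self, tmp_path):
        sheet = tmp_path / "s.tsv"
        sheet.write_text("individual_id\tother\nP1\tx\n")
        with pytest.raises(SampleSheetError, match="hpo_ids"):
            parse_sample_sheet(sheet)

    def test_duplicate_id_rejected(self, tmp_path):
        sheet = tmp_path / "s.tsv"
        sheet.write_text("individual_id\thpo_ids\nP1\tHP:0000505\nP1\tHP:0000505\n")
        with pytest.raises(SampleSheetError, match="duplicate"):
            parse_sample_sheet(sheet)

    def test_generated_sheet_roundtrips_ledger(self, tmp_path):
        result = make_cohort(CohortSpec(n_patients=50, n_genes=6, seed=3), tmp_path)
        parsed = parse_sample_sheet(result.sheet_path)
        assert {r.patient_id: set(r.phenotypes) for r in parsed.records} == {
            p: set(ph) for p, ph in result.ledger.phenotypes.items()
        }


class TestParseVcf:
    def test_carrier_set_follows_genotypes(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(VCF_2SAMPLE)
        (obs,) = parse_vcf(vcf).observations
        assert obs.carriers == frozenset({"P1"})
        assert (obs.gene, obs.transcript, obs.classification) == ("GENE1", "ENST01", "P")

    def test_multiallelic_split_and_bad_classification(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(VCF_MULTIALLELIC)
        result = parse_vcf(vcf)
        by_alt = {o.alt: o for o in result.observations if o.pos == 2000}
        assert set(by_alt) == {"A", "T"}
        assert by_alt["A"].carriers == frozenset({"P1", "P2"})
        assert by_alt["T"].carriers == frozenset({"P2"})
        # site 3000 has classification XX -> rejected to warnings
        assert all(o.pos != 3000 for o in result.observations)
        assert any("XX" in w for w in result.warnings)

    def test_missing_annotation_header_is_config_error(self, tmp_path):
        vcf = tmp_path / "n.vcf"
        vcf.write_text(VCF_2SAMPLE.replace("VIPC", "OTHER"))
        with pytest.raises(ValueError, match="VIPC"):
            parse_vcf(vcf)

    def test_generated_cohort_matches_ledger_counts(self, cohort):
        truth = {
            o["key"]: (set(o["carriers"]), o["classification"], o["gene"])
            for o in cohort.ledger.observations
        }
        got = {o.key: (set(o.carriers), o.classification, o.gene) for o in cohort.observations}
        assert got == truth


class TestBuildGraph:
    def test_minimal_patient_graph_shape(self):
        hpo = hpo_fragment()
        patient = PatientRecord("P1", frozenset({"HP:0000505"}))
        kg = build_variant_graph([patient], [], hpo=hpo)
        p = DEFAULT_SCHEMA.patient_iri("P1")
        hp = iri("http://purl.obolibrary.org/obo/HP_0000505")
        assert kg.match(p, RDF_TYPE, iri(DEFAULT_SCHEMA.patient_type))
        assert kg.match(p, RDFS_LABEL, literal("P1"))
        assert kg.match(p, iri(DEFAULT_SCHEMA.has_phenotype), hp)
        assert kg.match(hp, RDFS_LABEL, literal("Visual impairment"))
        # exactly: 4 class decls * 2 + patient type/label/phenotype + HP label
        assert len(kg.match(p, None, None)) == 3

    def test_shared_variant_minted_once(self):
        obs = VariantObservation("1", 500, "A", "G", "GENE1", "ENST01", "missense_variant", "P",
                                 frozenset({"P1", "P2"}))
        patients = [PatientRecord("P1", frozenset()), PatientRecord("P2", frozenset())]
        kg = build_variant_graph(patients, [obs])
        targets = {
            t.object.value
            for t in kg.match(None, iri(DEFAULT_SCHEMA.has_variant), None)
        }
        assert targets == {DEFAULT_SCHEMA.base + "variant/1-500-A-G"}

    def test_unknown_carrier_lists_ids(self):
        obs = VariantObservation("1", 500, "A", "G", "G1", "T1", "missense_variant", "P",
                                 frozenset({"P9"}))
        with pytest.raises(ReferentialIntegrityError, match="P9"):
            build_variant_graph([PatientRecord("P1", frozenset())], [obs])

    def test_output_lints_clean(self, cohort):
        assert lint_roles(cohort.kg).ok

    def test_deterministic_bytewise(self, cohort, tmp_path):
        a, b = tmp_path / "a.nt", tmp_path / "b.nt"
        write_rdf(cohort.kg, a, "ntriples")
        kg2 = build_variant_graph(
            cohort.records, cohort.observations, hpo_fragment(), glossary_fragment()
        )
        write_rdf(kg2, b, "ntriples")
        assert a.read_bytes() == b.read_bytes()

    def test_patient_variant_link_conservation(self, cohort):
        pairs = {
            (t.subject.value, t.object.value)
            for t in cohort.kg.match(None, iri(DEFAULT_SCHEMA.has_variant), None)
        }
        expected = {
            (DEFAULT_SCHEMA.patient_iri(p).value, DEFAULT_SCHEMA.base + "variant/" + o["key"])
            for o in cohort.ledger.observations
            for p in o["carriers"]
        }
        assert pairs == expected

    def test_schema_closure(self, cohort):
        allowed = set(DEFAULT_SCHEMA.predicate_iris()) | {RDF_TYPE.value, RDFS_LABEL.value}
        assert {t.predicate.value for t in cohort.kg.triples()} <= allowed

    def test_call_reification_mode(self):
        cfg = SchemaConfig(classification_on="call")
        obs = VariantObservation("1", 500, "A", "G", "G1", "T1", "missense_variant", "LP",
                                 frozenset({"P1"}))
        kg = build_variant_graph([PatientRecord("P1", frozenset())], [obs], cfg=cfg)
        calls = kg.match(None, iri(cfg.has_call), None)
        assert len(calls) == 1
        (call_t,) = calls
        assert kg.match(call_t.object, iri(cfg.has_classification), literal("LP"))


class TestAttachLabels:
    def test_adds_label_for_mentioned_iri(self):
        from varkg.rdf_core import KnowledgeGraph, Triple
        kg = KnowledgeGraph()
        cheminf = "http://semanticscience.org/resource/CHEMINF_000446"
        kg.add(Triple(iri("http://example.org/n"), iri("http://example.org/p"), iri(cheminf)))
        fragment = OntologyFragment(terms={cheminf: "has CAS Registry Number"})
        out = attach_labels(kg, fragment)
        assert out.match(iri(cheminf), RDFS_LABEL, literal("has CAS Registry Number"))

    def test_idempotent(self, cohort):
        fragment = hpo_fragment()
        once = attach_labels(cohort.kg, fragment)
        twice = attach_labels(once, fragment)
        assert once.triples() == twice.triples()

    def test_added_count_equals_unlabeled_intersection(self, cohort):
        fragment = hpo_fragment()
        labeled = {
            t.subject.value for t in cohort.kg.match(None, RDFS_LABEL, None)
        }
        mentioned = set()
        for t in cohort.kg.triples():
            for node in (t.subject, t.object):
                if node.is_iri:
                    mentioned.add(node.value)
        expected_new = {
            v for v in fragment.terms if v in mentioned and v not in labeled
        }
        out = attach_labels(cohort.kg, fragment)
        assert len(out.triples()) - len(cohort.kg.triples()) == len(expected_new)
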