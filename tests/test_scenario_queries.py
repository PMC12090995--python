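"""Clustering, closed gene–disease loops, and catalogue pattern queries."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_cohort
from oracles import enumerate_loops
from varkg.rdf_core import KnowledgeGraph, Triple, iri, literal
from varkg.scenario_queries import (
    DEFAULT_GDA_VOCAB,
    GdaVocab,
    VocabConfigError,
    class_hierarchy_roots,
    cluster_patients_by_gene,
    cluster_patients_by_phenotype,
    cohorts_by_harmonized_keyword,
    find_closed_loops,
    resources_by_topic,
)
from varkg.synthetic_data import (
    CohortSpec,
    demo_catalogue,
    make_catalogue_graph,
    make_gda_graph,
)
from varkg.variant_kg import (
    DEFAULT_SCHEMA,
    PatientRecord,
    VariantObservation,
    build_variant_graph,
)

S = DEFAULT_SCHEMA


def two_patient_one_gene_kg():
    obs = VariantObservation("1", 100, "A", "G", "GENE1", "T1", "missense_variant", "P",
                             frozenset({"P1", "P2"}))
    patients = [PatientRecord("P1", frozenset({"HP:0000505"})),
                PatientRecord("P2", frozenset({"HP:0000505"}))]
    return build_variant_graph(patients, [obs])


class TestGeneClusters:
    def test_shared_gene_cluster_of_two(self):
        (cluster,) = cluster_patients_by_gene(two_patient_one_gene_kg(), min_patients=2)
        assert cluster.key == S.gene_iri("GENE1").value
        assert cluster.members == {S.patient_iri("P1").value, S.patient_iri("P2").value}

    def test_threshold_excludes(self):
        assert cluster_patients_by_gene(two_patient_one_gene_kg(), min_patients=3) == ()

    def test_planted_clusters_recovered(self, cohort):
        clusters = cluster_patients_by_gene(cohort.kg, min_patients=2, classifications={"P", "LP"})
        got = {c.key: set(c.members) for c in clusters}
        expected = {
            S.gene_iri(g).value: {S.patient_iri(p).value for p in members}
            for g, members in cohort.ledger.clusters_by_gene.items()
            if len(members) >= 2
        }
        assert got == expected

    def test_monotone_in_threshold(self, cohort):
        prev = {c.key: c.members for c in cluster_patients_by_gene(cohort.kg, 2)}
        for m in (3, 4, 5):
            cur = {c.key: c.members for c in cluster_patients_by_gene(cohort.kg, m)}
            assert set(cur) <= set(prev)
            for key, members in cur.items():
                assert members == prev[key]
            prev = cur


class TestPhenotypeClusters:
    def test_cohort_filter_phenotype_holds_everyone(self, cohort):
        clusters = cluster_patients_by_phenotype(cohort.kg, min_patients=2)
        by_key = {c.key: c for c in clusters}
        visual = "http://purl.obolibrary.org/obo/HP_0000505"
        assert visual in by_key
        assert len(by_key[visual].members) == len(cohort.records)
        assert by_key[visual].label == "Visual impairment"

    def test_singleton_phenotype_excluded(self):
        patients = [PatientRecord("P1", frozenset({"HP:0000505", "HP:0001250"})),
                    PatientRecord("P2", frozenset({"HP:0000505"}))]
        kg = build_variant_graph(patients, [])
        keys = {c.key for c in cluster_patients_by_phenotype(kg, min_patients=2)}
        assert keys == {"http://purl.obolibrary.org/obo/HP_0000505"}

    def test_matches_ledger_grouping(self, cohort):
        expected: dict[str, set[str]] = {}
        for patient, phenos in cohort.ledger.phenotypes.items():
            for curie in phenos:
                hp = "http://purl.obolibrary.org/obo/HP_" + curie.split(":")[1]
                expected.setdefault(hp, set()).add(S.patient_iri(patient).value)
        expected = {k: v for k, v in expected.items() if len(v) >= 2}
        got = {c.key: set(c.members) for c in cluster_patients_by_phenotype(cohort.kg, 2)}
        assert got == expected

    def test_grouping_conserves_incidences(self, cohort):
        clusters = cluster_patients_by_phenotype(cohort.kg, min_patients=1)
        incidences = len(cohort.kg.match(None, iri(S.has_phenotype), None))
        assert sum(len(c) for c in clusters) == incidences  # no patient repeats a key


class TestClosedLoops:
    def _minimal(self):
        kg = two_patient_one_gene_kg()
        gda = KnowledgeGraph()
        v = DEFAULT_GDA_VOCAB
        disease = iri("http://example.org/disease/1")
        node = iri("http://example.org/gda/1")
        gda.add(Triple(disease, iri(v.disease_phenotype), iri("http://purl.obolibrary.org/obo/HP_0000505")))
        gda.add(Triple(node, iri(v.gda_disease), disease))
        gda.add(Triple(node, iri(v.gda_gene), S.gene_iri("GENE1")))
        return kg, gda, node

    def test_minimal_closable_loop(self):
        kg, gda, node = self._minimal()
        loops = find_closed_loops(kg, gda)
        # two patients carry the variant and share the phenotype -> two loops
        assert {l.patient for l in loops} == {S.patient_iri("P1").value, S.patient_iri("P2").value}
        assert all(l.gda == node.value for l in loops)

    def test_unclosable_without_gene_edge(self):
        kg, gda, node = self._minimal()
        v = DEFAULT_GDA_VOCAB
        for t in list(gda.match(node, iri(v.gda_gene), None)):
            gda.discard(t)
        assert find_closed_loops(kg, gda) == frozenset()

    def test_missing_vocab_slot_named(self):
        kg, gda, _ = self._minimal()
        with pytest.raises(VocabConfigError, match="gda_gene"):
            find_closed_loops(kg, gda, GdaVocab(gda_gene=""))

    @pytest.mark.parametrize("fraction", [0.0, 0.3, 1.0])
    def test_equals_bruteforce_enumeration(self, cohort, fraction):
        gda, ledger = make_gda_graph(cohort.ledger, n_candidates=40, loop_fraction=fraction, seed=11)
        loops = find_closed_loops(cohort.kg, gda)
        got = {l.nodes() for l in loops}
        assert got == enumerate_loops(cohort.kg, gda, DEFAULT_GDA_VOCAB)
        assert sorted(map(list, got)) == ledger.expected_loops
        if fraction == 0.0:
            assert loops == frozenset()

    def test_evidence_attached_where_present(self, cohort):
        gda, _ = make_gda_graph(cohort.ledger, n_candidates=30, loop_fraction=0.5,
                                evidence_fraction=1.0, seed=2)
        loops = find_closed_loops(cohort.kg, gda)
        assert loops and all(l.evidence for l in loops)

    def test_edge_knockout_removes_exactly_through_loops(self, cohort):
        v = DEFAULT_GDA_VOCAB
        gda, _ = make_gda_graph(cohort.ledger, n_candidates=30, loop_fraction=0.5, seed=13)
        base_loops = find_closed_loops(cohort.kg, gda)
        edges = sorted(gda.match(None, iri(v.gda_disease), None), key=lambda t: t.sort_key())
        for edge in edges[:5]:
            cut = gda.copy()
            cut.discard(edge)
            remaining = find_closed_loops(cohort.kg, cut)
            removed = base_loops - remaining
            assert remaining <= base_loops
            assert all(l.gda == edge.subject.value and l.disease == edge.object.value for l in removed)
            assert removed == {
                l for l in base_loops if l.gda == edge.subject.value and l.disease == edge.object.value
            }


class TestCatalogue:
    def test_hierarchy_roots_with_optional_labels(self):
        kg, _ = demo_catalogue()
        roots = dict(class_hierarchy_roots(kg))
        assert "Areas of information" in roots.values()
        # a root without a label is still returned
        from varkg.rdf_core import OWL_THING, RDFS_SUBCLASSOF
        kg.add(Triple(iri("http://example.org/Unlabeled"), RDFS_SUBCLASSOF, OWL_THING))
        roots = dict(class_hierarchy_roots(kg))
        assert roots["http://example.org/Unlabeled"] is None

    def test_non_root_class_excluded(self):
        kg, _ = demo_catalogue()
        roots = {r for r, _ in class_hierarchy_roots(kg)}
        assert "https://w3id.org/varkg/catalogue/topic/Tobacco" not in roots

    def test_tobacco_resources(self):
        kg, ledger = demo_catalogue()
        hits = resources_by_topic(kg, "Tobacco")
        assert sorted(hits) == ledger.topic_map["Tobacco"]
        assert {h.rsplit("/", 1)[1] for h in hits} == {"DNBC", "PSYCONN"}

    def test_unknown_topic_empty(self):
        kg, _ = demo_catalogue()
        assert resources_by_topic(kg, "Astrology") == frozenset()

    def test_blood_pressure_cohorts(self):
        kg, ledger = demo_catalogue()
        cohorts = cohorts_by_harmonized_keyword(kg, "blood pressure")
        assert list(cohorts) == ledger.keyword_map["blood pressure"]
        assert {c.rsplit("/", 1)[1] for c in cohorts} == {"G21", "ENVIRONAGE", "GENR"}

    def test_unknown_keyword_empty(self):
        kg, _ = demo_catalogue()
        assert cohorts_by_harmonized_keyword(kg, "shoe size") == ()

    @pytest.mark.parametrize("seed", [0, 3])
    def test_planted_maps_recovered(self, seed):
        kg, ledger = make_catalogue_graph(n_cohorts=8, seed=seed,
                                          keyword_maps={"blood pressure": 3, "smoking": 2})
        for topic, cohorts in ledger.topic_map.items():
            assert sorted(resources_by_topic(kg, topic)) == sorted(cohorts)
        for keyword, cohorts in ledger.keyword_map.items():
            assert list(cohorts_by_harmonized_keyword(kg, keyword)) == sorted(cohorts)


@given(st.integers(min_value=0, max_value=100))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_loops_match_oracle_across_seeds(seed):
    """Property: indexed loop join equals brute-force on arbitrary seeds."""
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        bundle = build_cohort(
            __import__("pathlib").Path(d), CohortSpec(n_patients=8, n_genes=3, seed=seed)
        )
    gda, _ = make_gda_graph(bundle.ledger, n_candidates=15, loop_fraction=0.4, seed=seed)
    loops = {l.nodes() for l in find_closed_loops(bundle.kg, gda)}
    assert loops == enumerate_loops(bundle.kg, gda, DEFAULT_GDA_VOCAB)
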