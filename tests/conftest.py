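import sys
from dataclasses import dataclass
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from varkg.rdf_core import KnowledgeGraph
from varkg.synthetic_data import (
    CohortSpec,
    TruthLedger,
    glossary_fragment,
    hpo_fragment,
    make_cohort,
)
from varkg.variant_kg import (
    build_variant_graph,
    parse_sample_sheet,
    parse_vcf,
)


@dataclass
class CohortBundle:
    """A generated cohort run through the full parse→build pipeline."""

    records: tuple
    observations: tuple
    kg: KnowledgeGraph
    ledger: TruthLedger
    vcf_path: Path
    sheet_path: Path


def build_cohort(tmp_dir: Path, spec: CohortSpec) -> CohortBundle:
    result = make_cohort(spec, tmp_dir)
    sheet = parse_sample_sheet(result.sheet_path)
    vcf = parse_vcf(result.vcf_path)
    kg = build_variant_graph(
        sheet.records, vcf.observations, hpo_fragment(), glossary_fragment()
    )
    return CohortBundle(
        records=sheet.records,
        observations=vcf.observations,
        kg=kg,
        ledger=result.ledger,
        vcf_path=result.vcf_path,
        sheet_path=result.sheet_path,
    )


@pytest.fixture(scope="session")
def cohort(tmp_path_factory) -> CohortBundle:
    """Default 20-patient cohort with 5 planted gene clusters (seed 7)."""
    return build_cohort(
        tmp_path_factory.mktemp("cohort"), CohortSpec(n_patients=20, n_genes=5, seed=7)
    )
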