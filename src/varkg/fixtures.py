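"""Accessors for the small Turtle fixtures shipped inside the package.

All shipped fixtures are synthetic: the drug trio embeds the aspirin worked
example (DB00945 / ATC B01AC06 / CAS 50-78-2) plus decoys, and the HPO
subset carries ~30 terms with real-style identifiers.  They are regenerated
deterministically by :mod:`varkg.synthetic_data` (seed 0); the files exist so
command-line users have ready inputs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .rdf_core import KnowledgeGraph, read_rdf
from .variant_kg import OntologyFragment

_FILES = {
    "drugbank": "drugbank_synthetic.ttl",
    "atc": "atc_synthetic.ttl",
    "pubchem": "pubchem_synthetic.ttl",
    "hpo": "hpo_subset_synthetic.ttl",
    "glossary": "glossary_synthetic.ttl",
}


def fixture_path(name: str) -> Path:
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}")
    return Path(str(resources.files("varkg").joinpath("data", _FILES[name])))


def load_fixture(name: str) -> KnowledgeGraph:
    return read_rdf(fixture_path(name))


def aspirin_fixture() -> tuple[KnowledgeGraph, KnowledgeGraph, KnowledgeGraph]:
    """The packaged (drugbank, atc, pubchem) trio around aspirin DB00945."""
    return load_fixture("drugbank"), load_fixture("atc"), load_fixture("pubchem")


def hpo_fixture_fragment() -> OntologyFragment:
    return OntologyFragment.from_rdf(fixture_path("hpo"))


def glossary_fixture_fragment() -> OntologyFragment:
    return OntologyFragment.from_rdf(fixture_path("glossary"))
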