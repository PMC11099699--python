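"""Shared fixtures: a tiny hand-drawn ontology and small annotation corpora."""

from __future__ import annotations

import io
import textwrap

import pytest

from domap.annotation_io import AnnotationCorpus
from domap.ontology_io import parse_obo
from domap.synthetic_data import SyntheticConfig, generate

# 12 terms over 3 namespaces with mixed is_a/part_of, including a diamond
# (GO:0000004 -> {GO:0000002, GO:0000003} -> GO:0000001) and an alt_id.
FIXTURE_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: fixture

    [Term]
    id: GO:0000001
    name: mf root
    namespace: molecular_function

    [Term]
    id: GO:0000002
    name: binding
    namespace: molecular_function
    is_a: GO:0000001

    [Term]
    id: GO:0000003
    name: catalysis
    namespace: molecular_function
    is_a: GO:0000001

    [Term]
    id: GO:0000004
    name: atp binding hydrolase
    namespace: molecular_function
    alt_id: GO:0000014
    is_a: GO:0000002
    relationship: part_of GO:0000003

    [Term]
    id: GO:0000005
    name: kinase
    namespace: molecular_function
    is_a: GO:0000003

    [Term]
    id: GO:0000006
    name: bp root
    namespace: biological_process

    [Term]
    id: GO:0000007
    name: metabolism
    namespace: biological_process
    is_a: GO:0000006

    [Term]
    id: GO:0000008
    name: glycolysis
    namespace: biological_process
    is_a: GO:0000007

    [Term]
    id: GO:0000009
    name: regulation of glycolysis
    namespace: biological_process
    relationship: part_of GO:0000008

    [Term]
    id: GO:0000010
    name: cc root
    namespace: cellular_component

    [Term]
    id: GO:0000011
    name: membrane
    namespace: cellular_component
    is_a: GO:0000010

    [Term]
    id: GO:0000012
    name: obsolete organelle
    namespace: cellular_component
    is_obsolete: true
    """
)

# hand-drawn ancestor closure of the fixture (is_a + part_of)
FIXTURE_CLOSURE = {
    "GO:0000001": set(),
    "GO:0000002": {"GO:0000001"},
    "GO:0000003": {"GO:0000001"},
    "GO:0000004": {"GO:0000002", "GO:0000003", "GO:0000001"},
    "GO:0000005": {"GO:0000003", "GO:0000001"},
    "GO:0000006": set(),
    "GO:0000007": {"GO:0000006"},
    "GO:0000008": {"GO:0000007", "GO:0000006"},
    "GO:0000009": {"GO:0000008", "GO:0000007", "GO:0000006"},
    "GO:0000010": set(),
    "GO:0000011": {"GO:0000010"},
}


@pytest.fixture(scope="session")
def fixture_dag():
    return parse_obo(io.StringIO(FIXTURE_OBO))


@pytest.fixture()
def small_corpus(fixture_dag):
    """Five proteins, propagated annotations, shared key space."""
    from domap.annotation_io import build_corpus

    protein_domains = {
        "P1": {"d1"},
        "P2": {"d1", "d2"},
        "P3": {"d2"},
        "P4": {"d1"},
        "P5": {"d3"},
    }
    protein_go = {
        "P1": {"GO:0000004"},
        "P2": {"GO:0000004", "GO:0000008"},
        "P3": {"GO:0000008"},
        "P4": {"GO:0000005"},
        "P5": {"GO:0000011"},
    }
    return build_corpus(protein_domains, protein_go, fixture_dag)


@pytest.fixture(scope="session")
def synthetic_truth():
    """Default-condition synthetic corpus, shared across tests (seed 1)."""
    return generate(SyntheticConfig(seed=1))


def brute_force_ancestors(obo_text: str, term: str) -> set:
    """Independent closure oracle: exhaustive path enumeration on raw stanzas."""
    parents = {}
    current = None
    for line in obo_text.splitlines():
        line = line.strip()
        if line == "[Term]":
            current = None
        elif line.startswith("id: "):
            current = line[4:]
            parents.setdefault(current, set())
        elif line.startswith("is_a: ") and current:
            parents[current].add(line[6:].split(" ")[0].split("!")[0].strip())
        elif line.startswith("relationship: part_of ") and current:
            parents[current].add(line.split()[2])
        elif line.startswith("is_obsolete: true") and current:
            parents.pop(current, None)
            current = None
    out, frontier = set(), {term}
    while frontier:
        nxt = set()
        for t in frontier:
            for p in parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    nxt.add(p)
        frontier = nxt
    return out
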