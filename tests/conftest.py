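"""Shared fixtures: tiny hand-written ontologies, networks and stores."""

import textwrap

import pytest

from gpsim.gene_network import GeneNetwork
from gpsim.ontology import OntologyGraph, Term, load_obo


def obo_text(stanzas, header="format-version: 1.2\nontology: test\n"):
    """Assemble an OBO 1.2 document from term dicts."""
    parts = [header]
    for s in stanzas:
        lines = ["[Term]", f"id: {s['id']}"]
        if "name" in s:
            lines.append(f"name: {s['name']}")
        for syn in s.get("synonyms", ()):
            lines.append(f'synonym: "{syn}" EXACT []')
        for x in s.get("xrefs", ()):
            lines.append(f"xref: {x}")
        for a in s.get("alt_ids", ()):
            lines.append(f"alt_id: {a}")
        for p in s.get("is_a", ()):
            lines.append(f"is_a: {p}")
        if s.get("obsolete"):
            lines.append("is_obsolete: true")
        parts.append("\n".join(lines))
    return "\n\n".join(parts) + "\n"


def write_obo(path, stanzas):
    path.write_text(obo_text(stanzas))
    return path


def graph_from_terms(term_specs, **kwargs):
    """Build an OntologyGraph directly from (id, parents) pairs."""
    terms = {
        tid: Term(id=tid, name=tid, parents=frozenset(parents))
        for tid, parents in term_specs.items()
    }
    return OntologyGraph(terms, **kwargs)


@pytest.fixture
def do_obo_path(tmp_path):
    """A 7-term DO snippet with 1 obsolete term, synonyms, xrefs, alt ids."""
    stanzas = [
        {"id": "DOID:0000001", "name": "disease"},
        {"id": "DOID:0000002", "name": "disease of anatomical entity", "is_a": ["DOID:0000001"]},
        {
            "id": "DOID:10652",
            "name": "Alzheimer's disease",
            "synonyms": ["Alzheimer disease"],
            "xrefs": ["OMIM:104300"],
            "alt_ids": ["DOID:24817"],
            "is_a": ["DOID:0000002"],
        },
        {"id": "DOID:5419", "name": "schizophrenia", "xrefs": ["OMIM:181500"], "is_a": ["DOID:0000002"]},
        {"id": "DOID:1234", "name": "amnesia", "is_a": ["DOID:0000002"]},
        {"id": "DOID:11165", "name": "common wart", "is_a": ["DOID:0000001"]},
        {"id": "DOID:9999", "name": "retired disease", "obsolete": True},
    ]
    return write_obo(tmp_path / "do.obo", stanzas)


@pytest.fixture
def do_graph(do_obo_path):
    return load_obo(do_obo_path)


@pytest.fixture
def diamond_graph():
    """root -> {a, b} -> c, plus a deeper limb under a for IC asymmetry.

    Edges: a and b are children of root; c has parents a and b; d is a
    child of a.
    """
    return graph_from_terms(
        {
            "T:root": [],
            "T:a": ["T:root"],
            "T:b": ["T:root"],
            "T:c": ["T:a", "T:b"],
            "T:d": ["T:a"],
        }
    )


@pytest.fixture
def hpo_graph():
    """Small HPO-like chain with siblings for depth filtering tests.

    Depths: root 0, n1 1, n2 2, n3 3, n4 4, n5 5; s1 sibling at depth 1.
    """
    return graph_from_terms(
        {
            "HP:0000001": [],
            "HP:0000010": ["HP:0000001"],
            "HP:0000020": ["HP:0000010"],
            "HP:0000030": ["HP:0000020"],
            "HP:0000040": ["HP:0000030"],
            "HP:0000050": ["HP:0000040"],
            "HP:0000099": ["HP:0000001"],
        }
    )


@pytest.fixture
def tiny_net():
    """Network with raw LLS {1.0, 2.0, 4.0} so LLSN(a, b) = 1/3."""
    return GeneNetwork.from_edges(
        [("x", "y", 1.0), ("x", "z", 4.0), ("a", "b", 2.0)]
    )


@pytest.fixture
def unit_net():
    """Network whose normalized weights equal handy round numbers.

    Anchor edges pin lls_min = 0 and lls_max = 1 so each remaining edge's
    LLSN equals its raw score.
    """
    return GeneNetwork.from_edges(
        [
            ("anchor0", "anchorA", 0.0),
            ("anchor1", "anchorB", 1.0),
            ("a", "b", 0.6),
            ("a", "c", 0.2),
            ("b", "c", 0.7),
            ("a", "d", 0.4),
        ]
    )
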