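"""Loading, imports merging and annotation extraction."""

import json
import os

import pytest

from obakit import fixtures as fx
from obakit.model import (
    AnnotationAssertion,
    IAO_DEFINITION,
    RDFS_LABEL,
    SubClassOf,
    class_axioms,
)
from obakit.ontology_store import (
    LoadError,
    Repository,
    load_ontology,
    load_ontology_text,
)

MINIMAL = """
Prefix(:=<http://example.org/min#>)
Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
Ontology(<http://example.org/min>
SubClassOf(:A :B)
AnnotationAssertion(rdfs:label :A "ventricular septal defect")
)
"""


def test_minimal_document_counts():
    doc = load_ontology_text(MINIMAL)
    assert doc.classes == {"http://example.org/min#A", "http://example.org/min#B"}
    assert len(class_axioms(doc.axioms)) == 1
    assert doc.labels["http://example.org/min#A"] == "ventricular septal defect"
    # fallback label for the unannotated class
    assert doc.labels["http://example.org/min#B"] == "B"
    assert doc.definitions == {}


def test_non_el_axiom_dropped_with_rest_loaded(caplog):
    text = MINIMAL.replace(
        "SubClassOf(:A :B)",
        "SubClassOf(:A :B)\nSubClassOf(:C ObjectAllValuesFrom(:r :B))\nDisjointClasses(:A :B)",
    )
    with caplog.at_level("WARNING"):
        doc = load_ontology_text(text)
    assert doc.dropped_axiom_count == 2
    assert len(class_axioms(doc.axioms)) == 1
    assert "EL subset" in caplog.text
    # dropped + kept = parsed
    from obakit import ofn

    parsed = ofn.parse_ofn(text)
    assert parsed.dropped_axiom_count + len(class_axioms(parsed.axioms)) == parsed.parsed_axiom_count


def test_import_merging_equals_union(tmp_path):
    root_path, catalog = fx.make_import_demo(str(tmp_path))
    merged = load_ontology(root_path, catalog)
    alone = load_ontology(root_path, {})  # import unresolvable -> skipped
    child = load_ontology(list(catalog.values())[0])
    assert merged.classes == alone.classes | child.classes
    assert set(merged.axioms) == set(alone.axioms) | set(child.axioms)
    assert set(merged.labels) == set(alone.labels) | set(child.labels)
    extra = fx.OBO + "UBERON_0001234"
    assert merged.labels[extra] == "cardiac valve"


def test_loading_is_idempotent(tmp_path):
    path = os.path.join(os.path.dirname(__file__), "data", "cardio.ofn")
    one = load_ontology(path)
    two = load_ontology(path)
    assert one.axioms == two.axioms
    assert one.classes == two.classes
    assert one.labels == two.labels


def test_syntax_error_raises_load_error(tmp_path):
    bad = tmp_path / "bad.ofn"
    bad.write_text("Ontology(<u> SubClassOf(:A")
    with pytest.raises(LoadError):
        load_ontology(str(bad))
    with pytest.raises(LoadError):
        load_ontology(str(tmp_path / "missing.ofn"))


def test_duplicate_labels_first_wins(caplog):
    text = MINIMAL.replace(
        'AnnotationAssertion(rdfs:label :A "ventricular septal defect")',
        'AnnotationAssertion(rdfs:label :A "first label")\n'
        'AnnotationAssertion(rdfs:label :A "second label")',
    )
    with caplog.at_level("WARNING"):
        doc = load_ontology_text(text)
    assert doc.labels["http://example.org/min#A"] == "first label"
    assert "multiple rdfs:label" in caplog.text


def test_definition_is_byte_exact():
    text = MINIMAL.replace(
        ")\n",
        'AnnotationAssertion(<http://purl.obolibrary.org/obo/IAO_0000115> :A "A hole in the septum.")\n)\n',
        1,
    )
    # splice before final close paren instead
    text = MINIMAL[: MINIMAL.rstrip().rfind(")")] + (
        'AnnotationAssertion(<http://purl.obolibrary.org/obo/IAO_0000115> :A "A hole in the septum.")\n)\n'
    )
    doc = load_ontology_text(text)
    assert doc.definitions["http://example.org/min#A"] == "A hole in the septum."


def test_repository_get_semantics(repo, cardio_doc):
    assert len(repo.get()) == 2
    assert repo.get(cardio_doc.document_uri) == [cardio_doc]
    assert repo.get("file:///nonexistent/path.ofn") == []


def test_repository_from_config(tmp_path):
    fx.make_cardio_ontology(str(tmp_path / "cardio.ofn"))
    config = tmp_path / "config.json"
    config.write_text(json.dumps({"sources": ["cardio.ofn"], "catalog": {}}))
    repo = Repository.from_config(str(config))
    assert [d.document_uri for d in repo.get()] == [fx.CARDIO_URI]


def test_labels_and_definitions_restricted_to_known_entities():
    text = MINIMAL[: MINIMAL.rstrip().rfind(")")] + (
        'AnnotationAssertion(rdfs:label <http://example.org/elsewhere#Z> "stray")\n)\n'
    )
    doc = load_ontology_text(text)
    assert "http://example.org/elsewhere#Z" not in doc.labels
    assert set(doc.labels) <= doc.classes | doc.properties
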