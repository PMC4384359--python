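"""Normalization, saturation, classification and expression queries."""

import pytest

from obakit import fixtures as fx
from obakit.el_reasoner import (
    Taxonomy,
    classify,
    is_fresh,
    normalize,
    query_expression,
    saturate,
)
from obakit.model import (
    Bottom,
    EquivalentClasses,
    Existential,
    NamedClass,
    OntologyDocument,
    OWL_NOTHING,
    OWL_THING,
    SubClassOf,
    TransitiveProperty,
    conj,
)
from obakit.naive_reasoner import entailed_subsumptions

EX = "http://example.org/t#"
A, B, C, D = (NamedClass(EX + x) for x in "ABCD")
R = EX + "r"


def doc_of(axioms, classes, properties=()):
    return OntologyDocument(
        document_uri="urn:test",
        axioms=list(axioms),
        classes={EX + c for c in classes},
        properties={EX + p for p in properties},
    )


def test_normalize_simple_subclass_has_no_fresh_names():
    n = normalize([SubClassOf(A, B)])
    assert n.nf1 == {(A.iri, B.iri)}
    assert not n.fresh and not n.nf2 and not n.nf3 and not n.nf4


def test_normalize_transitivity_is_a_chain():
    n = normalize([TransitiveProperty(R)])
    assert n.chains == {(R, R, R)}


def test_normalize_equivalence_preserves_consequences():
    # defining ToF-style equivalence both ways must entail membership of the
    # conjunction operands
    defined = EquivalentClasses((A, conj(B, C, D)))
    sat = saturate(normalize([defined]))
    assert sat.holds(A.iri, B.iri)
    assert sat.holds(A.iri, C.iri)
    # and the converse direction: B ⊓ C ⊓ D ⊑ A via an auxiliary member
    sat2 = saturate(
        normalize([defined, SubClassOf(NamedClass(EX + "X"), conj(B, C, D))])
    )
    assert sat2.holds(EX + "X", A.iri)


def test_saturate_transitive_subsumption():
    sat = saturate(normalize([SubClassOf(A, B), SubClassOf(B, C)]))
    assert sat.holds(A.iri, C.iri)


def test_saturate_role_transitivity_through_chain():
    part_of = R
    axioms = [
        SubClassOf(A, Existential(part_of, B)),
        SubClassOf(B, Existential(part_of, C)),
        TransitiveProperty(part_of),
        SubClassOf(Existential(part_of, C), D),
    ]
    sat = saturate(normalize(axioms))
    assert sat.holds(A.iri, D.iri)


def test_bottom_conjunction_yields_unsatisfiable():
    axioms = [SubClassOf(A, B), SubClassOf(A, C), SubClassOf(conj(B, C), Bottom)]
    sat = saturate(normalize(axioms))
    assert sat.unsatisfiable(A.iri)
    assert not sat.unsatisfiable(B.iri)


def test_classify_empty_ontology_is_flat():
    doc = doc_of([], "AB")
    taxonomy = classify(doc)
    assert taxonomy.subsumption_pairs() == set()
    assert taxonomy.equivalents_of(EX + "A") == {EX + "A"}
    assert not taxonomy.unsatisfiable


def test_classify_cardio_infers_tof_under_vsd(cardio_doc):
    taxonomy = classify(cardio_doc)
    assert taxonomy.subsumes(fx.HP["vsd"], fx.HP["tof"])
    # ... although no such subclass axiom is asserted
    asserted = {
        (ax.sub, ax.sup)
        for ax in cardio_doc.axioms
        if isinstance(ax, SubClassOf)
    }
    assert (NamedClass(fx.HP["tof"]), NamedClass(fx.HP["vsd"])) not in asserted


def test_taxonomy_direct_sub_has_no_redundant_edge(cardio_doc):
    taxonomy = classify(cardio_doc)
    # ToF-subtype is a direct subclass of ToF, not of 'ventricular septal
    # defect' (ToF lies in between)
    assert fx.HP["tof_subtype"] in taxonomy.direct_sub[fx.HP["tof"]]
    assert fx.HP["tof_subtype"] not in taxonomy.direct_sub[fx.HP["vsd"]]


def test_monotonicity_adding_axioms_never_removes_entailments(cardio_doc):
    base = classify(cardio_doc).subsumption_pairs()
    extended = OntologyDocument(
        document_uri="urn:ext",
        axioms=list(cardio_doc.axioms)
        + [SubClassOf(NamedClass(fx.UBERON["aorta"]), NamedClass(fx.HP["abn_heart"]))],
        classes=set(cardio_doc.classes),
        properties=set(cardio_doc.properties),
    )
    assert classify(extended).subsumption_pairs() >= base


def test_query_four_conjunct_returns_exactly_tof_and_subtype(cardio_doc):
    expr = conj(
        NamedClass(fx.HP["overriding_aorta"]),
        NamedClass(fx.HP["vsd"]),
        NamedClass(fx.HP["pulmonic_stenosis"]),
        NamedClass(fx.HP["rvh"]),
    )
    answers = query_expression(cardio_doc, expr, "subclass")
    assert answers == {fx.HP["tof"], fx.HP["tof_subtype"]}


def test_query_superclass_and_equivalent(cardio_doc):
    tof = NamedClass(fx.HP["tof"])
    supers = query_expression(cardio_doc, tof, "superclass")
    assert fx.HP["vsd"] in supers and fx.HP["abn_heart"] in supers
    assert OWL_THING not in supers
    equiv = query_expression(cardio_doc, NamedClass(fx.HP["vsd"]), "equivalent")
    assert equiv == {fx.HP["vsd"]}  # self-equivalence only


def test_query_direct_only_restricts_to_most_general(cardio_doc):
    answers = query_expression(
        cardio_doc, NamedClass(fx.HP["vsd"]), "subclass", direct_only=True
    )
    # direct layer below VSD: VSD itself (reflexive answer), then muscular
    # VSD and ToF; the ToF subtype is not direct
    assert fx.HP["tof_subtype"] not in answers
    assert fx.HP["tof"] in answers and fx.HP["muscular_vsd"] in answers


def test_query_unknown_iri_yields_empty(cardio_doc):
    answers = query_expression(cardio_doc, NamedClass(EX + "Nope"), "subclass")
    assert answers == set()


def test_query_matches_taxonomy_subclass_set(go_doc):
    taxonomy = classify(go_doc)
    for iri in sorted(go_doc.classes):
        answers = query_expression(go_doc, NamedClass(iri), "subclass")
        expected = {
            c for c in go_doc.classes if taxonomy.subsumes(iri, c)
        } - set(taxonomy.unsatisfiable)
        assert answers == expected


def test_unsatisfiable_class_excluded_from_answers():
    axioms = [
        SubClassOf(A, B),
        SubClassOf(A, C),
        SubClassOf(conj(B, C), Bottom),
        SubClassOf(D, B),
    ]
    doc = doc_of(axioms, "ABCD")
    taxonomy = classify(doc)
    assert taxonomy.unsatisfiable == {A.iri}
    for qtype in ("subclass", "superclass", "equivalent"):
        assert A.iri not in query_expression(doc, B, qtype)
    assert query_expression(doc, B, "subclass") == {B.iri, D.iri}


def test_fresh_names_never_leak(cardio_doc):
    taxonomy = classify(cardio_doc)
    everything = set(taxonomy.classes) | set(taxonomy.unsatisfiable)
    for sub, sups in taxonomy.subsumers.items():
        everything.add(sub)
        everything.update(sups)
    everything.update(query_expression(cardio_doc, NamedClass(fx.HP["vsd"]), "subclass"))
    assert not any(is_fresh(iri) for iri in everything)


def test_taxonomy_json_roundtrip(cardio_doc):
    import json

    payload = json.loads(classify(cardio_doc).to_json())
    assert set(payload) == {"direct_sub", "equivalents", "unsatisfiable"}
    assert payload["unsatisfiable"] == []
    assert fx.HP["tof_subtype"] in payload["direct_sub"][fx.HP["tof"]]


@pytest.mark.parametrize("seed", range(25))
def test_random_ontologies_match_naive_oracle(seed):
    """Completion-rule saturation equals the naive fixpoint oracle."""
    doc = fx.random_el_ontology(fx.GeneratorConfig(seed=1000 + seed))
    taxonomy = classify(doc)
    pairs, unsat = entailed_subsumptions(doc.axioms, doc.classes)
    assert taxonomy.subsumption_pairs() == pairs
    assert set(taxonomy.unsatisfiable) == unsat


def test_asserted_subclass_always_entailed():
    doc = fx.random_el_ontology(fx.GeneratorConfig(seed=5))
    taxonomy = classify(doc)
    for ax in doc.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, NamedClass) and isinstance(ax.sup, NamedClass):
            assert taxonomy.subsumes(ax.sup.iri, ax.sub.iri)
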