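"""Extended-SPARQL parsing, expansion, CURIE rewriting and form equivalence."""

import pytest

from obakit import fixtures as fx
from obakit.sparql_expansion import (
    PrefixMap,
    SparqlExtensionError,
    execute,
    expand,
    parse_extended,
    parse_sparql,
    to_curie,
)

VALUES_QUERY = """PREFIX core: <http://example.org/core/>
SELECT ?protein WHERE {
  ?protein a core:Protein .
  ?protein core:classifiedWith ?ontid .
  VALUES ?ontid OWL subclass FROM <http://example.org/ontologies/go-fragment.owl> { part_of some 'apoptotic process' }
}"""

FILTER_QUERY = """PREFIX core: <http://example.org/core/>
SELECT ?protein WHERE {
  ?protein a core:Protein .
  ?protein core:classifiedWith ?ontid .
  FILTER(?ontid IN (OWL subclass FROM <http://example.org/ontologies/go-fragment.owl> { part_of some 'apoptotic process' }))
}"""


def test_parse_extended_values_form():
    _tpl, blocks = parse_extended(VALUES_QUERY)
    assert len(blocks) == 1
    block = blocks[0]
    assert block.form == "values"
    assert block.var == "?ontid"
    assert block.qtype == "subclass"
    assert block.ontology_uri == fx.GO_URI
    assert block.expression_text == "part_of some 'apoptotic process'"


def test_parse_extended_filter_form():
    _tpl, blocks = parse_extended(FILTER_QUERY)
    assert len(blocks) == 1 and blocks[0].form == "filter"


def test_plain_sparql_passes_through(repo):
    plain = "SELECT ?s WHERE { ?s ?p ?o }"
    assert parse_extended(plain) == (plain, [])
    assert expand(plain, repo) == plain  # byte-identical no-op


def test_macro_in_unsupported_position_is_an_error():
    bad = "SELECT ?s WHERE { ?s ?p OWL { regulation } }"
    with pytest.raises(SparqlExtensionError) as err:
        parse_extended(bad)
    assert "line 1" in str(err.value)


def test_expand_values_full_iris(repo):
    out = expand(VALUES_QUERY, repo)
    for iri in fx.GO_PART_OF_APOPTOSIS:
        assert f"<{iri}>" in out
    assert "OWL" not in out.replace("owl", "")
    parse_sparql(out)  # valid SPARQL 1.1


def test_expand_rewrites_curies_and_prepends_prefix(repo):
    out = expand(VALUES_QUERY, repo, PrefixMap(rewrite_enabled=True))
    assert out.startswith("PREFIX GO: <http://purl.obolibrary.org/obo/GO_>")
    assert "GO:0006919" in out and "<http://purl.obolibrary.org/obo/GO_0006919>" not in out
    parse_sparql(out)


def test_user_prefix_declaration_wins(repo):
    query = "PREFIX GO: <http://purl.uniprot.org/go/>\n" + VALUES_QUERY
    out = expand(query, repo, PrefixMap(rewrite_enabled=True))
    # no second declaration prepended; emitted CURIEs now resolve to UniProt
    assert out.count("PREFIX GO:") == 1
    assert "purl.uniprot.org" in out.splitlines()[0]


def test_empty_answers_values_and_filter(repo):
    empty_values = "SELECT ?x WHERE { VALUES ?x OWL { 'no such label' } }"
    out = expand(empty_values, repo)
    assert "VALUES ?x { }" in out
    parse_sparql(out)
    empty_filter = "SELECT ?x WHERE { ?x ?p ?o FILTER(?x IN (OWL { 'no such label' })) }"
    out2 = expand(empty_filter, repo)
    assert "FILTER(false)" in out2
    parse_sparql(out2)


def test_to_curie_obo_pattern():
    assert to_curie("http://purl.obolibrary.org/obo/GO_0008150") == (
        "GO:0008150",
        "GO",
        "http://purl.obolibrary.org/obo/GO_",
    )
    # split at the FIRST underscore
    curie, label, base = to_curie("http://example.org/x/AB_12_34")
    assert (curie, label) == ("AB:12_34", "AB")
    assert base + "12_34" == "http://example.org/x/AB_12_34"
    assert to_curie("http://example.org/nounderscore") is None


def test_curie_roundtrip_recovers_answer_set(repo):
    from obakit.query_service import Query, answer

    answers = sorted(
        {r.class_iri for r in answer(Query("part_of some 'apoptotic process'", ontology_uri=fx.GO_URI), repo)}
    )
    recovered = []
    for iri in answers:
        curie, _label, base = to_curie(iri)
        local = curie.split(":", 1)[1]
        recovered.append(base + local)
    assert recovered == answers


def test_redefined_base_retargets_scheme():
    curie, _label, base = to_curie(
        "http://purl.obolibrary.org/obo/GO_0008150",
        PrefixMap(entries={"GO": fx.UNIPROT_GO_BASE}, rewrite_enabled=True),
    )
    assert base + curie.split(":", 1)[1] == "http://purl.uniprot.org/go/0008150"


def test_both_forms_execute_identically(repo, triple_files):
    values_out = expand(VALUES_QUERY, repo)
    filter_out = expand(FILTER_QUERY, repo)
    rows_v = execute(values_out, triple_files["triples_obo"])
    rows_f = execute(filter_out, triple_files["triples_obo"])
    assert sorted(rows_v) == sorted(rows_f)
    assert rows_v  # fixture guarantees annotated proteins exist


def test_uniprot_scheme_returns_same_proteins(repo, triple_files):
    obo_rows = execute(expand(VALUES_QUERY, repo), triple_files["triples_obo"])
    uniprot_query = expand(
        VALUES_QUERY, repo, PrefixMap(entries={"GO": fx.UNIPROT_GO_BASE}, rewrite_enabled=True)
    )
    uniprot_rows = execute(uniprot_query, triple_files["triples_uniprot"])
    assert sorted(uniprot_rows) == sorted(obo_rows)


def test_expanded_values_matches_ground_truth(repo, triple_files):
    import json

    with open(triple_files["ground_truth"], "r", encoding="utf-8") as handle:
        truth = json.load(handle)
    answer_set = set(fx.GO_PART_OF_APOPTOSIS)
    expected = {
        protein
        for protein, classes in truth["proteins"].items()
        if answer_set & set(classes)
    }
    rows = execute(expand(VALUES_QUERY, repo), triple_files["triples_obo"])
    assert {row[0] for row in rows} == expected
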