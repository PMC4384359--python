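"""Analyzer, inverted index, Boolean phrase retrieval and highlighting."""

import pytest

from obakit import fixtures as fx
from obakit.literature_search import (
    FIELDS,
    Document,
    DuplicateDocumentError,
    Phrase,
    _WORD_RE,
    analyze,
    build_index,
    build_label_query,
    highlight,
    read_jsonl,
    read_medline,
    search,
    write_jsonl,
)
from obakit.query_service import ClassRecord, Query, answer


def scan_phrase(doc: Document, phrase: Phrase) -> bool:
    """Independent substring-scan oracle on analyzed text."""
    for field in FIELDS:
        tokens = [m.group(0).lower() for m in _WORD_RE.finditer(doc.field_text(field))]
        slots = dict(enumerate(tokens))
        for start in range(len(tokens)):
            if all(slots.get(start + off) == tok for tok, off in phrase.tokens):
                return True
    return False


def scan_query(doc, label_query) -> bool:
    return any(scan_phrase(doc, p) for p in label_query.phrases)


def test_analyze_drops_stop_words_but_keeps_slots():
    assert analyze("Tetralogy of Fallot") == [("tetralogy", 0), ("fallot", 2)]
    assert analyze("") == []
    assert analyze("VSD—muscular defect.") == [("vsd", 0), ("muscular", 1), ("defect", 2)]


def test_phrase_matches_across_stop_words(small_corpus):
    corpus, _truth = small_corpus
    index = build_index(corpus)
    phrase = Phrase.from_label("tetralogy of Fallot")
    hits = index.phrase_docs(phrase)
    assert "PM000001" in hits
    for doc in corpus:
        assert (doc.doc_id in hits) == scan_phrase(doc, phrase)


def test_duplicate_doc_id_rejected():
    doc = Document(doc_id="X", title="aorta", abstract="")
    index = build_index([doc])
    with pytest.raises(DuplicateDocumentError):
        index.add(doc)


def test_fulltext_only_mention_is_matched():
    docs = [
        Document(doc_id="A", title="plain title", abstract="nothing here", fulltext="the heart morphology"),
        Document(doc_id="B", title="plain title", abstract="nothing here"),
    ]
    index = build_index(docs)
    assert index.phrase_docs(Phrase.from_label("heart")) == {"A"}


def test_build_label_query_dedupes_labels(repo):
    records = answer(Query("'ventricular septal defect'", ontology_uri=fx.CARDIO_URI), repo)
    lq = build_label_query(records + records)
    labels = [p.label for p in lq.phrases]
    assert len(labels) == len(set(labels))
    assert "ventricular septal defect" in labels
    assert "tetralogy of Fallot" in labels
    assert build_label_query([]).empty


def test_search_boolean_completeness_vs_scan_oracle(repo, small_corpus):
    corpus, _truth = small_corpus
    index = build_index(corpus)
    vsd_q = build_label_query(answer(Query("'ventricular septal defect'", ontology_uri=fx.CARDIO_URI), repo))
    heart_q = build_label_query(answer(Query("part_of some heart", ontology_uri=fx.CARDIO_URI), repo))

    single = {h.doc_id for h in search(index, [vsd_q])}
    assert single == {d.doc_id for d in corpus if scan_query(d, vsd_q)}

    conjunctive = {h.doc_id for h in search(index, [vsd_q, heart_q])}
    assert conjunctive == {
        d.doc_id for d in corpus if scan_query(d, vsd_q) and scan_query(d, heart_q)
    }
    assert conjunctive <= single


def test_tof_only_document_retrieved_by_vsd_query(repo, small_corpus):
    corpus, truth = small_corpus
    assert truth["PM000001"] == ["tetralogy of Fallot"]
    index = build_index(corpus)
    vsd_q = build_label_query(answer(Query("'ventricular septal defect'", ontology_uri=fx.CARDIO_URI), repo))
    hits = search(index, [vsd_q])
    match = next(h for h in hits if h.doc_id == "PM000001")
    assert match.matched_labels == ("tetralogy of Fallot",)


def test_empty_answer_set_matches_nothing(small_corpus):
    corpus, _truth = small_corpus
    index = build_index(corpus)
    assert search(index, [build_label_query([])]) == []


def test_scores_ordering_and_stability(small_corpus):
    corpus, _truth = small_corpus
    index = build_index(corpus)
    record = ClassRecord(fx.CARDIO_URI, fx.HP["tof"], "tetralogy of Fallot")
    hits = search(index, [build_label_query([record])])
    assert all(h.score > 0 for h in hits)
    assert hits == sorted(hits, key=lambda h: (-h.score, h.doc_id))


def test_adding_unrelated_document_never_changes_matches(small_corpus):
    corpus, _truth = small_corpus
    record = ClassRecord(fx.CARDIO_URI, fx.HP["tof"], "tetralogy of Fallot")
    lq = build_label_query([record])
    before = {h.doc_id for h in search(build_index(corpus), [lq])}
    extended = corpus + [Document(doc_id="ZZZ", title="unrelated placebo registry", abstract="enrolled cohort")]
    after = {h.doc_id for h in search(build_index(extended), [lq])}
    assert before == after


def test_result_set_monotone_in_answer_classes(small_corpus):
    corpus, _truth = small_corpus
    index = build_index(corpus)
    tof = ClassRecord(fx.CARDIO_URI, fx.HP["tof"], "tetralogy of Fallot")
    vsd = ClassRecord(fx.CARDIO_URI, fx.HP["vsd"], "ventricular septal defect")
    smaller = {h.doc_id for h in search(index, [build_label_query([tof])])}
    larger = {h.doc_id for h in search(index, [build_label_query([tof, vsd])])}
    assert smaller <= larger


def test_highlight_simple_and_merged_spans():
    doc = Document(
        doc_id="H",
        title="Infants with tetralogy of Fallot and more",
        abstract="a muscular ventricular septal defect; septal defect noted",
    )
    title_spans = [s for s in highlight(doc, ["tetralogy of Fallot"]) if s[0] == "title"]
    assert len(title_spans) == 1
    lo, hi = title_spans[0][1], title_spans[0][2]
    assert doc.title[lo:hi] == "tetralogy of Fallot"
    # overlapping phrases merge into one span
    merged = [s for s in highlight(doc, ["ventricular septal defect", "septal defect"]) if s[0] == "abstract"]
    assert len(merged) == 2  # one merged span + the second standalone occurrence
    lo, hi = merged[0][1], merged[0][2]
    assert doc.abstract[lo:hi] == "ventricular septal defect"


def test_highlight_reports_fulltext_field():
    doc = Document(doc_id="F", title="x", abstract="y", fulltext="noted tetralogy of Fallot here")
    spans = highlight(doc, ["tetralogy of Fallot"])
    assert [s[0] for s in spans] == ["fulltext"]


def test_jsonl_roundtrip_and_medline_reader(tmp_path):
    docs = [
        Document(doc_id="1", title="t1", abstract="a1", fulltext="f1"),
        Document(doc_id="2", title="t2", abstract="a2"),
    ]
    path = tmp_path / "corpus.jsonl"
    write_jsonl(str(path), docs)
    assert read_jsonl(str(path)) == docs

    medline = tmp_path / "corpus.txt"
    medline.write_text(
        "PMID- 100\nTI  - Tetralogy of Fallot in infants\nAB  - A study of the heart.\n"
        "\nPMID- 200\nTI  - Another title\nAB  - Another abstract.\n"
    )
    parsed = read_medline(str(medline))
    assert [d.doc_id for d in parsed] == ["100", "200"]
    assert parsed[0].title == "Tetralogy of Fallot in infants"
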