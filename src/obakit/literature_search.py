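"""Boolean, relevance-ranked retrieval of documents by inferred class labels.

The analyzer lower-cases, tokenizes on letter/digit runs and removes a fixed
33-entry English stop-word list; token *positions count pre-removal slots*,
so the phrase "tetralogy of fallot" is stored as tokens at slots 0 and 2 and
matches text in which the stop word is present.  A semantic query contributes
one disjunctive label query (any label phrase may match); multiple queries
are combined conjunctively (a document must match every query).  Relevance is
the sum of idf values of the distinct matched phrases,

    idf(phrase) = 1 + ln(N / (1 + df(phrase))),

with ties broken by ascending document id for byte-stable output.  No
stemming, no synonym expansion.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .query_service import ClassRecord

#: Fixed stop-word list (classic Lucene English set, 33 entries).
STOP_WORDS = frozenset(
    "a an and are as at be but by for if in into is it no not of on or such "
    "that the their then there these they this to was will with".split()
)

_WORD_RE = re.compile(r"[A-Za-z0-9]+")

FIELDS = ("title", "abstract", "fulltext")


def analyze(text: str) -> list[tuple[str, int]]:
    """Lower-cased tokens with pre-stop-removal slot positions."""
    out: list[tuple[str, int]] = []
    for slot, m in enumerate(_WORD_RE.finditer(text)):
        token = m.group(0).lower()
        if token not in STOP_WORDS:
            out.append((token, slot))
    return out


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str
    fulltext: Optional[str] = None

    def field_text(self, fieldname: str) -> str:
        value = getattr(self, fieldname if fieldname != "fulltext" else "fulltext")
        return value or ""


@dataclass(frozen=True)
class Phrase:
    """One analyzed label phrase: tokens with slot offsets from the first."""

    label: str
    tokens: tuple[tuple[str, int], ...]  # (token, offset) with offsets[0] == 0

    @classmethod
    def from_label(cls, label: str) -> Optional["Phrase"]:
        analyzed = analyze(label)
        if not analyzed:
            return None
        first = analyzed[0][1]
        return cls(label=label, tokens=tuple((t, p - first) for t, p in analyzed))


@dataclass
class LabelQuery:
    """Disjunction of label phrases produced by one semantic query."""

    phrases: tuple[Phrase, ...]

    @property
    def empty(self) -> bool:
        return not self.phrases


def build_label_query(answers: Sequence[ClassRecord]) -> LabelQuery:
    """One phrase per distinct label; an empty answer set matches nothing."""
    labels = sorted({r.label for r in answers})
    phrases = tuple(p for p in (Phrase.from_label(lbl) for lbl in labels) if p is not None)
    return LabelQuery(phrases=phrases)


class DuplicateDocumentError(ValueError):
    pass


class InvertedIndex:
    """Positional inverted index over (title, abstract, fulltext)."""

    def __init__(self) -> None:
        # token -> doc_id -> field -> sorted slot list
        self.postings: dict[str, dict[str, dict[str, list[int]]]] = {}
        self.doc_ids: list[str] = []

    @property
    def doc_count(self) -> int:
        return len(self.doc_ids)

    def add(self, doc: Document) -> None:
        if doc.doc_id in set(self.doc_ids):
            raise DuplicateDocumentError(doc.doc_id)
        self.doc_ids.append(doc.doc_id)
        for fieldname in FIELDS:
            for token, slot in analyze(doc.field_text(fieldname)):
                self.postings.setdefault(token, {}).setdefault(doc.doc_id, {}).setdefault(
                    fieldname, []
                ).append(slot)

    def phrase_docs(self, phrase: Phrase) -> set[str]:
        """Documents containing the phrase in any field."""
        candidates = None
        for token, _off in phrase.tokens:
            docs = set(self.postings.get(token, ()))
            candidates = docs if candidates is None else candidates & docs
            if not candidates:
                return set()
        hits: set[str] = set()
        for doc_id in candidates:
            if self._matches_in_doc(phrase, doc_id):
                hits.add(doc_id)
        return hits

    def _matches_in_doc(self, phrase: Phrase, doc_id: str) -> bool:
        first = self.postings[phrase.tokens[0][0]].get(doc_id, {})
        for fieldname, starts in first.items():
            for start in starts:
                if all(
                    start + off
                    in self._slots(token, doc_id, fieldname)
                    for token, off in phrase.tokens[1:]
                ):
                    return True
        return False

    def _slots(self, token: str, doc_id: str, fieldname: str) -> set[int]:
        return set(self.postings.get(token, {}).get(doc_id, {}).get(fieldname, ()))


def build_index(corpus: Iterable[Document]) -> InvertedIndex:
    index = InvertedIndex()
    for doc in corpus:
        index.add(doc)
    return index


@dataclass(frozen=True)
class SearchHit:
    doc_id: str
    score: float
    matched_labels: tuple[str, ...]


def search(index: InvertedIndex, queries: Sequence[LabelQuery]) -> list[SearchHit]:
    """Conjunctive multi-query search with summed-idf ranking.

    A document qualifies iff every query has at least one matching phrase in
    it.  The score sums the idf of each distinct matched phrase.
    """
    if not queries:
        raise ValueError("at least one label query is required")
    if any(q.empty for q in queries):
        return []

    phrase_hits: dict[tuple, set[str]] = {}
    for query in queries:
        for phrase in query.phrases:
            if phrase.tokens not in phrase_hits:
                phrase_hits[phrase.tokens] = index.phrase_docs(phrase)

    qualifying: Optional[set[str]] = None
    for query in queries:
        matched = set()
        for phrase in query.phrases:
            matched |= phrase_hits[phrase.tokens]
        qualifying = matched if qualifying is None else qualifying & matched
    assert qualifying is not None

    n = index.doc_count
    idf = {
        tokens: 1.0 + math.log(n / (1 + len(docs))) if n else 0.0
        for tokens, docs in phrase_hits.items()
    }
    label_of: dict[tuple, str] = {}
    for query in queries:
        for phrase in query.phrases:
            label_of.setdefault(phrase.tokens, phrase.label)

    hits = []
    for doc_id in qualifying:
        matched_tokens = {t for t, docs in phrase_hits.items() if doc_id in docs}
        score = sum(idf[t] for t in matched_tokens)
        labels = tuple(sorted({label_of[t] for t in matched_tokens}))
        hits.append(SearchHit(doc_id=doc_id, score=score, matched_labels=labels))
    hits.sort(key=lambda h: (-h.score, h.doc_id))
    return hits


# ---------------------------------------------------------------------------
# Highlighting
# ---------------------------------------------------------------------------

def highlight(doc: Document, labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """Character spans of each label-phrase occurrence, merged per field."""
    spans: list[tuple[str, int, int]] = []
    for fieldname in FIELDS:
        text = doc.field_text(fieldname)
        if not text:
            continue
        token_spans = [(m.group(0).lower(), m.start(), m.end()) for m in _WORD_RE.finditer(text)]
        raw: list[tuple[int, int]] = []
        for label in labels:
            phrase = Phrase.from_label(label)
            if phrase is None:
                continue
            for start_slot in range(len(token_spans)):
                ok = True
                for token, off in phrase.tokens:
                    slot = start_slot + off
                    if slot >= len(token_spans) or token_spans[slot][0] != token:
                        ok = False
                        break
                if ok:
                    last_slot = start_slot + phrase.tokens[-1][1]
                    raw.append((token_spans[start_slot][1], token_spans[last_slot][2]))
        for lo, hi in _merge_spans(raw):
            spans.append((fieldname, lo, hi))
    return spans


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(spans):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# Corpus readers
# ---------------------------------------------------------------------------

def read_jsonl(path: str) -> list[Document]:
    """Line-delimited JSON records {id, title, abstract, fulltext?}."""
    docs: list[Document] = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            raw = json.loads(line)
            docs.append(
                Document(
                    doc_id=str(raw["id"]),
                    title=raw.get("title", ""),
                    abstract=raw.get("abstract", ""),
                    fulltext=raw.get("fulltext"),
                )
            )
    return docs


def write_jsonl(path: str, docs: Sequence[Document]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for doc in docs:
            record = {"id": doc.doc_id, "title": doc.title, "abstract": doc.abstract}
            if doc.fulltext is not None:
                record["fulltext"] = doc.fulltext
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_medline(path: str) -> list[Document]:
    """Minimal MEDLINE-style reader: PMID-, TI- and AB-tagged records."""
    docs: list[Document] = []
    pmid = title = abstract = None
    last_tag = None

    def flush() -> None:
        nonlocal pmid, title, abstract
        if pmid is not None:
            docs.append(Document(doc_id=pmid, title=title or "", abstract=abstract or ""))
        pmid = title = abstract = None

    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                last_tag = None
                continue
            tag, _, rest = line.partition("- ")
            tag = tag.strip()
            if tag == "PMID":
                flush()
                pmid = rest.strip()
                last_tag = "PMID"
            elif tag == "TI":
                title = rest.strip()
                last_tag = "TI"
            elif tag == "AB":
                abstract = rest.strip()
                last_tag = "AB"
            elif line.startswith(" ") and last_tag in ("TI", "AB"):
                if last_tag == "TI":
                    title = (title or "") + " " + line.strip()
                else:
                    abstract = (abstract or "") + " " + line.strip()
    flush()
    return docs
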