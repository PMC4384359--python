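"""Prefix trie over class/property labels, plus a short-form resolver.

Matching is case-insensitive with case-preserving storage: trie keys are the
lower-cased labels, payloads keep the original casing.  The resolver maps
Manchester-syntax tokens (quoted labels, bare identifiers, bracketed IRIs)
to entity IRIs within one ontology; an ambiguous token resolves to nothing,
with a warning, and the query layer then returns empty results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import IRI, OntologyDocument, local_name

logger = logging.getLogger(__name__)

Entry = tuple[str, IRI, IRI]  # (label as stored, entity IRI, ontology URI)


@dataclass
class _Node:
    children: dict[str, "_Node"] = field(default_factory=dict)
    payloads: list[Entry] = field(default_factory=list)


class LabelTrie:
    """Character trie keyed by lower-cased labels."""

    def __init__(self) -> None:
        self.root = _Node()
        self._size = 0

    def insert(self, label: str, iri: IRI, ontology_uri: IRI) -> None:
        node = self.root
        for ch in label.lower():
            node = node.children.setdefault(ch, _Node())
        node.payloads.append((label, iri, ontology_uri))
        self._size += 1

    def __len__(self) -> int:
        return self._size

    def lookup(self, label: str) -> list[Entry]:
        """Entries stored under exactly this label (case-insensitive)."""
        node = self.root
        for ch in label.lower():
            node = node.children.get(ch)
            if node is None:
                return []
        return list(node.payloads)

    def complete(self, prefix: str) -> list[Entry]:
        """All entries whose label starts with ``prefix``, sorted by
        (label, IRI, ontology URI)."""
        node = self.root
        for ch in prefix.lower():
            node = node.children.get(ch)
            if node is None:
                return []
        results: list[Entry] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            results.extend(cur.payloads)
            stack.extend(cur.children.values())
        results.sort()
        return results


def build_trie(docs: Iterable[OntologyDocument]) -> LabelTrie:
    """One trie entry per (label, entity IRI, ontology URI)."""
    trie = LabelTrie()
    for doc in docs:
        for iri in sorted(doc.classes | doc.properties):
            trie.insert(doc.label_of(iri), iri, doc.document_uri)
    return trie


def complete(trie: LabelTrie, prefix: str) -> list[Entry]:
    return trie.complete(prefix)


def resolve(doc: OntologyDocument, token: str, kind: str = "any") -> Optional[IRI]:
    """Resolve a Manchester token to an IRI within one ontology.

    * ``<full-iri>`` resolves to itself.
    * ``'quoted label'`` requires a case-insensitive exact label match.
    * a bare token tries a label match first, then an IRI local-name match.

    ``kind`` restricts candidates to ``"class"`` or ``"property"`` entities.
    Ambiguity within the ontology resolves to ``None`` with a warning.
    """
    if token.startswith("<") and token.endswith(">"):
        return token[1:-1]
    quoted = token.startswith("'") and token.endswith("'") and len(token) >= 2
    text = token[1:-1] if quoted else token

    if kind == "class":
        candidates = doc.classes
    elif kind == "property":
        candidates = doc.properties
    else:
        candidates = doc.classes | doc.properties

    wanted = text.lower()
    matches = sorted(iri for iri in candidates if doc.label_of(iri).lower() == wanted)
    if not matches and not quoted:
        matches = sorted(iri for iri in candidates if local_name(iri).lower() == wanted)
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        logger.warning(
            "token %r is ambiguous in %s: %s", token, doc.document_uri, ", ".join(matches)
        )
    return None
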