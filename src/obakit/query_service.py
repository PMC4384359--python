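"""Manchester-syntax queries over a repository, with the JSON result contract.

A query is parsed per ontology (labels resolve within the ontology being
queried), answered by the EL reasoner, and serialised as a JSON array of
objects carrying the ontology document URI, the class IRI, the class label
and its text definition (``null`` when absent).  Every failure mode — parse
error, unresolvable token, unknown ontology — contributes an empty result
for that ontology instead of an exception.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

from . import label_index
from .el_reasoner import QUERY_TYPES, query_expression
from .manchester import ManchesterParseError, parse_manchester
from .model import IRI, OntologyDocument
from .ontology_store import Repository

logger = logging.getLogger(__name__)


@dataclass
class Query:
    expression_text: str
    qtype: str = "subclass"
    ontology_uri: Optional[IRI] = None
    direct_only: bool = False

    def __post_init__(self) -> None:
        if not self.qtype:
            self.qtype = "subclass"
        if self.qtype not in QUERY_TYPES:
            raise ValueError(f"unknown query type {self.qtype!r}")


@dataclass(frozen=True)
class ClassRecord:
    ontology_uri: IRI
    class_iri: IRI
    label: str
    definition: Optional[str] = None


def answer_one(query: Query, doc: OntologyDocument) -> list[ClassRecord]:
    """Answer a query against a single ontology (empty list on any failure)."""

    def resolver(token: str, kind: str) -> Optional[IRI]:
        return label_index.resolve(doc, token, kind)

    try:
        expr = parse_manchester(query.expression_text, resolver)
    except ManchesterParseError as exc:
        logger.warning("query %r failed on %s: %s", query.expression_text, doc.document_uri, exc)
        return []
    answers = query_expression(doc, expr, qtype=query.qtype, direct_only=query.direct_only)
    records = [
        ClassRecord(
            ontology_uri=doc.document_uri,
            class_iri=iri,
            label=doc.label_of(iri),
            definition=doc.definitions.get(iri),
        )
        for iri in sorted(answers)
    ]
    return records


def answer(query: Query, repo: Repository) -> list[ClassRecord]:
    """Answer against one ontology or fan out over the whole repository.

    Results are grouped by ontology URI (URIs in sorted order), each group
    sorted by class IRI, deduplicated per (ontology, IRI).
    """
    records: list[ClassRecord] = []
    for doc in repo.get(query.ontology_uri):
        records.extend(answer_one(query, doc))
    return records


def to_json(records: list[ClassRecord]) -> str:
    """Serialise records to the stable JSON array contract."""
    payload = [
        {
            "ontology": r.ontology_uri,
            "class": r.class_iri,
            "label": r.label,
            "definition": r.definition,
        }
        for r in records
    ]
    return json.dumps(payload, indent=2, ensure_ascii=False)
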