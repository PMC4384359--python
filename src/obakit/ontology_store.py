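"""Loading OWL documents, resolving imports locally and extracting annotations.

Imports are resolved exclusively through a caller-supplied catalog mapping
ontology IRIs to local files — no network access, ever.  An unresolvable
import is skipped with a warning; an unreadable or malformed source raises
:class:`LoadError`, which the query layer maps to the empty-result contract.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable, Optional

from . import ofn
from .model import (
    AnnotationAssertion,
    Axiom,
    IAO_DEFINITION,
    IRI,
    OntologyDocument,
    OWL_NOTHING,
    OWL_THING,
    RDFS_LABEL,
    class_axioms,
    local_name,
)

logger = logging.getLogger(__name__)

Catalog = dict[IRI, str]


class LoadError(Exception):
    """Source unreadable or not well-formed functional syntax."""


def _read_source(source: str) -> str:
    try:
        with open(source, "r", encoding="utf-8") as handle:
            return handle.read()
    except OSError as exc:
        raise LoadError(f"cannot read ontology source {source!r}: {exc}") from exc


def _collect_entity_iris(axioms: Iterable[Axiom], doc: OntologyDocument) -> None:
    """Register every IRI used in a class or property position."""
    from .model import Conjunction, Existential, NamedClass, SubClassOf, EquivalentClasses
    from .model import PropertyChain, SubPropertyOf, TransitiveProperty

    def walk(expr) -> None:
        if isinstance(expr, NamedClass):
            if expr.iri not in (OWL_THING, OWL_NOTHING):
                doc.classes.add(expr.iri)
        elif isinstance(expr, Existential):
            doc.properties.add(expr.prop)
            walk(expr.filler)
        elif isinstance(expr, Conjunction):
            for op in expr.operands:
                walk(op)

    for axiom in axioms:
        if isinstance(axiom, SubClassOf):
            walk(axiom.sub)
            walk(axiom.sup)
        elif isinstance(axiom, EquivalentClasses):
            for expr in axiom.exprs:
                walk(expr)
        elif isinstance(axiom, SubPropertyOf):
            doc.properties.update((axiom.sub, axiom.sup))
        elif isinstance(axiom, PropertyChain):
            doc.properties.update((axiom.first, axiom.second, axiom.implied))
        elif isinstance(axiom, TransitiveProperty):
            doc.properties.add(axiom.prop)


def load_ontology(source: str, catalog: Optional[Catalog] = None) -> OntologyDocument:
    """Load a functional-syntax document and merge its imports closure.

    ``catalog`` maps import IRIs to local file paths.  Axioms outside the EL
    subset are dropped with a logged warning.  Raises :class:`LoadError` for
    unreadable or syntactically broken sources.
    """
    return load_ontology_text(_read_source(source), catalog, source=source)


def load_ontology_text(
    text: str, catalog: Optional[Catalog] = None, source: str = "<string>"
) -> OntologyDocument:
    """Like :func:`load_ontology` but from document text already in memory."""
    catalog = catalog or {}
    merged = OntologyDocument(document_uri="")
    seen: set[str] = {source}

    def visit(doc_text: str, origin: str) -> ofn.ParsedDocument:
        try:
            parsed = ofn.parse_ofn(doc_text)
        except ofn.OfnSyntaxError as exc:
            raise LoadError(f"syntax error in {origin!r}: {exc}") from exc
        merged.axioms.extend(parsed.axioms)
        merged.classes.update(parsed.classes)
        merged.properties.update(parsed.properties)
        merged.dropped_axiom_count += parsed.dropped_axiom_count
        for imp in parsed.imports:
            if imp in seen:
                continue
            seen.add(imp)
            target = catalog.get(imp)
            if target is None:
                logger.warning("import %s not in catalog; skipped", imp)
                continue
            visit(_read_source(target), target)
        return parsed

    root = visit(text, source)
    merged.document_uri = root.ontology_iri or source
    _collect_entity_iris(class_axioms(merged.axioms), merged)
    labels, definitions = extract_annotations(merged)
    merged.labels = labels
    merged.definitions = definitions
    return merged


def extract_annotations(doc: OntologyDocument) -> tuple[dict[IRI, str], dict[IRI, str]]:
    """Labels from ``rdfs:label``, definitions from IAO_0000115.

    Every known class/property gets a label entry (IRI local name when no
    ``rdfs:label`` is asserted).  Multiple labels on one IRI: the first in
    document order wins, with a warning.
    """
    labels: dict[IRI, str] = {}
    definitions: dict[IRI, str] = {}
    known = doc.classes | doc.properties
    for axiom in doc.axioms:
        if not isinstance(axiom, AnnotationAssertion):
            continue
        if axiom.subject not in known:
            continue
        if axiom.prop == RDFS_LABEL:
            if axiom.subject in labels:
                logger.warning(
                    "multiple rdfs:label values for %s; keeping %r",
                    axiom.subject,
                    labels[axiom.subject],
                )
            else:
                labels[axiom.subject] = axiom.value
        elif axiom.prop == IAO_DEFINITION:
            definitions.setdefault(axiom.subject, axiom.value)
    for iri in known:
        labels.setdefault(iri, local_name(iri))
    return labels, definitions


def load_catalog(path: str) -> Catalog:
    """Read a JSON catalog ``{"ontologyIRI": "relative/path.ofn"}``.

    Relative paths are resolved against the catalog file's directory.
    """
    with open(path, "r", encoding="utf-8") as handle:
        raw = json.load(handle)
    base = os.path.dirname(os.path.abspath(path))
    return {iri: os.path.join(base, p) if not os.path.isabs(p) else p for iri, p in raw.items()}


class Repository:
    """A set of loaded ontologies addressed by document URI.

    ``get(None)`` fans out to every document; ``get(uri)`` returns a singleton
    for a known URI, attempts a one-off load for an unknown one, and returns
    an empty list on any failure — the caller then yields empty results.
    """

    def __init__(self, docs: Iterable[OntologyDocument] = (), catalog: Optional[Catalog] = None):
        self.catalog: Catalog = dict(catalog or {})
        self.docs: dict[IRI, OntologyDocument] = {}
        for doc in docs:
            self.docs[doc.document_uri] = doc
        self._taxonomies: dict[IRI, "object"] = {}

    @classmethod
    def from_sources(cls, sources: Iterable[str], catalog: Optional[Catalog] = None) -> "Repository":
        repo = cls(catalog=catalog)
        for source in sources:
            try:
                repo.add(load_ontology(source, repo.catalog))
            except LoadError as exc:
                logger.warning("skipping source %s: %s", source, exc)
        return repo

    @classmethod
    def from_config(cls, path: str) -> "Repository":
        """Config: ``{"sources": [...], "catalog": "catalog.json" | {...}}``."""
        with open(path, "r", encoding="utf-8") as handle:
            config = json.load(handle)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base, p)

        catalog_spec = config.get("catalog")
        if isinstance(catalog_spec, str):
            catalog = load_catalog(resolve(catalog_spec))
        elif isinstance(catalog_spec, dict):
            catalog = {iri: resolve(p) for iri, p in catalog_spec.items()}
        else:
            catalog = {}
        sources = [resolve(s) for s in config.get("sources", [])]
        return cls.from_sources(sources, catalog)

    def add(self, doc: OntologyDocument) -> None:
        self.docs[doc.document_uri] = doc
        self._taxonomies.pop(doc.document_uri, None)

    def get(self, uri: Optional[IRI] = None) -> list[OntologyDocument]:
        if uri is None:
            return [self.docs[key] for key in sorted(self.docs)]
        if uri in self.docs:
            return [self.docs[uri]]
        # unknown URI: attempt a load (local path or catalog entry only)
        source = self.catalog.get(uri, uri)
        try:
            doc = load_ontology(source, self.catalog)
        except LoadError as exc:
            logger.warning("cannot retrieve ontology %s: %s", uri, exc)
            return []
        self.add(doc)
        return [doc]

    def taxonomy(self, doc: OntologyDocument):
        """Classification result for ``doc``, cached per document URI."""
        cached = self._taxonomies.get(doc.document_uri)
        if cached is None:
            from .el_reasoner import classify

            cached = classify(doc)
            self._taxonomies[doc.document_uri] = cached
        return cached
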