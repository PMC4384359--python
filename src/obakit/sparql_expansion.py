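"""Expansion of extended SPARQL with embedded ontology-query (OWL) blocks.

The extension macro is::

    OWL [subclass|superclass|equivalent] [FROM <ontologyIRI>] { <manchester> }

and is recognised in exactly two positions of an otherwise standard SPARQL
1.1 query:

* ``VALUES ?var OWL ... { ... }``            (VALUES form)
* ``FILTER(?var IN (OWL ... { ... }))``      (FILTER form)

Expansion replaces the construct with the reasoner's answer set — an inline
``VALUES`` data block or an ``IN`` term list.  An empty answer set becomes an
empty ``VALUES`` block or ``FILTER(false)`` (a zero-term ``IN`` is not legal
SPARQL).  With prefix rewriting enabled, answer IRIs are emitted as CURIEs
(``http://purl.obolibrary.org/obo/GO_0008150`` → ``GO:0008150``) and missing
``PREFIX`` declarations are prepended; declarations already present in the
query always win, which lets users retarget a URI scheme (e.g. the UniProt
GO base) by redefining the prefix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .model import IRI
from .ontology_store import Repository
from .query_service import Query, answer

logger = logging.getLogger(__name__)


class SparqlExtensionError(ValueError):
    """An OWL macro appears in an unsupported position."""


@dataclass
class OwlBlock:
    expression_text: str
    qtype: str = "subclass"
    ontology_uri: Optional[IRI] = None
    form: str = "values"  # "values" | "filter"
    var: str = "?x"
    span: tuple[int, int] = (0, 0)  # character range of the whole embedding


@dataclass
class PrefixMap:
    """User prefix redefinitions plus the rewrite switch."""

    entries: dict[str, str] = field(default_factory=dict)
    rewrite_enabled: bool = False


_MACRO = (
    r"OWL\s*(?:(?P<qtype>subclass|superclass|equivalent)\s*)?"
    r"(?:FROM\s*<(?P<ont>[^<>]*)>\s*)?\{(?P<expr>[^{}]*)\}"
)

_VALUES_RE = re.compile(
    r"VALUES\s+(?P<var>\?\w+)\s+" + _MACRO,
    re.IGNORECASE,
)
_FILTER_RE = re.compile(
    r"FILTER\s*\(\s*(?P<var>\?\w+)\s+IN\s*\(\s*" + _MACRO + r"\s*\)\s*\)",
    re.IGNORECASE,
)
_ANY_MACRO_RE = re.compile(_MACRO)
_PREFIX_DECL_RE = re.compile(r"PREFIX\s+(?P<label>[A-Za-z][\w\-]*):\s*<(?P<base>[^<>]*)>", re.IGNORECASE)


def parse_extended(text: str) -> tuple[str, list[OwlBlock]]:
    """Locate OWL blocks; returns the unchanged template and the blocks.

    Raises :class:`SparqlExtensionError` when a macro occurs outside the two
    supported embeddings.
    """
    blocks: list[OwlBlock] = []
    covered: list[tuple[int, int]] = []
    for form, pattern in (("values", _VALUES_RE), ("filter", _FILTER_RE)):
        for m in pattern.finditer(text):
            blocks.append(
                OwlBlock(
                    expression_text=m.group("expr").strip(),
                    qtype=(m.group("qtype") or "subclass").lower(),
                    ontology_uri=m.group("ont") or None,
                    form=form,
                    var=m.group("var"),
                    span=m.span(),
                )
            )
            covered.append(m.span())
    for m in _ANY_MACRO_RE.finditer(text):
        if not any(lo <= m.start() < hi for lo, hi in covered):
            line = text.count("\n", 0, m.start()) + 1
            raise SparqlExtensionError(
                f"OWL block at line {line} (offset {m.start()}) is neither a VALUES "
                "data block nor a FILTER(?var IN (...)) term list"
            )
    blocks.sort(key=lambda b: b.span)
    return text, blocks


def to_curie(iri: IRI, prefixes: Optional[PrefixMap] = None) -> Optional[tuple[str, str, str]]:
    """Rewrite an IRI into prefix form.

    The final path segment is split at its FIRST underscore: the left part is
    the prefix label, the right part the local id, and the declaration base is
    the IRI minus the local id.  Returns ``(curie, label, base)`` or ``None``
    (with a warning) when the segment has no underscore.  A user-supplied base
    for the label (in ``prefixes``) overrides the derived one.
    """
    segment = iri.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    if "_" not in segment or segment.startswith("_"):
        logger.warning("IRI %s has no PREFIX_localid pattern; left unrewritten", iri)
        return None
    label, local = segment.split("_", 1)
    if not re.fullmatch(r"[A-Za-z][\w\-]*", label):
        logger.warning("IRI %s yields invalid prefix label %r; left unrewritten", iri, label)
        return None
    base = iri[: len(iri) - len(local)]
    if prefixes is not None and label in prefixes.entries:
        base = prefixes.entries[label]
    return f"{label}:{local}", label, base


def expand(text: str, repo: Repository, prefixes: Optional[PrefixMap] = None) -> str:
    """Rewrite extended SPARQL into standard SPARQL 1.1."""
    prefixes = prefixes or PrefixMap()
    _template, blocks = parse_extended(text)
    declared = {m.group("label") for m in _PREFIX_DECL_RE.finditer(text)}

    needed_decls: dict[str, str] = {}
    pieces: list[str] = []
    cursor = 0
    for block in blocks:
        lo, hi = block.span
        pieces.append(text[cursor:lo])
        query = Query(
            expression_text=block.expression_text,
            qtype=block.qtype,
            ontology_uri=block.ontology_uri,
        )
        iris = sorted({record.class_iri for record in answer(query, repo)})
        terms: list[str] = []
        for iri in iris:
            if prefixes.rewrite_enabled:
                rewritten = to_curie(iri, prefixes)
                if rewritten is not None:
                    curie, label, base = rewritten
                    terms.append(curie)
                    if label not in declared:
                        needed_decls.setdefault(label, base)
                    continue
            terms.append(f"<{iri}>")
        if block.form == "values":
            body = " ".join(terms)
            pieces.append(f"VALUES {block.var} {{ {body} }}" if terms else f"VALUES {block.var} {{ }}")
        else:
            pieces.append(
                f"FILTER({block.var} IN ({', '.join(terms)}))" if terms else "FILTER(false)"
            )
        cursor = hi
    pieces.append(text[cursor:])
    out = "".join(pieces)
    if needed_decls:
        decl_text = "".join(
            f"PREFIX {label}: <{base}>\n" for label, base in sorted(needed_decls.items())
        )
        out = decl_text + out
    return out


# ---------------------------------------------------------------------------
# Execution helpers (rdflib-backed), used by the CLI and by validation
# ---------------------------------------------------------------------------

def parse_sparql(query_text: str):
    """Parse a query with rdflib's SPARQL 1.1 parser (raises on error)."""
    from rdflib.plugins.sparql import prepareQuery

    return prepareQuery(query_text)


def execute(query_text: str, ntriples_path: str) -> list[tuple]:
    """Run a standard SPARQL query over an N-Triples file; solution rows as
    tuples of string values, in a deterministic (sorted) order."""
    import rdflib

    graph = rdflib.Graph()
    graph.parse(ntriples_path, format="nt")
    rows = [
        tuple(None if v is None else str(v) for v in row)
        for row in graph.query(query_text)
    ]
    rows.sort(key=lambda row: tuple("" if v is None else v for v in row))
    return rows
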