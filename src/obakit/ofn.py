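"""Reader/writer for OWL Functional-Style Syntax documents (EL subset).

Only the constructs the reasoner consumes are materialised: ``SubClassOf``,
``EquivalentClasses`` over named classes / ``ObjectIntersectionOf`` /
``ObjectSomeValuesFrom`` / ``owl:Thing`` / ``owl:Nothing``,
``SubObjectPropertyOf`` (including length-2 ``ObjectPropertyChain``),
``TransitiveObjectProperty``, declarations and annotation assertions.  Every
other axiom (or any axiom containing an unsupported expression) is dropped
with a warning — never an error — mirroring how an EL reasoner ignores
out-of-profile axioms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .model import (
    Axiom,
    AnnotationAssertion,
    Bottom,
    ClassExpr,
    Conjunction,
    EquivalentClasses,
    Existential,
    IRI,
    NamedClass,
    OWL_NOTHING,
    OWL_THING,
    PropertyChain,
    SubClassOf,
    SubPropertyOf,
    Top,
    TransitiveProperty,
    conj,
    expr_sort_key,
)

logger = logging.getLogger(__name__)

DEFAULT_PREFIXES = {
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "xml": "http://www.w3.org/XML/1998/namespace",
}


class OfnSyntaxError(ValueError):
    """Raised when a document is not well-formed functional syntax."""


class _Unsupported(Exception):
    """Internal: expression/axiom outside the EL subset."""


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)            # whitespace / comment
  | (?P<iri><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<lang>@[A-Za-z][A-Za-z0-9-]*)
  | (?P<dtype>\^\^)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<eq>=)
  | (?P<pname>[A-Za-z_][A-Za-z0-9_.\-]*)?:(?P<plocal>[A-Za-z0-9_.\-]*)
  | (?P<word>[A-Za-z_][A-Za-z0-9_.\-]*)
    """,
    re.VERBOSE,
)


@dataclass
class _Token:
    kind: str
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    n = len(text)
    while i < n:
        m = _TOKEN_RE.match(text, i)
        if m is None:
            raise OfnSyntaxError(f"unexpected character {text[i]!r} at offset {i}")
        i = m.end()
        kind = m.lastgroup
        if kind in ("ws",):
            continue
        if m.group("pname") is not None or (kind == "plocal"):
            tokens.append(_Token("pname", m.group(0), m.start()))
        elif kind == "plocal":  # pragma: no cover - folded into branch above
            tokens.append(_Token("pname", m.group(0), m.start()))
        else:
            tokens.append(_Token(kind, m.group(0), m.start()))
    return tokens


@dataclass
class ParsedDocument:
    """Raw parse result for a single file (imports not yet resolved)."""

    ontology_iri: IRI
    imports: list[IRI] = field(default_factory=list)
    axioms: list[Axiom] = field(default_factory=list)
    classes: set[IRI] = field(default_factory=set)
    properties: set[IRI] = field(default_factory=set)
    parsed_axiom_count: int = 0
    dropped_axiom_count: int = 0


_ANNOTATION_AXIOM = "AnnotationAssertion"


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.i = 0
        self.prefixes = dict(DEFAULT_PREFIXES)

    # -- token helpers ------------------------------------------------------
    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise OfnSyntaxError("unexpected end of document")
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise OfnSyntaxError(f"expected {kind}, got {tok.text!r} at offset {tok.pos}")
        return tok

    def expect_word(self, word: str) -> None:
        tok = self.next()
        if tok.kind != "word" or tok.text != word:
            raise OfnSyntaxError(f"expected {word!r}, got {tok.text!r} at offset {tok.pos}")

    def skip_balanced(self) -> None:
        """Skip a parenthesised group (after its opening paren was consumed)."""
        depth = 1
        while depth:
            tok = self.next()
            if tok.kind == "lpar":
                depth += 1
            elif tok.kind == "rpar":
                depth -= 1

    # -- terms --------------------------------------------------------------
    def iri_token(self, tok: _Token) -> IRI:
        if tok.kind == "iri":
            return tok.text[1:-1]
        if tok.kind == "pname":
            prefix, _, local = tok.text.partition(":")
            base = self.prefixes.get(prefix)
            if base is None:
                raise OfnSyntaxError(f"undeclared prefix {prefix!r} at offset {tok.pos}")
            return base + local
        raise OfnSyntaxError(f"expected an IRI, got {tok.text!r} at offset {tok.pos}")

    def parse_iri(self) -> IRI:
        return self.iri_token(self.next())

    def parse_literal(self) -> str:
        tok = self.expect("string")
        value = tok.text[1:-1].replace('\\"', '"').replace("\\\\", "\\")
        nxt = self.peek()
        if nxt is not None and nxt.kind == "lang":
            self.next()
        elif nxt is not None and nxt.kind == "dtype":
            self.next()
            self.next()  # datatype IRI
        return value

    # -- class expressions ---------------------------------------------------
    def parse_class_expr(self) -> ClassExpr:
        tok = self.next()
        if tok.kind in ("iri", "pname"):
            iri = self.iri_token(tok)
            if iri == OWL_THING:
                return Top
            if iri == OWL_NOTHING:
                return Bottom
            return NamedClass(iri)
        if tok.kind == "word":
            head = tok.text
            self.expect("lpar")
            if head == "ObjectIntersectionOf":
                ops = []
                while self.peek() and self.peek().kind != "rpar":
                    ops.append(self.parse_class_expr())
                self.expect("rpar")
                if len(ops) < 2:
                    raise OfnSyntaxError("ObjectIntersectionOf needs >= 2 operands")
                return conj(*ops)
            if head == "ObjectSomeValuesFrom":
                prop = self.parse_iri()
                filler = self.parse_class_expr()
                self.expect("rpar")
                return Existential(prop, filler)
            # anything else (unions, complements, universal/cardinality
            # restrictions, nominals ...) is outside EL
            self.skip_balanced()
            raise _Unsupported(head)
        raise OfnSyntaxError(f"unexpected token {tok.text!r} in class expression at offset {tok.pos}")

    # -- axioms ---------------------------------------------------------------
    def skip_axiom_annotations(self) -> None:
        """Consume leading Annotation(...) blocks inside an axiom."""
        while True:
            tok = self.peek()
            if tok is not None and tok.kind == "word" and tok.text == "Annotation":
                self.next()
                self.expect("lpar")
                self.skip_balanced()
            else:
                return

    def parse_document(self) -> ParsedDocument:
        while True:
            tok = self.peek()
            if tok is None:
                raise OfnSyntaxError("missing Ontology(...) block")
            if tok.kind == "word" and tok.text == "Prefix":
                self.next()
                self.expect("lpar")
                name_tok = self.expect("pname")
                prefix = name_tok.text[:-1] if name_tok.text.endswith(":") else name_tok.text.partition(":")[0]
                self.expect("eq")
                base = self.parse_iri()
                self.expect("rpar")
                self.prefixes[prefix] = base
            elif tok.kind == "word" and tok.text == "Ontology":
                break
            else:
                raise OfnSyntaxError(f"unexpected {tok.text!r} before Ontology block at offset {tok.pos}")

        self.expect_word("Ontology")
        self.expect("lpar")
        ontology_iri = ""
        tok = self.peek()
        if tok is not None and tok.kind in ("iri", "pname"):
            ontology_iri = self.parse_iri()
            tok = self.peek()
            if tok is not None and tok.kind in ("iri", "pname"):  # version IRI
                self.parse_iri()
        doc = ParsedDocument(ontology_iri=ontology_iri)

        while True:
            tok = self.next()
            if tok.kind == "rpar":
                break
            if tok.kind != "word":
                raise OfnSyntaxError(f"unexpected {tok.text!r} at offset {tok.pos}")
            head = tok.text
            self.expect("lpar")
            if head == "Import":
                doc.imports.append(self.parse_iri())
                self.expect("rpar")
                continue
            self._parse_axiom(head, doc)
        return doc

    def _parse_axiom(self, head: str, doc: ParsedDocument) -> None:
        start = self.i  # after the opening paren
        doc.parsed_axiom_count += 1
        try:
            if head == "Declaration":
                doc.parsed_axiom_count -= 1  # declarations are not axioms for counting
                kind = self.next()
                self.expect("lpar")
                iri = self.parse_iri()
                self.expect("rpar")
                self.expect("rpar")
                if kind.text == "Class":
                    doc.classes.add(iri)
                elif kind.text == "ObjectProperty":
                    doc.properties.add(iri)
                # AnnotationProperty / Datatype / NamedIndividual: recorded nowhere
                return
            if head == "SubClassOf":
                self.skip_axiom_annotations()
                sub = self.parse_class_expr()
                sup = self.parse_class_expr()
                self.expect("rpar")
                doc.axioms.append(SubClassOf(sub, sup))
                return
            if head == "EquivalentClasses":
                self.skip_axiom_annotations()
                exprs = []
                while self.peek() and self.peek().kind != "rpar":
                    exprs.append(self.parse_class_expr())
                self.expect("rpar")
                doc.axioms.append(EquivalentClasses(tuple(exprs)))
                return
            if head == "SubObjectPropertyOf":
                self.skip_axiom_annotations()
                tok = self.peek()
                if tok is not None and tok.kind == "word" and tok.text == "ObjectPropertyChain":
                    self.next()
                    self.expect("lpar")
                    chain = []
                    while self.peek() and self.peek().kind != "rpar":
                        chain.append(self.parse_iri())
                    self.expect("rpar")
                    implied = self.parse_iri()
                    self.expect("rpar")
                    if len(chain) != 2:
                        raise _Unsupported(f"property chain of length {len(chain)}")
                    doc.axioms.append(PropertyChain(chain[0], chain[1], implied))
                else:
                    sub = self.parse_iri()
                    sup = self.parse_iri()
                    self.expect("rpar")
                    doc.axioms.append(SubPropertyOf(sub, sup))
                return
            if head == "TransitiveObjectProperty":
                self.skip_axiom_annotations()
                prop = self.parse_iri()
                self.expect("rpar")
                doc.axioms.append(TransitiveProperty(prop))
                return
            if head == _ANNOTATION_AXIOM:
                doc.parsed_axiom_count -= 1  # annotations never count as logical axioms
                self.skip_axiom_annotations()
                prop = self.parse_iri()
                subject = self.parse_iri()
                tok = self.peek()
                if tok is not None and tok.kind == "string":
                    value = self.parse_literal()
                    self.expect("rpar")
                    doc.axioms.append(AnnotationAssertion(subject, prop, value))
                else:
                    # IRI- or node-valued annotation: irrelevant to this toolkit
                    self.skip_balanced()
                return
            raise _Unsupported(head)
        except _Unsupported as exc:
            # resynchronise: skip to the close of this axiom
            self.i = start
            self.skip_balanced()
            doc.dropped_axiom_count += 1
            logger.warning("dropping axiom outside the EL subset: %s (%s)", head, exc)


def parse_ofn(text: str) -> ParsedDocument:
    """Parse one functional-syntax document (no import resolution)."""
    return _Parser(text).parse_document()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _render_iri(iri: IRI) -> str:
    return f"<{iri}>"


def render_expr(expr: ClassExpr) -> str:
    if isinstance(expr, NamedClass):
        if expr.iri == OWL_THING:
            return "owl:Thing"
        if expr.iri == OWL_NOTHING:
            return "owl:Nothing"
        return _render_iri(expr.iri)
    if isinstance(expr, Existential):
        return f"ObjectSomeValuesFrom({_render_iri(expr.prop)} {render_expr(expr.filler)})"
    if isinstance(expr, Conjunction):
        inner = " ".join(render_expr(o) for o in expr.operands_sorted())
        return f"ObjectIntersectionOf({inner})"
    raise TypeError(type(expr))


def render_axiom(axiom: Axiom) -> str:
    if isinstance(axiom, SubClassOf):
        return f"SubClassOf({render_expr(axiom.sub)} {render_expr(axiom.sup)})"
    if isinstance(axiom, EquivalentClasses):
        inner = " ".join(render_expr(e) for e in sorted(axiom.exprs, key=expr_sort_key))
        return f"EquivalentClasses({inner})"
    if isinstance(axiom, SubPropertyOf):
        return f"SubObjectPropertyOf({_render_iri(axiom.sub)} {_render_iri(axiom.sup)})"
    if isinstance(axiom, PropertyChain):
        return (
            "SubObjectPropertyOf(ObjectPropertyChain("
            f"{_render_iri(axiom.first)} {_render_iri(axiom.second)}) {_render_iri(axiom.implied)})"
        )
    if isinstance(axiom, TransitiveProperty):
        return f"TransitiveObjectProperty({_render_iri(axiom.prop)})"
    if isinstance(axiom, AnnotationAssertion):
        value = axiom.value.replace("\\", "\\\\").replace('"', '\\"')
        return f'AnnotationAssertion({_render_iri(axiom.prop)} {_render_iri(axiom.subject)} "{value}")'
    raise TypeError(type(axiom))


def serialize_ofn(
    ontology_iri: IRI,
    axioms: list[Axiom],
    classes: set[IRI] | None = None,
    properties: set[IRI] | None = None,
    imports: list[IRI] | None = None,
) -> str:
    """Write a functional-syntax document; output is byte-deterministic."""
    lines = [
        'Prefix(owl:=<http://www.w3.org/2002/07/owl#>)',
        'Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)',
        f"Ontology(<{ontology_iri}>",
    ]
    for imp in imports or []:
        lines.append(f"Import(<{imp}>)")
    for cls in sorted(classes or ()):
        lines.append(f"Declaration(Class(<{cls}>))")
    for prop in sorted(properties or ()):
        lines.append(f"Declaration(ObjectProperty(<{prop}>))")
    for axiom in axioms:
        lines.append(render_axiom(axiom))
    lines.append(")")
    return "\n".join(lines) + "\n"
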