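"""Manchester OWL Syntax parser for the EL-expressible query fragment.

Grammar::

    expr        := conj
    conj        := prim ("and" prim)*
    prim        := quotedLabel | bareToken | fullIRI | "(" expr ")" | restriction
    restriction := propertyToken "some" prim

Keywords outside EL (``or``, ``not``, ``only``, ``min``, ``max``,
``exactly``, ``value``) are rejected outright: silently approximating them
would change query semantics.  Tokens are resolved against one ontology via
:func:`obakit.label_index.resolve`; an unresolvable token is a parse failure
and the service layer maps every parse failure to an empty result set.
"""

from __future__ import annotations

import re
from typing import Callable, Optional

from .model import ClassExpr, Existential, IRI, NamedClass, conj

Resolver = Callable[[str, str], Optional[IRI]]  # (token, kind) -> IRI | None


class ManchesterParseError(ValueError):
    """Query string is not a valid EL class expression for this ontology."""


_TOKEN_RE = re.compile(
    r"""
    \s+
  | (?P<quoted>'[^']*')
  | (?P<iri><[^<>\s]*>)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<word>[A-Za-z0-9_.\-:]+)
    """,
    re.VERBOSE,
)

_FORBIDDEN = {"or", "not", "only", "min", "max", "exactly", "value", "self", "that", "inverse"}
_KEYWORDS = {"and", "some"}


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None or m.end() == i:
            raise ManchesterParseError(f"unexpected character {text[i]!r} at offset {i}")
        i = m.end()
        if m.lastgroup is not None:
            tokens.append(m.group(0))
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], resolver: Resolver) -> None:
        self.tokens = tokens
        self.i = 0
        self.resolver = resolver

    def peek(self) -> Optional[str]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ManchesterParseError("unexpected end of expression")
        self.i += 1
        return tok

    def parse_expr(self) -> ClassExpr:
        operands = [self.parse_prim()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            operands.append(self.parse_prim())
        return conj(*operands) if len(operands) > 1 else operands[0]

    def parse_prim(self) -> ClassExpr:
        tok = self.next()
        if tok == "(":
            inner = self.parse_expr()
            if self.next() != ")":
                raise ManchesterParseError("expected ')'")
            return inner
        low = tok.lower()
        if low in _FORBIDDEN:
            raise ManchesterParseError(f"construct {tok!r} is outside the EL query fragment")
        if low in _KEYWORDS or tok in (")",):
            raise ManchesterParseError(f"unexpected {tok!r}")
        # restriction?  one-token lookahead for "some"
        nxt = self.peek()
        if nxt is not None and nxt.lower() == "some":
            self.next()
            prop = self.resolve(tok, "property")
            filler = self.parse_prim()
            return Existential(prop, filler)
        return NamedClass(self.resolve(tok, "class"))

    def resolve(self, token: str, kind: str) -> IRI:
        iri = self.resolver(token, kind)
        if iri is None:
            raise ManchesterParseError(f"cannot resolve {token!r} as a {kind}")
        return iri


def parse_manchester(text: str, resolver: Resolver) -> ClassExpr:
    """Parse a Manchester query string into an EL class expression.

    Raises :class:`ManchesterParseError` on syntax errors, non-EL constructs
    and unresolvable tokens.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ManchesterParseError("empty query")
    parser = _Parser(tokens, resolver)
    expr = parser.parse_expr()
    if parser.peek() is not None:
        raise ManchesterParseError(f"trailing input starting at {parser.peek()!r}")
    return expr


def render_manchester(expr: ClassExpr, label_of: Callable[[IRI], str]) -> str:
    """Pretty-print an expression back to Manchester syntax (labels quoted)."""
    from .model import Conjunction

    def quote(iri: IRI) -> str:
        label = label_of(iri)
        return f"'{label}'" if (" " in label or "'" in label) else label

    def render(e: ClassExpr, nested: bool) -> str:
        if isinstance(e, NamedClass):
            return quote(e.iri)
        if isinstance(e, Existential):
            inner = render(e.filler, True)
            text = f"{quote(e.prop)} some {inner}"
            return f"({text})" if nested else text
        if isinstance(e, Conjunction):
            text = " and ".join(render(op, True) for op in e.operands_sorted())
            return f"({text})" if nested else text
        raise TypeError(type(e))

    return render(expr, False)
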