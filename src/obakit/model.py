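"""Core value types: OWL EL class expressions, axioms and ontology documents.

The toolkit works on the EL fragment of OWL: named classes, ``owl:Thing``,
``owl:Nothing``, intersections and existential restrictions, plus subclass /
equivalence axioms, role hierarchies and role chains of length two
(transitivity is the special case ``r o r -> r``).  Everything outside this
fragment is dropped at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

IRI = str

OWL_THING: IRI = "http://www.w3.org/2002/07/owl#Thing"
OWL_NOTHING: IRI = "http://www.w3.org/2002/07/owl#Nothing"
RDFS_LABEL: IRI = "http://www.w3.org/2000/01/rdf-schema#label"
IAO_DEFINITION: IRI = "http://purl.obolibrary.org/obo/IAO_0000115"

#: Reserved namespace for reasoner-internal class names.  Input documents must
#: never use it; no public result may contain it.
FRESH_NS: IRI = "urn:obakit:fresh#"


def local_name(iri: IRI) -> str:
    """Last path/fragment segment of an IRI (the conventional short form)."""
    for sep in ("#", "/", ":"):
        if sep in iri:
            tail = iri.rsplit(sep, 1)[1]
            if tail:
                return tail
    return iri


# ---------------------------------------------------------------------------
# Class expressions
# ---------------------------------------------------------------------------

class ClassExpr:
    """Base class for EL class expressions (immutable)."""

    __slots__ = ()

    def iris(self) -> Iterator[IRI]:
        """All class and property IRIs mentioned in the expression."""
        raise NotImplementedError


@dataclass(frozen=True, slots=True)
class NamedClass(ClassExpr):
    iri: IRI

    def iris(self) -> Iterator[IRI]:
        yield self.iri

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NamedClass({local_name(self.iri)!r})"


#: ``owl:Thing`` / ``owl:Nothing`` as expressions.
Top = NamedClass(OWL_THING)
Bottom = NamedClass(OWL_NOTHING)


@dataclass(frozen=True, slots=True)
class Existential(ClassExpr):
    """``ObjectSomeValuesFrom(property filler)``."""

    prop: IRI
    filler: ClassExpr

    def iris(self) -> Iterator[IRI]:
        yield self.prop
        yield from self.filler.iris()


@dataclass(frozen=True, slots=True)
class Conjunction(ClassExpr):
    """``ObjectIntersectionOf`` with order-insensitive equality.

    Use :func:`conj` to build one: it flattens nesting, removes ``owl:Thing``
    and duplicates, and collapses singleton intersections.
    """

    operands: frozenset[ClassExpr]

    def iris(self) -> Iterator[IRI]:
        for op in self.operands:
            yield from op.iris()

    def operands_sorted(self) -> list[ClassExpr]:
        return sorted(self.operands, key=expr_sort_key)


def conj(*operands: ClassExpr) -> ClassExpr:
    """Smart intersection constructor enforcing the Conjunction invariants."""
    flat: set[ClassExpr] = set()
    for op in operands:
        if isinstance(op, Conjunction):
            flat.update(op.operands)
        elif op == Top:
            continue
        else:
            flat.add(op)
    if not flat:
        return Top
    if len(flat) == 1:
        return next(iter(flat))
    return Conjunction(frozenset(flat))


def expr_sort_key(expr: ClassExpr) -> str:
    """Deterministic total order on expressions (used for serialization)."""
    if isinstance(expr, NamedClass):
        return "0" + expr.iri
    if isinstance(expr, Existential):
        return "1" + expr.prop + "\x00" + expr_sort_key(expr.filler)
    if isinstance(expr, Conjunction):
        return "2" + "\x00".join(expr_sort_key(o) for o in sorted(expr.operands, key=expr_sort_key))
    raise TypeError(type(expr))


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------

class Axiom:
    __slots__ = ()


@dataclass(frozen=True, slots=True)
class SubClassOf(Axiom):
    sub: ClassExpr
    sup: ClassExpr


@dataclass(frozen=True, slots=True)
class EquivalentClasses(Axiom):
    exprs: tuple[ClassExpr, ...]

    def __post_init__(self) -> None:
        if len(self.exprs) < 2:
            raise ValueError("EquivalentClasses needs at least two expressions")


@dataclass(frozen=True, slots=True)
class SubPropertyOf(Axiom):
    sub: IRI
    sup: IRI


@dataclass(frozen=True, slots=True)
class PropertyChain(Axiom):
    """``first o second`` is a sub-property of ``implied``."""

    first: IRI
    second: IRI
    implied: IRI


@dataclass(frozen=True, slots=True)
class TransitiveProperty(Axiom):
    prop: IRI

    def as_chain(self) -> PropertyChain:
        return PropertyChain(self.prop, self.prop, self.prop)


@dataclass(frozen=True, slots=True)
class AnnotationAssertion(Axiom):
    subject: IRI
    prop: IRI
    value: str


LogicalAxiom = Union[SubClassOf, EquivalentClasses, SubPropertyOf, PropertyChain, TransitiveProperty]


def class_axioms(axioms: Iterable[Axiom]) -> list[Axiom]:
    """Logical axioms only (annotations stripped)."""
    return [a for a in axioms if not isinstance(a, AnnotationAssertion)]


# ---------------------------------------------------------------------------
# Ontology document
# ---------------------------------------------------------------------------

@dataclass
class OntologyDocument:
    """One loaded ontology, with its imports closure merged in.

    ``labels`` carries an entry for *every* class and property: the asserted
    ``rdfs:label`` where present, otherwise the IRI local name.  ``definitions``
    carries only asserted textual definitions.
    """

    document_uri: IRI
    axioms: list[Axiom] = field(default_factory=list)
    classes: set[IRI] = field(default_factory=set)
    properties: set[IRI] = field(default_factory=set)
    labels: dict[IRI, str] = field(default_factory=dict)
    definitions: dict[IRI, str] = field(default_factory=dict)
    #: number of parsed axioms dropped for falling outside the EL subset
    dropped_axiom_count: int = 0

    def label_of(self, iri: IRI) -> str:
        return self.labels.get(iri, local_name(iri))

    def knows(self, iri: IRI) -> bool:
        return iri in self.classes or iri in self.properties
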