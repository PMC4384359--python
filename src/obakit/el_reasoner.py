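"""Consequence-based classification for OWL EL ontologies.

The classifier follows the standard EL++ completion-rule calculus: axioms are
first normalised (fresh names for complex subexpressions) into the normal
forms

* NF1  ``A  ⊑ B``
* NF2  ``A1 ⊓ A2 ⊑ B``
* NF3  ``A  ⊑ ∃r.B``
* NF4  ``∃r.A ⊑ B``

plus role inclusions ``r ⊑ s`` and role chains ``r∘s ⊑ t`` (transitivity is
the chain ``r∘r ⊑ r``), and then saturated to a fixpoint with an indexed
worklist.  Saturation is polynomial in the input and its result is
independent of rule-application order.

Fresh names live in a reserved namespace and are projected out of every
public result.  Unsatisfiable classes (subclasses of ``owl:Nothing``) are
reported by :func:`classify` and excluded from query answers.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .model import (
    Axiom,
    Bottom,
    ClassExpr,
    Conjunction,
    EquivalentClasses,
    Existential,
    FRESH_NS,
    IRI,
    NamedClass,
    OntologyDocument,
    OWL_NOTHING,
    OWL_THING,
    PropertyChain,
    SubClassOf,
    SubPropertyOf,
    Top,
    TransitiveProperty,
    class_axioms,
)

logger = logging.getLogger(__name__)


def is_fresh(iri: IRI) -> bool:
    return iri.startswith(FRESH_NS)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedAxiomSet:
    nf1: set[tuple[IRI, IRI]] = field(default_factory=set)
    nf2: set[tuple[IRI, IRI, IRI]] = field(default_factory=set)  # (A1, A2, B)
    nf3: set[tuple[IRI, IRI, IRI]] = field(default_factory=set)  # (A, r, B)
    nf4: set[tuple[IRI, IRI, IRI]] = field(default_factory=set)  # (r, A, B)
    roles: set[tuple[IRI, IRI]] = field(default_factory=set)
    chains: set[tuple[IRI, IRI, IRI]] = field(default_factory=set)
    fresh: set[IRI] = field(default_factory=set)

    def class_names(self) -> set[IRI]:
        names: set[IRI] = set()
        for a, b in self.nf1:
            names.update((a, b))
        for a1, a2, b in self.nf2:
            names.update((a1, a2, b))
        for a, _r, b in self.nf3:
            names.update((a, b))
        for _r, a, b in self.nf4:
            names.update((a, b))
        return names


class NonELAxiomError(ValueError):
    """An axiom outside the accepted EL subset reached the reasoner."""


def normalize(axioms: Iterable[Axiom], allow: frozenset[IRI] = frozenset()) -> NormalizedAxiomSet:
    """Rewrite EL axioms into the NF1–NF4 normal forms.

    Complex subexpressions receive fresh definitional names (both inclusion
    directions asserted), which makes the rewriting a conservative extension:
    subsumptions between original named classes are preserved exactly.
    ``allow`` whitelists reserved-namespace names the caller introduced itself
    (the query machinery's Q class).
    """
    out = NormalizedAxiomSet()
    counter = itertools.count()
    defined: dict[ClassExpr, IRI] = {}
    todo: list[tuple[ClassExpr, ClassExpr]] = []

    def name_of(expr: ClassExpr) -> IRI:
        """A named handle for ``expr`` (fresh definition when complex)."""
        if isinstance(expr, NamedClass):
            if is_fresh(expr.iri) and expr.iri not in allow:
                # input must not use the reserved namespace
                raise NonELAxiomError(f"reserved namespace in input: {expr.iri}")
            return expr.iri
        existing = defined.get(expr)
        if existing is not None:
            return existing
        fresh = f"{FRESH_NS}X{next(counter)}"
        defined[expr] = fresh
        out.fresh.add(fresh)
        node = NamedClass(fresh)
        todo.append((node, expr))
        todo.append((expr, node))
        return fresh

    for axiom in class_axioms(axioms):
        if isinstance(axiom, SubClassOf):
            todo.append((axiom.sub, axiom.sup))
        elif isinstance(axiom, EquivalentClasses):
            first = axiom.exprs[0]
            for other in axiom.exprs[1:]:
                todo.append((first, other))
                todo.append((other, first))
        elif isinstance(axiom, SubPropertyOf):
            out.roles.add((axiom.sub, axiom.sup))
        elif isinstance(axiom, PropertyChain):
            out.chains.add((axiom.first, axiom.second, axiom.implied))
        elif isinstance(axiom, TransitiveProperty):
            out.chains.add((axiom.prop, axiom.prop, axiom.prop))
        else:
            raise NonELAxiomError(f"unsupported axiom reached normalize: {axiom!r}")

    while todo:
        sub, sup = todo.pop()
        # trivial forms
        if sup == Top or sub == Bottom:
            continue
        if isinstance(sup, Conjunction):
            for op in sup.operands:
                todo.append((sub, op))
            continue
        if isinstance(sup, Existential):
            filler = name_of(sup.filler)
            if isinstance(sub, NamedClass):
                out.nf3.add((sub.iri, sup.prop, filler))
            else:
                out.nf3.add((name_of(sub), sup.prop, filler))
            continue
        # sup is named from here on
        assert isinstance(sup, NamedClass)
        if isinstance(sub, NamedClass):
            out.nf1.add((sub.iri, sup.iri))
        elif isinstance(sub, Existential):
            out.nf4.add((sub.prop, name_of(sub.filler), sup.iri))
        elif isinstance(sub, Conjunction):
            ops = [name_of(op) for op in sub.operands_sorted()]
            # binarise left-to-right with fresh intermediates
            acc = ops[0]
            for nxt in ops[1:-1]:
                inter = f"{FRESH_NS}X{next(counter)}"
                out.fresh.add(inter)
                out.nf2.add((acc, nxt, inter))
                acc = inter
            out.nf2.add((acc, ops[-1], sup.iri))
        else:  # pragma: no cover - exhaustive over ClassExpr
            raise NonELAxiomError(f"unsupported expression {sub!r}")
    return out


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def _role_closure(pairs: set[tuple[IRI, IRI]], roles: set[IRI]) -> dict[IRI, set[IRI]]:
    """Reflexive-transitive closure of the role hierarchy: r -> its superroles."""
    superroles: dict[IRI, set[IRI]] = {r: {r} for r in roles}
    adjacency: dict[IRI, set[IRI]] = defaultdict(set)
    for sub, sup in pairs:
        adjacency[sub].add(sup)
    for r in roles:
        stack = [r]
        while stack:
            cur = stack.pop()
            for nxt in adjacency.get(cur, ()):
                if nxt not in superroles[r]:
                    superroles[r].add(nxt)
                    stack.append(nxt)
    return superroles


@dataclass
class Saturation:
    """Raw fixpoint: subsumer sets over all (named + fresh) classes."""

    subsumers: dict[IRI, set[IRI]]
    edges: dict[IRI, set[tuple[IRI, IRI]]]  # role -> {(source, target)}

    def holds(self, sub: IRI, sup: IRI) -> bool:
        if sup == OWL_THING or sub == OWL_NOTHING or sub == sup:
            return True
        if OWL_NOTHING in self.subsumers.get(sub, ()):  # unsatisfiable: below everything
            return True
        return sup in self.subsumers.get(sub, ())

    def unsatisfiable(self, iri: IRI) -> bool:
        return OWL_NOTHING in self.subsumers.get(iri, ())


def saturate(n: NormalizedAxiomSet) -> Saturation:
    """Run the EL completion rules to their fixpoint."""
    classes = n.class_names() | {OWL_THING}
    all_roles = {r for _a, r, _b in n.nf3} | {r for r, _a, _b in n.nf4}
    for sub, sup in n.roles:
        all_roles.update((sub, sup))
    for r, s, t in n.chains:
        all_roles.update((r, s, t))
    superroles = _role_closure(n.roles, all_roles)

    nf1_idx: dict[IRI, list[IRI]] = defaultdict(list)
    for a, b in n.nf1:
        nf1_idx[a].append(b)
    nf2_idx: dict[IRI, list[tuple[IRI, IRI]]] = defaultdict(list)  # operand -> (other, rhs)
    for a1, a2, b in n.nf2:
        nf2_idx[a1].append((a2, b))
        if a1 != a2:
            nf2_idx[a2].append((a1, b))
    nf3_idx: dict[IRI, list[tuple[IRI, IRI]]] = defaultdict(list)  # A' -> (r, B)
    for a, r, b in n.nf3:
        nf3_idx[a].append((r, b))
    nf4_idx: dict[tuple[IRI, IRI], list[IRI]] = defaultdict(list)  # (r, B') -> C
    nf4_roles_of: dict[IRI, set[IRI]] = defaultdict(set)  # B' -> roles with an NF4 entry
    for r, a, b in n.nf4:
        nf4_idx[(r, a)].append(b)
        nf4_roles_of[a].add(r)
    chain_left: dict[IRI, list[tuple[IRI, IRI]]] = defaultdict(list)  # r -> (s, t)
    chain_right: dict[IRI, list[tuple[IRI, IRI]]] = defaultdict(list)  # s -> (r, t)
    for r, s, t in n.chains:
        chain_left[r].append((s, t))
        chain_right[s].append((r, t))

    subsumers: dict[IRI, set[IRI]] = {c: set() for c in classes}
    out_edges: dict[IRI, dict[IRI, set[IRI]]] = defaultdict(lambda: defaultdict(set))  # src -> role -> targets
    in_edges: dict[IRI, set[tuple[IRI, IRI]]] = defaultdict(set)  # tgt -> {(role, src)}
    edge_set: dict[IRI, set[tuple[IRI, IRI]]] = defaultdict(set)  # role -> {(src, tgt)}

    queue: list[tuple] = []

    def add_sub(cls: IRI, sup: IRI) -> None:
        bucket = subsumers.setdefault(cls, set())
        if sup not in bucket:
            bucket.add(sup)
            queue.append(("s", cls, sup))

    def add_edge(role: IRI, src: IRI, tgt: IRI) -> None:
        for sup_role in superroles.get(role, (role,)):
            if (src, tgt) not in edge_set[sup_role]:
                edge_set[sup_role].add((src, tgt))
                out_edges[src][sup_role].add(tgt)
                in_edges[tgt].add((sup_role, src))
                queue.append(("e", sup_role, src, tgt))

    for c in classes:
        add_sub(c, c)
        add_sub(c, OWL_THING)

    while queue:
        item = queue.pop()
        if item[0] == "s":
            _, cls, sup = item
            # CR1: sup ⊑ B
            for b in nf1_idx.get(sup, ()):
                add_sub(cls, b)
            # CR2: sup ⊓ other ⊑ B with other already a subsumer
            mine = subsumers[cls]
            for other, b in nf2_idx.get(sup, ()):
                if other in mine:
                    add_sub(cls, b)
            # CR3: sup ⊑ ∃r.B
            for role, b in nf3_idx.get(sup, ()):
                add_edge(role, cls, b)
            # CR4 (new subsumer on an edge target): ∃r.sup ⊑ C
            roles_involved = nf4_roles_of.get(sup)
            if roles_involved:
                for role, src in in_edges.get(cls, ()):
                    if role in roles_involved:
                        for c_out in nf4_idx.get((role, sup), ()):
                            add_sub(src, c_out)
            # CR5 (bottom propagates backwards over edges)
            if sup == OWL_NOTHING:
                for _role, src in in_edges.get(cls, ()):
                    add_sub(src, OWL_NOTHING)
        else:
            _, role, src, tgt = item
            # CR4 (new edge): some subsumer of tgt fires an NF4 axiom
            for b_prime in list(subsumers.get(tgt, ())):
                for c_out in nf4_idx.get((role, b_prime), ()):
                    add_sub(src, c_out)
            # CR5
            if OWL_NOTHING in subsumers.get(tgt, ()):
                add_sub(src, OWL_NOTHING)
            # role chains: r∘s ⊑ t
            for s_role, t_role in chain_left.get(role, ()):
                for tgt2 in list(out_edges.get(tgt, {}).get(s_role, ())):
                    add_edge(t_role, src, tgt2)
            for r_role, t_role in chain_right.get(role, ()):
                for _role2, src0 in list(in_edges.get(src, ())):
                    if _role2 == r_role:
                        add_edge(t_role, src0, tgt)
    return Saturation(subsumers=subsumers, edges=dict(edge_set))


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """Inferred subsumption structure over the named classes of one ontology.

    ``subsumers[A]`` is the full reflexive-transitive subsumer set of A
    restricted to named classes (unsatisfiable classes subsume everything, as
    classes equivalent to ``owl:Nothing`` do); ``direct_sub`` maps a class to
    its direct (non-redundant) subclasses, with equivalence groups collapsed
    onto a canonical representative; ``unsatisfiable`` lists classes entailed
    to be subclasses of ``owl:Nothing``.
    """

    classes: set[IRI]
    subsumers: dict[IRI, frozenset[IRI]]
    equivalents: dict[IRI, frozenset[IRI]]
    direct_sub: dict[IRI, frozenset[IRI]]
    unsatisfiable: frozenset[IRI]

    def subsumes(self, sup: IRI, sub: IRI) -> bool:
        """Entailed ``sub ⊑ sup`` (reflexive)."""
        if sup == OWL_THING or sub == OWL_NOTHING:
            return True
        return sup in self.subsumers.get(sub, ())

    def subclasses_of(self, iri: IRI) -> set[IRI]:
        return {c for c in self.classes if c != iri and self.subsumes(iri, c)}

    def superclasses_of(self, iri: IRI) -> set[IRI]:
        return {c for c in self.subsumers.get(iri, ()) if c != iri}

    def equivalents_of(self, iri: IRI) -> set[IRI]:
        return set(self.equivalents.get(iri, frozenset({iri})))

    def subsumption_pairs(self) -> set[tuple[IRI, IRI]]:
        """All entailed (sub, sup) pairs over named classes, sub ≠ sup."""
        return {
            (sub, sup)
            for sub, sups in self.subsumers.items()
            for sup in sups
            if sub != sup
        }

    def to_json(self) -> str:
        payload = {
            "direct_sub": {
                cls: sorted(subs) for cls, subs in sorted(self.direct_sub.items()) if subs
            },
            "equivalents": sorted(
                sorted(group) for group in {self.equivalents[c] for c in self.classes} if len(group) > 1
            ),
            "unsatisfiable": sorted(self.unsatisfiable),
        }
        return json.dumps(payload, indent=2, sort_keys=False)


def _build_taxonomy(sat: Saturation, named: set[IRI]) -> Taxonomy:
    named = set(named)
    unsat = frozenset(c for c in named if sat.unsatisfiable(c))
    subsumers: dict[IRI, frozenset[IRI]] = {}
    for cls in named:
        if cls in unsat:
            subsumers[cls] = frozenset(named)  # ⊥-equivalent: below everything
        else:
            subsumers[cls] = frozenset(
                s for s in sat.subsumers.get(cls, {cls}) if s in named
            ) | {cls}

    equivalents: dict[IRI, frozenset[IRI]] = {}
    for cls in named:
        group = frozenset(
            other for other in subsumers[cls] if cls in subsumers.get(other, ())
        )
        equivalents[cls] = group

    # canonical representative per equivalence group (lexicographic minimum)
    rep = {cls: min(equivalents[cls]) for cls in named}
    reps = sorted({rep[c] for c in named if c not in unsat})
    strict: dict[IRI, set[IRI]] = {
        r: {rep[s] for s in subsumers[r] if rep[s] != r} for r in reps
    }
    direct_sub: dict[IRI, set[IRI]] = {r: set() for r in reps}
    for sub_rep in reps:
        for sup_rep in strict[sub_rep]:
            if sup_rep not in direct_sub:
                continue
            # direct unless some representative lies strictly between
            if not any(sup_rep in strict[mid] for mid in strict[sub_rep] if mid != sup_rep and mid in strict):
                direct_sub[sup_rep].add(sub_rep)
    return Taxonomy(
        classes=named,
        subsumers=subsumers,
        equivalents=equivalents,
        direct_sub={k: frozenset(v) for k, v in direct_sub.items()},
        unsatisfiable=unsat,
    )


def classify(doc: OntologyDocument) -> Taxonomy:
    """Compute the inferred taxonomy of a loaded ontology."""
    sat = saturate(normalize(doc.axioms))
    return _build_taxonomy(sat, set(doc.classes))


# ---------------------------------------------------------------------------
# Class-expression queries
# ---------------------------------------------------------------------------

_QUERY_NAME = FRESH_NS + "Query"

QUERY_TYPES = ("subclass", "superclass", "equivalent")


def query_expression(
    doc: OntologyDocument,
    expr: ClassExpr,
    qtype: str = "subclass",
    direct_only: bool = False,
) -> set[IRI]:
    """Named classes answering ``expr`` under the given query type.

    A fresh class ``Q ≡ expr`` is added and the extended ontology is
    re-saturated.  Subsumption is reflexive, so sub- and superclass answers
    include classes *equivalent* to the expression (for a named-class query,
    the class itself): everything subsumed by the expression satisfies the
    query.  Q itself, ``owl:Thing``, ``owl:Nothing`` and unsatisfiable
    classes are excluded.  Any unknown IRI in ``expr`` yields the empty set.
    """
    if qtype not in QUERY_TYPES:
        raise ValueError(f"unknown query type {qtype!r}")
    for iri in expr.iris():
        if iri in (OWL_THING, OWL_NOTHING):
            continue
        if not doc.knows(iri):
            logger.warning("query uses IRI unknown to %s: %s", doc.document_uri, iri)
            return set()

    axioms: list[Axiom] = list(class_axioms(doc.axioms))
    axioms.append(EquivalentClasses((NamedClass(_QUERY_NAME), expr)))
    renamed = _QUERY_NAME
    sat = saturate(normalize(axioms, allow=frozenset({renamed})))

    named = {c for c in doc.classes}
    unsat = {c for c in named if sat.unsatisfiable(c)}
    q_unsat = sat.unsatisfiable(renamed)

    if qtype == "subclass":
        answers = {c for c in named if sat.holds(c, renamed)}
    elif qtype == "superclass":
        if q_unsat:
            answers = set(named)  # ⊥ is below every class
        else:
            answers = {c for c in named if sat.holds(renamed, c)}
    else:  # equivalent
        answers = {c for c in named if sat.holds(c, renamed) and sat.holds(renamed, c)}
    answers -= unsat
    answers.discard(renamed)

    if direct_only and qtype in ("subclass", "superclass") and answers:
        answers = _direct_answers(sat, answers, renamed, qtype)
    return answers


def _direct_answers(sat: Saturation, answers: set[IRI], query: IRI, qtype: str) -> set[IRI]:
    """Most specific (superclass query) / most general (subclass) answers."""

    def strictly_below(a: IRI, b: IRI) -> bool:
        return sat.holds(a, b) and not sat.holds(b, a)

    direct: set[IRI] = set()
    for cand in answers:
        if qtype == "subclass":
            # no other answer strictly between cand and the query
            blocked = any(
                strictly_below(cand, other) and not (sat.holds(other, query) and sat.holds(query, other))
                for other in answers
                if other != cand and not (sat.holds(cand, other) and sat.holds(other, cand))
            )
        else:
            blocked = any(
                strictly_below(other, cand) and not (sat.holds(other, query) and sat.holds(query, other))
                for other in answers
                if other != cand and not (sat.holds(cand, other) and sat.holds(other, cand))
            )
        if not blocked:
            direct.add(cand)
    return direct
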