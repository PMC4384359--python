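"""Reference EL subsumption oracle: naive derive-until-fixpoint.

This is an intentionally unoptimised second implementation used to validate
the worklist reasoner in :mod:`obakit.el_reasoner`.  It never normalises the
input.  Instead it builds the canonical model directly over the *original*
axioms: the domain has one element per named class and one per existential
filler expression, and membership facts ``S(element, expression)`` are
recomputed round after round with structural rules (conjunction
introduction/elimination, existential introduction/elimination, axiom
application, role hierarchy, role chains, bottom propagation) until nothing
changes.  ``A ⊑ B`` holds iff the element of A ends up satisfying B.

Complexity is far worse than the worklist algorithm; use it only at toy
scale.
"""

from __future__ import annotations

from typing import Iterable

from .model import (
    Axiom,
    Bottom,
    ClassExpr,
    Conjunction,
    EquivalentClasses,
    Existential,
    IRI,
    NamedClass,
    PropertyChain,
    SubClassOf,
    SubPropertyOf,
    Top,
    TransitiveProperty,
    class_axioms,
)


def _subexpressions(expr: ClassExpr, into: set[ClassExpr]) -> None:
    if expr in into:
        return
    into.add(expr)
    if isinstance(expr, Conjunction):
        for op in expr.operands:
            _subexpressions(op, into)
    elif isinstance(expr, Existential):
        _subexpressions(expr.filler, into)


def entailed_subsumptions(
    axioms: Iterable[Axiom], named_classes: set[IRI]
) -> tuple[set[tuple[IRI, IRI]], set[IRI]]:
    """All entailed ``(sub, sup)`` pairs (sub != sup) over ``named_classes``
    plus the set of unsatisfiable classes.

    Unsatisfiable classes are completed to subsume under every named class
    (they are equivalent to ``owl:Nothing``), matching the public Taxonomy
    contract.
    """
    logical = class_axioms(axioms)

    # inclusion pairs to apply (equivalences split into both directions)
    inclusions: list[tuple[ClassExpr, ClassExpr]] = []
    role_pairs: set[tuple[IRI, IRI]] = set()
    chains: set[tuple[IRI, IRI, IRI]] = set()
    for axiom in logical:
        if isinstance(axiom, SubClassOf):
            inclusions.append((axiom.sub, axiom.sup))
        elif isinstance(axiom, EquivalentClasses):
            exprs = axiom.exprs
            for i in range(len(exprs)):
                for j in range(len(exprs)):
                    if i != j:
                        inclusions.append((exprs[i], exprs[j]))
        elif isinstance(axiom, SubPropertyOf):
            role_pairs.add((axiom.sub, axiom.sup))
        elif isinstance(axiom, PropertyChain):
            chains.add((axiom.first, axiom.second, axiom.implied))
        elif isinstance(axiom, TransitiveProperty):
            chains.add((axiom.prop, axiom.prop, axiom.prop))

    # expression closure: all subexpressions of all axioms + every named class
    closure: set[ClassExpr] = {Top, Bottom}
    for lhs, rhs in inclusions:
        _subexpressions(lhs, closure)
        _subexpressions(rhs, closure)
    for cls in named_classes:
        closure.add(NamedClass(cls))
    conjunctions = [e for e in closure if isinstance(e, Conjunction)]
    existentials = [e for e in closure if isinstance(e, Existential)]

    # canonical elements: named classes and existential fillers
    elements: dict[ClassExpr, str] = {}
    for cls in sorted(named_classes):
        elements.setdefault(NamedClass(cls), f"c:{cls}")
    for e in existentials:
        elements.setdefault(e.filler, f"f:{id(e.filler)}")
    # deterministic re-id of filler elements
    elements = {expr: f"e{i}" for i, expr in enumerate(sorted(elements, key=_expr_key))}

    satisfies: dict[str, set[ClassExpr]] = {el: {deff, Top} for deff, el in elements.items()}
    edges: dict[IRI, set[tuple[str, str]]] = {}
    all_roles = {r for r, _s in role_pairs} | {s for _r, s in role_pairs}
    all_roles |= {e.prop for e in existentials}
    for r, s, t in chains:
        all_roles.update((r, s, t))
    for r in all_roles:
        edges[r] = set()

    changed = True
    while changed:
        changed = False

        def add_fact(el: str, expr: ClassExpr) -> None:
            nonlocal changed
            if expr not in satisfies[el]:
                satisfies[el].add(expr)
                changed = True

        def add_edge(role: IRI, src: str, tgt: str) -> None:
            nonlocal changed
            if (src, tgt) not in edges[role]:
                edges[role].add((src, tgt))
                changed = True

        for el in list(satisfies):
            facts = list(satisfies[el])
            for expr in facts:
                # conjunction elimination
                if isinstance(expr, Conjunction):
                    for op in expr.operands:
                        add_fact(el, op)
                # existential elimination: materialise the canonical successor
                if isinstance(expr, Existential) and expr.filler in elements:
                    add_edge(expr.prop, el, elements[expr.filler])
            # conjunction introduction
            for c in conjunctions:
                if c not in satisfies[el] and all(op in satisfies[el] for op in c.operands):
                    add_fact(el, c)
            # axiom application
            for lhs, rhs in inclusions:
                if lhs in satisfies[el]:
                    add_fact(el, rhs)

        # role hierarchy (asserted pairs, applied transitively by iteration)
        for sub, sup in role_pairs:
            for pair in list(edges.get(sub, ())):
                if pair not in edges[sup]:
                    edges[sup].add(pair)
                    changed = True
        # role chains
        for r, s, t in chains:
            succ_s: dict[str, set[str]] = {}
            for src, tgt in edges.get(s, ()):
                succ_s.setdefault(src, set()).add(tgt)
            for src, mid in list(edges.get(r, ())):
                for tgt in succ_s.get(mid, ()):
                    add_edge(t, src, tgt)
        # existential introduction
        for e in existentials:
            for src, tgt in edges.get(e.prop, ()):
                if e.filler in satisfies[tgt]:
                    add_fact(src, e)
        # bottom propagation backwards over edges
        for role in edges:
            for src, tgt in list(edges[role]):
                if Bottom in satisfies[tgt]:
                    add_fact(src, Bottom)

    unsat = {cls for cls in named_classes if Bottom in satisfies[elements[NamedClass(cls)]]}
    pairs: set[tuple[IRI, IRI]] = set()
    for sub in named_classes:
        if sub in unsat:
            pairs.update((sub, sup) for sup in named_classes if sup != sub)
            continue
        el = elements[NamedClass(sub)]
        for sup in named_classes:
            if sup != sub and NamedClass(sup) in satisfies[el]:
                pairs.add((sub, sup))
    return pairs, unsat


def _expr_key(expr: ClassExpr) -> str:
    from .model import expr_sort_key

    return expr_sort_key(expr)
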