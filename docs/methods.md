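# Methods

## Scope and model

`obakit` operates on the OWL EL fragment: named classes, `owl:Thing`,
`owl:Nothing`, intersection, existential restriction; `SubClassOf`,
`EquivalentClasses`, `SubObjectPropertyOf`, property chains of length two,
`TransitiveObjectProperty` (sugar for the chain `r∘r ⊑ r`), plus
`rdfs:label` and IAO_0000115 (textual definition) annotations.  EL admits
polynomial-time classification and covers the bulk of the large biomedical
ontologies; everything outside the fragment is dropped at load time with a
warning, mirroring how an EL reasoner treats out-of-profile axioms.  Input is
OWL Functional-Style Syntax only; converting RDF/XML or OBO flatfiles is a
pre-processing step outside this package.  Imports are resolved exclusively
through a local JSON catalog (`{"ontologyIRI": "path.ofn"}`); there is no
network access anywhere, which keeps loading reproducible.

## Classification calculus

Axioms are normalised into the standard EL normal forms

* NF1 `A ⊑ B`
* NF2 `A₁ ⊓ A₂ ⊑ B`
* NF3 `A ⊑ ∃r.B`
* NF4 `∃r.A ⊑ B`

with fresh definitional names (namespace `urn:obakit:fresh#`, asserted in
both inclusion directions) for complex subexpressions; n-ary conjunctions are
binarised left-to-right over a deterministic operand order.  The rewriting is
a conservative extension: subsumptions between original named classes are
preserved exactly.  Saturation runs the completion rules — subsumer
propagation through NF1/NF2, edge creation from NF3, edge-target subsumers
firing NF4, role-hierarchy lifting of edges, chain composition, and backward
propagation of `owl:Nothing` over edges — with an indexed worklist.  The
fixpoint is order-independent; all public iteration orders are sorted, so
outputs are byte-stable.  Fresh names are projected out of every result.

Unsatisfiable classes (`A ⊑ ⊥`) are reported by classification and treated
as equivalent to `owl:Nothing`, i.e. their subsumer set is completed to all
named classes — the semantically complete reading.  They are excluded from
all query answers but kept in the taxonomy as diagnostics.

### Validation oracle

`obakit.naive_reasoner` is a second, independent implementation used only for
testing: it never normalises, instead building the canonical model directly
over the original axioms (one domain element per named class and per
existential filler expression) and recomputing structural rules — conjunction
introduction/elimination, existential introduction/elimination, axiom
application, role hierarchy, chains, bottom propagation — in naive
derive-until-fixpoint rounds.  `A ⊑ B` holds iff A's element satisfies B.
The two code paths share no reasoning machinery, so agreement on random
ontologies is a meaningful check.  Its complexity is far worse than the
worklist reasoner; it is only run at toy scale (≤ 30 classes).

## Queries

A query expression is answered by adding a fresh class `Q ≡ expr` and
re-saturating the extended axiom set (correctness over speed at desk scale;
per-document classification is cached, query saturations are not).
Subsumption is reflexive, so sub-/superclass answers include classes
*equivalent* to the expression — a defined class is retrieved by the query
for its own definition, and a named-class query returns that class itself.
`owl:Thing`, `owl:Nothing`, the fresh Q and unsatisfiable classes are never
answered.  `direct_only` keeps only the most general (subclass) or most
specific (superclass) answers, with equivalence groups kept intact.  The
default query type is subclass.

The Manchester grammar accepted is exactly the EL-expressible fragment:

    expr        := prim ("and" prim)*
    prim        := 'quoted label' | bareToken | <IRI> | "(" expr ")" | restriction
    restriction := propertyToken "some" prim

`or`, `not`, `only`, cardinalities and `value` are rejected as parse errors
rather than silently approximated, because dropping parts of a *query*
(unlike dropping ontology axioms) would change its meaning.  Tokens resolve
within the ontology being queried: quoted labels by case-insensitive exact
label match, bare tokens by label match then IRI local-name match, bracketed
IRIs literally; ambiguity resolves to nothing, with a warning.  Every failure
mode — parse error, unresolved token, unknown ontology URI — produces an
empty result list for that ontology; no exception crosses the service
boundary.  Queries without an ontology URI fan out over the whole repository;
results group by ontology URI with each group sorted by class IRI.

## SPARQL expansion

The extension macro `OWL [subclass|superclass|equivalent] [FROM <iri>]
{ <manchester> }` is recognised in exactly two embeddings — a `VALUES`
data block and a `FILTER(?v IN (...))` term list — and replaced by the
answer IRIs.  The two forms are semantically equivalent on any dataset; the
test suite executes both against a generated N-Triples store with rdflib and
compares solution multisets.  An empty answer set becomes `VALUES ?v { }`
(legal) or `FILTER(false)` (a zero-term `IN` is not legal SPARQL).  The
concrete macro grammar is this package's own design; only its semantics are
fixed by the use cases it serves.

CURIE rewriting splits the final IRI segment at its *first* underscore
(`GO_0008150 → GO:0008150`, declaration base = IRI minus the local id).
Missing `PREFIX` declarations are prepended; a declaration already present in
the query always wins, so redefining `PREFIX GO:` to
`http://purl.uniprot.org/go/` retargets every emitted CURIE to that URI
scheme.  IRIs without the `LABEL_localid` pattern are left as full IRIs with
a warning.

## Literature retrieval

The analyzer lower-cases, tokenises on letter/digit runs and removes a fixed
33-entry English stop-word list.  Token positions count pre-removal slots, so
the stored phrase "tetralogy of fallot" occupies slots 0 and 2 and matches
text with the stop word present; slots between phrase tokens are not
otherwise constrained.  No stemming, no synonym expansion — retrieval sees
exactly the `rdfs:label` strings.

One semantic query contributes a disjunctive label query (one phrase per
distinct answer label); a document qualifies iff *every* supplied query has
at least one matching phrase.  Ranking is the sum over distinct matched
phrases of `idf = 1 + ln(N / (1 + df))`, ties broken by ascending document
id.  Any deterministic, documented ranking satisfies the retrieval contract;
this one was chosen for its simplicity and stability.  Highlighting reports
character spans per field, merging overlapping matches.

## Synthetic fixtures

The fixtures module generates every test input:

* **Cardiac toy** (12 classes): ToF defined as the conjunction of the four
  phenotypes, a ToF subtype, a muscular VSD, and `part_of` anatomy with
  transitivity.  No ToF⊑phenotype edge is asserted, so the worked example
  genuinely requires reasoning.
* **GO-like fragment** (9 classes): transitive `part_of`, parts of parts of
  the apoptotic process, and one class that is a part of both a regulation
  and (transitively) the apoptotic process — the unique answer to the
  conjunctive regulation query.
* **Random EL ontologies** for oracle testing: defaults of 24 classes, 3
  properties and 48 axioms (within the ≤30/≤4/≤60 envelope the oracle is
  meant for), drawn over all accepted axiom families above a layered
  subclass backbone, with a rare `A ⊓ B ⊑ ⊥` to exercise unsatisfiability.
  Instances are regenerated from a derived sub-seed until at least 10% of
  unordered class pairs are entailed-related, so the comparison is never
  vacuous.  Identical configs yield byte-identical files.
* **Corpus** (default 500 documents): distractor sentences whose vocabulary
  shares no token with any ontology label, plus planted label phrases; the
  emitted ground truth is the planted set closed under label-in-label phrase
  containment, i.e. the exact occurrence truth.  The first document mentions
  only "tetralogy of Fallot".  What the corpus does *not* emulate: real
  prose syntax, label inflection, synonyms/acronyms, entity-boundary
  ambiguity — passing retrieval tests therefore demonstrates Boolean/phrase
  correctness, not named-entity recognition performance on real text.
* **Triple store**: 12 toy proteins annotated to GO-fragment classes, written
  both with OBO-scheme and UniProt-scheme URIs to exercise prefix
  retargeting, with JSON ground truth alongside.

The two worked-example ontologies are also committed under `tests/data/` and
a test asserts the committed bytes equal the generator output.

## Numerical and degenerate-input choices

There are no floating-point tolerances anywhere except idf scores, which are
compared only by ordering.  Degenerate inputs are defined, not errors: empty
ontologies classify to a flat taxonomy; an empty completion prefix returns
every entry; an empty answer set yields a null label query that matches
nothing; duplicate `rdfs:label` values keep the first in document order with
a warning; entities without labels fall back to the IRI local name.
Duplicate corpus document ids are the one hard error in the search module,
since they would corrupt the index.

## Problem sizes

Default verification sizes: 200 random ontologies for reasoner/oracle
agreement, a 500-document corpus with 50 random retrieval queries, 10,000
random labels with 1,000 completion prefixes.  These sizes make the full
suite and the acceptance script each run in well under a minute on one CPU
while exercising every rule of the calculus (the random family generates
conjunctions, existentials on both sides, equivalences, hierarchies, chains
and disjointness-via-bottom).

## Known limitations

* EL only: no disjunction, negation, universal or cardinality restrictions,
  nominals, inverse roles or datatypes; such axioms are dropped, so
  classification is complete for the EL *projection* of a document.
* Query re-saturation is linear in ontology size per query; fine at desk
  scale, not engineered for million-axiom ontologies.
* Retrieval matches exact label phrases only — no synonyms, acronyms or
  morphological variants.
* The SPARQL macro recogniser assumes the Manchester text contains no `{`/`}`
  and does not parse the surrounding query beyond the two supported
  embeddings; the *output* is always validated as SPARQL 1.1 in tests.
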