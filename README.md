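# obakit — ontology-based data access for biomedical ontologies

Biomedical data and literature are annotated with OWL ontologies (GO, HPO,
Uberon, ...), but most access paths use only the *asserted* class names and
identifiers.  The knowledge the ontologies actually carry lives in their
axioms and only becomes visible through automated reasoning: a *Tetralogy of
Fallot* is, by its axioms, a kind of *ventricular septal defect* even when no
such subclass edge is written down.  `obakit` makes that inferred structure
queryable and then uses it to reach data:

* **EL classification.**  A built-in consequence-based reasoner computes the
  complete subsumption hierarchy `C ⊑ D` of an OWL EL ontology (conjunction
  `C ⊓ D`, existential restriction `∃r.C`, role hierarchies and role chains
  `r∘s ⊑ t`; axioms outside the EL profile are ignored with a warning).
  Classification runs the standard completion-rule saturation over the normal
  forms `A ⊑ B`, `A₁ ⊓ A₂ ⊑ B`, `A ⊑ ∃r.B`, `∃r.A ⊑ B` and is polynomial in
  the input.  Unsatisfiable classes (`A ⊑ ⊥`) are detected and reported.
* **Class-expression queries** in Manchester OWL syntax
  (`part_of some 'apoptotic process'`), answered as the named sub-, super- or
  equivalent classes of the expression, serialised as a JSON array of
  `{ontology, class, label, definition}` records.  Any failure — malformed
  expression, unresolvable label, unknown ontology — yields an empty result
  set, never an error.
* **Label completion** from a prefix trie over `rdfs:label` annotations.
* **SPARQL expansion.**  `VALUES ?v OWL {...}` / `FILTER(?v IN (OWL {...}))`
  blocks embedded in a SPARQL 1.1 query are replaced by the reasoner's answer
  set, optionally rewritten to CURIEs (`GO:0008150`) with the matching
  `PREFIX` declaration prepended — and retargetable to other URI schemes
  (e.g. `http://purl.uniprot.org/go/`) by redefining the prefix.
* **Literature retrieval.**  Documents (title/abstract/fulltext) are indexed
  with a lower-casing, stop-word-removing analyzer; the labels of all classes
  answering one or more semantic queries are searched as OR-combined phrases,
  multiple queries combine conjunctively, and hits are ranked by summed
  phrase idf with matched passages highlightable.

Inputs are OWL Functional-Style Syntax documents (EL subset) with imports
resolved through a local catalog — no network access.

## Worked example

The bundled cardiac toy ontology (`tests/data/cardio.ofn`) defines

```
EquivalentClasses(ToF, VSD ⊓ OverridingAorta ⊓ PulmonicStenosis ⊓ RightVentricularHypertrophy)
```

and asserts **no** subclass relation between ToF and any of the four
phenotypes.  A subclass query for the defect still retrieves it, by
reasoning:

```sh
obakit query --source tests/data/cardio.ofn --type subclass "'ventricular septal defect'"
```

```json
[
  {
    "ontology": "http://example.org/ontologies/cardio.owl",
    "class": "http://purl.obolibrary.org/obo/HP_0001629",
    "label": "ventricular septal defect",
    "definition": "An abnormality in which the ventricular septum has a hole."
  },
  {
    "ontology": "http://example.org/ontologies/cardio.owl",
    "class": "http://purl.obolibrary.org/obo/HP_0001636",
    "label": "tetralogy of Fallot",
    "definition": "A cardiac malformation defined by four co-occurring heart phenotypes."
  },
  {
    "ontology": "http://example.org/ontologies/cardio.owl",
    "class": "http://purl.obolibrary.org/obo/HP_0009999",
    "label": "tetralogy of Fallot with pulmonary atresia",
    "definition": null
  },
  {
    "ontology": "http://example.org/ontologies/cardio.owl",
    "class": "http://purl.obolibrary.org/obo/HP_0011623",
    "label": "muscular ventricular septal defect",
    "definition": null
  }
]
```

The answer set contains the queried class itself (subsumption is reflexive),
its asserted subclass (*muscular VSD*), and — inferred — *tetralogy of
Fallot* with its subtype.  Feeding these four labels into the literature
search retrieves articles that mention only "tetralogy of fallot"; embedding
the same query in SPARQL (`VALUES ?ontid OWL { ... }`) retrieves data
records annotated to any of the four classes.

Other subcommands: `obakit classify` (taxonomy JSON), `obakit complete
tetral` (label completion), `obakit expand` (SPARQL rewriting), `obakit
search` (corpus retrieval), `obakit fixtures` (regenerate all bundled
inputs).  Every subcommand prints its payload to stdout and diagnostics to
stderr, and exits 0 with an empty payload on query-level failures.

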