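"""Deterministic generators for every input the toolkit consumes.

Nothing is downloaded: the worked-example ontologies (a cardiac-phenotype toy
modelled on the Tetralogy-of-Fallot inference and a Gene-Ontology-like
``part_of`` fragment), random EL ontologies for oracle testing, a synthetic
literature corpus with planted label mentions, and a toy protein-annotation
triple store are all produced here, byte-identically for a given seed.

Toy IRIs follow the OBO Foundry pattern (``.../obo/GO_0006915``) so the
CURIE/prefix machinery is exercised honestly; none of the axioms claim to
reproduce the real HPO/GO content.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass

from .el_reasoner import classify
from .literature_search import Document, write_jsonl
from .model import (
    AnnotationAssertion,
    Axiom,
    Bottom,
    EquivalentClasses,
    Existential,
    IAO_DEFINITION,
    IRI,
    NamedClass,
    OntologyDocument,
    RDFS_LABEL,
    SubClassOf,
    SubPropertyOf,
    TransitiveProperty,
    conj,
)
from .ofn import serialize_ofn
from .ontology_store import load_ontology_text

OBO = "http://purl.obolibrary.org/obo/"
PART_OF = OBO + "BFO_0000050"

CARDIO_URI = "http://example.org/ontologies/cardio.owl"
GO_URI = "http://example.org/ontologies/go-fragment.owl"

PROTEIN_BASE = "http://example.org/uniprot/"
CORE = "http://example.org/core/"
CLASSIFIED_WITH = CORE + "classifiedWith"
PROTEIN_CLASS = CORE + "Protein"
UNIPROT_GO_BASE = "http://purl.uniprot.org/go/"


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_classes: int = 24
    n_properties: int = 3
    n_axioms: int = 48
    corpus_size: int = 500


# ---------------------------------------------------------------------------
# Worked-example ontologies
# ---------------------------------------------------------------------------

# cardiac phenotype toy
HP = {
    "abn_heart": OBO + "HP_0001627",
    "vsd": OBO + "HP_0001629",
    "muscular_vsd": OBO + "HP_0011623",
    "overriding_aorta": OBO + "HP_0002623",
    "pulmonic_stenosis": OBO + "HP_0001642",
    "rvh": OBO + "HP_0001667",
    "tof": OBO + "HP_0001636",
    "tof_subtype": OBO + "HP_0009999",
}
UBERON = {
    "heart": OBO + "UBERON_0000948",
    "aorta": OBO + "UBERON_0000947",
    "ventricle": OBO + "UBERON_0002082",
    "septum": OBO + "UBERON_0002094",
}

CARDIO_LABELS = {
    HP["abn_heart"]: "abnormal heart morphology",
    HP["vsd"]: "ventricular septal defect",
    HP["muscular_vsd"]: "muscular ventricular septal defect",
    HP["overriding_aorta"]: "overriding aorta",
    HP["pulmonic_stenosis"]: "pulmonic stenosis",
    HP["rvh"]: "right ventricular hypertrophy",
    HP["tof"]: "tetralogy of Fallot",
    HP["tof_subtype"]: "tetralogy of Fallot with pulmonary atresia",
    UBERON["heart"]: "heart",
    UBERON["aorta"]: "aorta",
    UBERON["ventricle"]: "cardiac ventricle",
    UBERON["septum"]: "interventricular septum",
    PART_OF: "part_of",
}


def cardio_ontology_text() -> str:
    """Functional-syntax text of the cardiac toy ontology.

    The Tetralogy-of-Fallot class is *defined* as the conjunction of the four
    key phenotypes; no subclass axiom between ToF and any of the four is
    asserted, so retrieving ToF under 'ventricular septal defect' requires
    reasoning.
    """
    part_of = PART_OF
    named = {iri: NamedClass(iri) for iri in CARDIO_LABELS if iri != part_of}
    axioms: list[Axiom] = [
        SubClassOf(named[HP["vsd"]], named[HP["abn_heart"]]),
        SubClassOf(named[HP["overriding_aorta"]], named[HP["abn_heart"]]),
        SubClassOf(named[HP["pulmonic_stenosis"]], named[HP["abn_heart"]]),
        SubClassOf(named[HP["rvh"]], named[HP["abn_heart"]]),
        EquivalentClasses(
            (
                named[HP["tof"]],
                conj(
                    named[HP["vsd"]],
                    named[HP["overriding_aorta"]],
                    named[HP["pulmonic_stenosis"]],
                    named[HP["rvh"]],
                ),
            )
        ),
        SubClassOf(named[HP["tof_subtype"]], named[HP["tof"]]),
        SubClassOf(named[HP["muscular_vsd"]], named[HP["vsd"]]),
        SubClassOf(named[UBERON["aorta"]], Existential(part_of, named[UBERON["heart"]])),
        SubClassOf(named[UBERON["ventricle"]], Existential(part_of, named[UBERON["heart"]])),
        SubClassOf(named[UBERON["septum"]], Existential(part_of, named[UBERON["ventricle"]])),
        TransitiveProperty(part_of),
    ]
    for iri, label in sorted(CARDIO_LABELS.items()):
        axioms.append(AnnotationAssertion(iri, RDFS_LABEL, label))
    axioms.append(
        AnnotationAssertion(
            HP["vsd"], IAO_DEFINITION, "An abnormality in which the ventricular septum has a hole."
        )
    )
    axioms.append(
        AnnotationAssertion(
            HP["tof"],
            IAO_DEFINITION,
            "A cardiac malformation defined by four co-occurring heart phenotypes.",
        )
    )
    classes = set(named)
    return serialize_ofn(CARDIO_URI, axioms, classes=classes, properties={part_of})


def make_cardio_ontology(path: str | None = None) -> OntologyDocument:
    text = cardio_ontology_text()
    if path is not None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)
    return load_ontology_text(text, source=path or "<cardio>")


# Gene-Ontology-like part_of fragment
GO = {
    "bp": OBO + "GO_0008150",
    "apoptosis": OBO + "GO_0006915",
    "regulation": OBO + "GO_0065007",
    "execution": OBO + "GO_0097194",
    "caspase": OBO + "GO_0006919",
    "reg_apoptosis": OBO + "GO_0042981",
    "checkpoint": OBO + "GO_0043066",
    "cell_growth": OBO + "GO_0016049",
    "reg_growth": OBO + "GO_0040008",
}

GO_LABELS = {
    GO["bp"]: "biological_process",
    GO["apoptosis"]: "apoptotic process",
    GO["regulation"]: "regulation",
    GO["execution"]: "execution phase of apoptosis",
    GO["caspase"]: "caspase activation",
    GO["reg_apoptosis"]: "regulation of apoptotic process",
    GO["checkpoint"]: "apoptotic regulation checkpoint",
    GO["cell_growth"]: "cell growth",
    GO["reg_growth"]: "regulation of growth",
    PART_OF: "part_of",
}

#: classes entailed to be subclasses of ``part_of some 'apoptotic process'``
GO_PART_OF_APOPTOSIS = (
    GO["execution"],
    GO["caspase"],
    GO["reg_apoptosis"],
    GO["checkpoint"],
)
#: ... of which only this one is also a part of some regulation
GO_REGULATORY_PARTS = (GO["checkpoint"],)


def go_fragment_text() -> str:
    named = {iri: NamedClass(iri) for iri in GO_LABELS if iri != PART_OF}
    part = PART_OF
    axioms: list[Axiom] = [
        SubClassOf(named[GO["apoptosis"]], named[GO["bp"]]),
        SubClassOf(named[GO["regulation"]], named[GO["bp"]]),
        SubClassOf(named[GO["cell_growth"]], named[GO["bp"]]),
        SubClassOf(
            named[GO["execution"]],
            conj(named[GO["bp"]], Existential(part, named[GO["apoptosis"]])),
        ),
        # part of a part: needs transitivity to reach the apoptotic process
        SubClassOf(
            named[GO["caspase"]],
            conj(named[GO["bp"]], Existential(part, named[GO["execution"]])),
        ),
        SubClassOf(
            named[GO["reg_apoptosis"]],
            conj(named[GO["regulation"]], Existential(part, named[GO["apoptosis"]])),
        ),
        SubClassOf(
            named[GO["checkpoint"]],
            conj(named[GO["bp"]], Existential(part, named[GO["reg_apoptosis"]])),
        ),
        SubClassOf(
            named[GO["reg_growth"]],
            conj(named[GO["regulation"]], Existential(part, named[GO["cell_growth"]])),
        ),
        TransitiveProperty(part),
    ]
    for iri, label in sorted(GO_LABELS.items()):
        axioms.append(AnnotationAssertion(iri, RDFS_LABEL, label))
    axioms.append(
        AnnotationAssertion(
            GO["apoptosis"],
            IAO_DEFINITION,
            "A programmed cell death process which begins when a cell receives an internal or external signal.",
        )
    )
    return serialize_ofn(GO_URI, axioms, classes=set(named), properties={part})


def make_go_fragment(path: str | None = None) -> OntologyDocument:
    text = go_fragment_text()
    if path is not None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)
    return load_ontology_text(text, source=path or "<go-fragment>")


def make_import_demo(directory: str) -> tuple[str, dict[IRI, str]]:
    """A two-file imports demo: returns (root path, catalog)."""
    child_uri = "http://example.org/ontologies/anatomy-extra.owl"
    extra_cls = OBO + "UBERON_0001234"
    child_axioms: list[Axiom] = [
        SubClassOf(NamedClass(extra_cls), Existential(PART_OF, NamedClass(UBERON["heart"]))),
        AnnotationAssertion(extra_cls, RDFS_LABEL, "cardiac valve"),
    ]
    child_text = serialize_ofn(child_uri, child_axioms, classes={extra_cls, UBERON["heart"]})
    child_path = os.path.join(directory, "anatomy-extra.ofn")
    with open(child_path, "w", encoding="utf-8") as handle:
        handle.write(child_text)

    root_uri = "http://example.org/ontologies/cardio-with-import.owl"
    root_text = cardio_ontology_text().replace(
        f"Ontology(<{CARDIO_URI}>", f"Ontology(<{root_uri}>\nImport(<{child_uri}>)"
    )
    root_path = os.path.join(directory, "cardio-with-import.ofn")
    with open(root_path, "w", encoding="utf-8") as handle:
        handle.write(root_text)
    return root_path, {child_uri: child_path}


# ---------------------------------------------------------------------------
# Random EL ontologies (oracle testing)
# ---------------------------------------------------------------------------

RANDOM_NS = "http://example.org/rand#"


def random_el_ontology(cfg: GeneratorConfig, path: str | None = None) -> OntologyDocument:
    """A random EL ontology, deterministic in ``cfg.seed``.

    A layered subclass backbone keeps the ontology connected; random axioms
    from every accepted EL family are layered on top.  The instance is
    regenerated (with a derived sub-seed) until at least 10% of unordered
    class pairs are entailed-related.
    """
    for attempt in range(50):
        seed = (cfg.seed * 1000003 + attempt * 7919) % (2**31)
        rng = random.Random(seed)
        axioms = _random_axioms(rng, cfg)
        text = _random_ontology_text(axioms, cfg, seed)
        doc = load_ontology_text(text, source=f"<random:{cfg.seed}>")
        if _relatedness(doc) >= 0.10:
            break
    if path is not None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)
    return doc


def _relatedness(doc: OntologyDocument) -> float:
    taxonomy = classify(doc)
    n = len(doc.classes)
    if n < 2:
        return 1.0
    related = {frozenset((a, b)) for a, b in taxonomy.subsumption_pairs()}
    return len(related) / (n * (n - 1) / 2)


def _random_axioms(rng: random.Random, cfg: GeneratorConfig) -> list[Axiom]:
    classes = [NamedClass(f"{RANDOM_NS}C{i}") for i in range(cfg.n_classes)]
    props = [f"{RANDOM_NS}r{i}" for i in range(cfg.n_properties)]
    axioms: list[Axiom] = []

    # backbone: every class below a random earlier class
    for i in range(1, len(classes)):
        axioms.append(SubClassOf(classes[i], classes[rng.randrange(i)]))

    def any_class() -> NamedClass:
        return rng.choice(classes)

    def pair() -> tuple[NamedClass, NamedClass]:
        a = any_class()
        b = any_class()
        while b == a:
            b = any_class()
        return a, b

    while len(axioms) < cfg.n_axioms:
        kind = rng.choices(
            ["sub", "sub_conj_rhs", "sub_conj_lhs", "sub_exists_rhs", "sub_exists_lhs",
             "equiv", "subprop", "transitive", "chain", "disjoint"],
            weights=[20, 12, 12, 16, 12, 10, 5, 6, 4, 3],
        )[0]
        if kind == "sub":
            a, b = pair()
            axioms.append(SubClassOf(a, b))
        elif kind == "sub_conj_rhs":
            a, b = pair()
            c = any_class()
            expr = conj(b, c)
            if expr != a:
                axioms.append(SubClassOf(a, expr))
        elif kind == "sub_conj_lhs":
            a, b = pair()
            c = any_class()
            expr = conj(a, b)
            if expr != c:
                axioms.append(SubClassOf(expr, c))
        elif kind == "sub_exists_rhs":
            a, b = pair()
            axioms.append(SubClassOf(a, Existential(rng.choice(props), b)))
        elif kind == "sub_exists_lhs":
            a, b = pair()
            axioms.append(SubClassOf(Existential(rng.choice(props), a), b))
        elif kind == "equiv":
            a, b = pair()
            c = any_class()
            if rng.random() < 0.5:
                expr = conj(b, c)
            else:
                expr = Existential(rng.choice(props), b)
            if expr != a:
                axioms.append(EquivalentClasses((a, expr)))
        elif kind == "subprop":
            r, s = rng.sample(props, 2) if len(props) >= 2 else (props[0], props[0])
            axioms.append(SubPropertyOf(r, s))
        elif kind == "transitive":
            axioms.append(TransitiveProperty(rng.choice(props)))
        elif kind == "chain":
            from .model import PropertyChain

            axioms.append(
                PropertyChain(rng.choice(props), rng.choice(props), rng.choice(props))
            )
        else:  # rare disjointness via Bottom, to exercise unsatisfiability
            a, b = pair()
            axioms.append(SubClassOf(conj(a, b), Bottom))
    return axioms


def _random_ontology_text(axioms: list[Axiom], cfg: GeneratorConfig, seed: int) -> str:
    classes = {f"{RANDOM_NS}C{i}" for i in range(cfg.n_classes)}
    props = {f"{RANDOM_NS}r{i}" for i in range(cfg.n_properties)}
    return serialize_ofn(
        f"http://example.org/ontologies/random-{seed}.owl", axioms, classes=classes, properties=props
    )


# ---------------------------------------------------------------------------
# Corpus and triple-store fixtures
# ---------------------------------------------------------------------------

_DISTRACTOR_VOCAB = (
    "study cohort patients baseline imaging measurement protocol analysis "
    "results clinical followup enrolled randomized outcomes therapy dosage "
    "biomarker serum plasma assay sequencing variants annotation pipeline "
    "statistics model estimate confidence interval screening diagnosis "
    "prognosis intervention placebo survival morbidity registry consent "
    "methods discussion conclusion novel findings evidence significant"
).split()


def _label_pool(docs: list[OntologyDocument]) -> list[str]:
    labels: set[str] = set()
    for doc in docs:
        for iri in doc.classes:
            labels.add(doc.label_of(iri))
    return sorted(labels)


def _safe_vocab(labels: list[str]) -> list[str]:
    label_tokens = {tok.lower() for lbl in labels for tok in lbl.split()}
    return [w for w in _DISTRACTOR_VOCAB if w.lower() not in label_tokens]


def _phrase_contains(container: str, label: str) -> bool:
    """True when ``label``'s analyzed token sequence occurs inside
    ``container``'s (with matching stop-word gaps)."""
    from .literature_search import analyze

    outer = analyze(container)
    inner = analyze(label)
    if not inner:
        return False
    slots = {slot: tok for tok, slot in outer}
    base = inner[0][1]
    offsets = [(tok, slot - base) for tok, slot in inner]
    return any(
        all(slots.get(start + off) == tok for tok, off in offsets)
        for _t, start in outer
    )


def make_corpus(
    cfg: GeneratorConfig, docs: list[OntologyDocument]
) -> tuple[list[Document], dict[str, list[str]]]:
    """Synthetic corpus with planted label phrases.

    Returns the documents and the ground truth ``doc_id -> labels occurring
    in the document``.  Distractor words never share a token with any
    ontology label, so the truth is the exact phrase-occurrence truth: it is
    the planted labels closed under label-in-label containment (planting
    "overriding aorta" also plants "aorta").  The first document mentions
    only "tetralogy of Fallot" among all labels.
    """
    rng = random.Random(cfg.seed + 77)
    labels = _label_pool(docs)
    vocab = _safe_vocab(labels)
    if not vocab:
        raise ValueError("distractor vocabulary exhausted")
    contained_in = {
        planted: sorted(l for l in labels if _phrase_contains(planted, l))
        for planted in labels
    }

    def sentence(words: int, planted: list[str]) -> str:
        parts = [rng.choice(vocab) for _ in range(words)]
        for phrase in planted:
            parts.insert(rng.randrange(len(parts) + 1), phrase)
        return " ".join(parts) + "."

    corpus: list[Document] = []
    truth: dict[str, list[str]] = {}
    for i in range(cfg.corpus_size):
        doc_id = f"PM{i + 1:06d}"
        if i == 0:
            planted = ["tetralogy of Fallot"]
        else:
            k = rng.choices([0, 1, 2, 3], weights=[30, 40, 20, 10])[0]
            planted = rng.sample(labels, k) if k else []
        in_title = [p for p in planted if rng.random() < 0.3]
        in_fulltext = [p for p in planted if p not in in_title and rng.random() < 0.2]
        in_abstract = [p for p in planted if p not in in_title and p not in in_fulltext]
        title = sentence(rng.randint(4, 8), in_title)
        abstract = sentence(rng.randint(15, 30), in_abstract)
        fulltext = sentence(rng.randint(30, 60), in_fulltext) if (in_fulltext or rng.random() < 0.2) else None
        corpus.append(Document(doc_id=doc_id, title=title, abstract=abstract, fulltext=fulltext))
        truth[doc_id] = sorted({lbl for p in planted for lbl in contained_in[p]})
    return corpus, truth


def make_triples(
    cfg: GeneratorConfig, go_doc: OntologyDocument, n_proteins: int = 12
) -> tuple[list[tuple[str, str, str]], dict[str, list[str]]]:
    """Toy protein→GO annotation triples plus ground truth.

    Returns (triples, protein IRI -> annotated class IRIs); triples use the
    OBO URI scheme.  Use :func:`to_uniprot_scheme` for the alternative base.
    """
    rng = random.Random(cfg.seed + 101)
    go_classes = sorted(go_doc.classes)
    triples: list[tuple[str, str, str]] = []
    truth: dict[str, list[str]] = {}
    for i in range(n_proteins):
        protein = f"{PROTEIN_BASE}P{i + 1:03d}"
        triples.append((protein, "http://www.w3.org/1999/02/22-rdf-syntax-ns#type", PROTEIN_CLASS))
        annotations = rng.sample(go_classes, rng.randint(1, 3))
        for cls in sorted(annotations):
            triples.append((protein, CLASSIFIED_WITH, cls))
        truth[protein] = sorted(annotations)
    return triples, truth


def to_uniprot_scheme(iri: str) -> str:
    """Map an OBO GO IRI to the UniProt-endpoint URI scheme."""
    prefix = OBO + "GO_"
    if iri.startswith(prefix):
        return UNIPROT_GO_BASE + iri[len(prefix):]
    return iri


def write_ntriples(path: str, triples: list[tuple[str, str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for s, p, o in triples:
            handle.write(f"<{s}> <{p}> <{o}> .\n")


def make_corpus_and_triples(
    cfg: GeneratorConfig, docs: list[OntologyDocument], out_dir: str
) -> dict[str, str]:
    """Write corpus.jsonl, triples (both URI schemes) and ground-truth JSON.

    Returns a name→path map of everything written.
    """
    os.makedirs(out_dir, exist_ok=True)
    corpus, corpus_truth = make_corpus(cfg, docs)
    go_doc = next((d for d in docs if d.document_uri == GO_URI), None)
    paths = {
        "corpus": os.path.join(out_dir, "corpus.jsonl"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_jsonl(paths["corpus"], corpus)
    truth: dict[str, object] = {"documents": corpus_truth}
    if go_doc is not None:
        triples, protein_truth = make_triples(cfg, go_doc)
        paths["triples_obo"] = os.path.join(out_dir, "annotations-obo.nt")
        paths["triples_uniprot"] = os.path.join(out_dir, "annotations-uniprot.nt")
        write_ntriples(paths["triples_obo"], triples)
        write_ntriples(
            paths["triples_uniprot"],
            [(s, p, to_uniprot_scheme(o)) for s, p, o in triples],
        )
        truth["proteins"] = protein_truth
    with open(paths["ground_truth"], "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=2, sort_keys=True)
    return paths
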