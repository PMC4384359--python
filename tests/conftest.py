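import os

import pytest

from obakit import fixtures as fx
from obakit.ontology_store import Repository, load_ontology

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")

CARDIO_PATH = os.path.join(DATA_DIR, "cardio.ofn")
GO_PATH = os.path.join(DATA_DIR, "go-fragment.ofn")


@pytest.fixture(scope="session")
def cardio_doc():
    return load_ontology(CARDIO_PATH)


@pytest.fixture(scope="session")
def go_doc():
    return load_ontology(GO_PATH)


@pytest.fixture(scope="session")
def repo(cardio_doc, go_doc):
    return Repository([cardio_doc, go_doc])


@pytest.fixture(scope="session")
def small_corpus(cardio_doc, go_doc):
    """50-document corpus with planted labels plus its ground truth."""
    cfg = fx.GeneratorConfig(seed=11, corpus_size=50)
    return fx.make_corpus(cfg, [cardio_doc, go_doc])


@pytest.fixture(scope="session")
def triple_files(tmp_path_factory, cardio_doc, go_doc):
    """Corpus + N-Triples fixture files written to a session tmp dir."""
    out = tmp_path_factory.mktemp("fixtures")
    cfg = fx.GeneratorConfig(seed=7, corpus_size=60)
    return fx.make_corpus_and_triples(cfg, [cardio_doc, go_doc], str(out))
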