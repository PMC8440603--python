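import numpy as np
import pytest

from attnov.synthetic import SimulationConfig, generate_dataset
from attnov.textnovelty import Corpus, Document, ReferenceCorpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two-document corpus with hand-computable Tf-idf values."""
    return Corpus([Document("d1", ["a", "a", "b"]), Document("d2", ["a", "c"])])


@pytest.fixture
def tiny_reference() -> ReferenceCorpus:
    return ReferenceCorpus({"a": 3, "b": 1})


@pytest.fixture(scope="session")
def survey_dataset():
    """One survey-scale synthetic dataset shared across read-only tests."""
    return generate_dataset(SimulationConfig(n_participants=200, seed=11))


def random_corpus(rng: np.random.Generator, max_docs: int = 5, max_types: int = 10) -> Corpus:
    """Small random corpus for oracle-equivalence checks."""
    vocab = [f"t{k}" for k in range(rng.integers(2, max_types + 1))]
    n_docs = rng.integers(1, max_docs + 1)
    docs = []
    for i in range(n_docs):
        length = rng.integers(1, 12)
        docs.append(Document(f"doc{i}", rng.choice(vocab, size=length)))
    return Corpus(docs)


def random_reference(rng: np.random.Generator, corpus: Corpus) -> ReferenceCorpus:
    """Reference counts covering every token of `corpus` (plus extras)."""
    counts = {}
    for doc in corpus:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + int(rng.integers(1, 20))
    counts["background"] = int(rng.integers(10, 100))
    return ReferenceCorpus(counts)
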