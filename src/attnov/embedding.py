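"""Document-vector distances to a specialist reference corpus.

A document's "distance to the specialists" is the mean cosine distance
between its vector and the vectors of documents written by known domain
specialists; a *small* distance is read as a *large* amount of professional
knowledge.  The vectorizer is a pluggable backend.  The default backend is a
deterministic term-count vectorizer, which keeps the whole computation
bit-reproducible; neural document-embedding backends can be registered with
the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, StateError
from .textnovelty import Corpus, Document

__all__ = [
    "cosine_distance",
    "CountVectorizerBackend",
    "DistanceScore",
    "distance_to_specialists",
    "score_distances",
]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance ``1 - u.v / (|u||v|)``; in [0, 2], symmetric.

    Raises :class:`DomainError` for zero vectors or mismatched dimensions.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DomainError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DomainError("cosine distance is undefined for a zero vector")
    return float(1.0 - float(u @ v) / (nu * nv))


class CountVectorizerBackend:
    """Deterministic bag-of-words vectorizer over a fixed fitted vocabulary.

    ``fit`` freezes the vocabulary (sorted token types of the training
    corpus); ``vector`` maps a document to its raw term-count vector.
    Tokens outside the fitted vocabulary are ignored.
    """

    name = "count"

    def __init__(self) -> None:
        self._vocab: dict[str, int] | None = None

    @property
    def is_fitted(self) -> bool:
        return self._vocab is not None

    @property
    def dimension(self) -> int:
        if self._vocab is None:
            raise StateError("backend is not fitted")
        return len(self._vocab)

    def fit(self, *corpora: Corpus) -> "CountVectorizerBackend":
        vocab = sorted({w for corpus in corpora for doc in corpus for w in doc.tokens})
        self._vocab = {w: i for i, w in enumerate(vocab)}
        return self

    def vector(self, doc: Document) -> np.ndarray:
        if self._vocab is None:
            raise StateError("backend must be fitted before vectorizing")
        vec = np.zeros(len(self._vocab), dtype=float)
        for w in doc.tokens:
            idx = self._vocab.get(w)
            if idx is not None:
                vec[idx] += 1.0
        return vec


@dataclass(frozen=True)
class DistanceScore:
    doc_id: str
    mean_distance: float


def distance_to_specialists(
    doc: Document,
    specialists: Corpus,
    backend: CountVectorizerBackend,
    aggregate: str = "mean",
) -> DistanceScore:
    """Mean cosine distance of ``doc`` to each specialist document.

    ``aggregate="centroid"`` instead measures the distance to the centroid of
    the specialist vectors (one distance rather than an average of many).
    """
    if not getattr(backend, "is_fitted", False):
        raise StateError("vectorizer backend must be fitted on the union corpus")
    if specialists.n_docs == 0:
        raise DomainError("at least one specialist document is required")
    u = backend.vector(doc)
    if aggregate == "centroid":
        centroid = np.mean([backend.vector(s) for s in specialists], axis=0)
        dist = cosine_distance(u, centroid)
    elif aggregate == "mean":
        dist = float(
            np.mean([cosine_distance(u, backend.vector(s)) for s in specialists])
        )
    else:
        raise DomainError(f"unknown aggregate {aggregate!r}")
    return DistanceScore(doc_id=doc.id, mean_distance=dist)


def score_distances(
    corpus: Corpus,
    specialists: Corpus,
    backend: CountVectorizerBackend | None = None,
    aggregate: str = "mean",
):
    """Distance to the specialists for every document; (doc_id, distance) frame."""
    import pandas as pd

    if backend is None:
        backend = CountVectorizerBackend().fit(corpus, specialists)
    rows = [
        {
            "doc_id": doc.id,
            "distance": distance_to_specialists(doc, specialists, backend, aggregate).mean_distance,
        }
        for doc in corpus
    ]
    return pd.DataFrame(rows, columns=["doc_id", "distance"])
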