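"""Corpus-based text novelty statistics.

Two document-level novelty scores are implemented, both operating on raw
bag-of-words counts:

* **novelty to a group** — the summed Tf-idf of a document ``d`` against the
  collection ``D`` it belongs to,

  .. math:: \\mathrm{Tfidf}_d = \\sum_{w \\in d} p_{w,d}
            \\, \\log\\frac{|D|}{f_{w,D}}

  where :math:`p_{w,d}` is the within-document relative frequency of word
  ``w`` and :math:`f_{w,D}` the number of documents of ``D`` containing it;

* **novelty in history (communication burden)** — the summed per-word
  surprisal of ``d`` against a large background reference corpus ``Q``,

  .. math:: \\mathrm{CB}_d = -\\sum_{w \\in d} p_{w,d} \\, \\log p_{w,Q}.

Both sums run over the *distinct* words of ``d``: the word frequency is
already carried by :math:`p_{w,d}`, so summing per occurrence would count it
twice.  Larger values mean rarer word usage, read as higher novelty.

A third, rater-based score (``novelty_to_individuals``) is the median of a
panel of ordinal expert ratings.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, IntegrityError, ScoringError

__all__ = [
    "Document",
    "Corpus",
    "ReferenceCorpus",
    "NoveltyBreakdown",
    "tokenize",
    "register_tokenizer",
    "tfidf_document",
    "communication_burden",
    "score_corpus",
    "novelty_to_individuals",
    "corpus_from_texts",
    "read_corpus_jsonl",
    "read_reference_corpus",
]


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)


def _simple_tokenizer(raw_text: str) -> list[str]:
    # lowercase, split on whitespace/punctuation; underscores count as
    # punctuation so "a_b" -> ["a", "b"]
    return _WORD_RE.findall(raw_text.lower())


_TOKENIZERS: dict[str, Callable[[str], list[str]]] = {"simple": _simple_tokenizer}


def register_tokenizer(name: str, func: Callable[[str], list[str]]) -> None:
    """Register a tokenizer backend (e.g. a morphological analyzer)."""
    _TOKENIZERS[name] = func


def tokenize(raw_text: str, scheme: str = "simple") -> list[str]:
    """Tokenize ``raw_text`` with the registered ``scheme``.

    The default ``"simple"`` scheme lowercases and splits on whitespace and
    punctuation; it is language-agnostic and deterministic.  Unknown schemes
    raise :class:`ConfigurationError`.
    """
    try:
        func = _TOKENIZERS[scheme]
    except KeyError:
        known = ", ".join(sorted(_TOKENIZERS))
        raise ConfigurationError(
            f"unknown tokenizer scheme {scheme!r}; registered schemes: {known}"
        ) from None
    return func(raw_text)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Document:
    """An ordered token list with an identifier."""

    id: str
    tokens: tuple[str, ...]

    def __init__(self, id: str, tokens: Iterable[str]):  # noqa: A002
        object.__setattr__(self, "id", str(id))
        object.__setattr__(self, "tokens", tuple(tokens))

    @property
    def term_probabilities(self) -> dict[str, float]:
        """Relative frequency :math:`p_{w,d}` of each distinct token."""
        if not self.tokens:
            raise ScoringError(f"document {self.id!r} has no tokens")
        n = len(self.tokens)
        return {w: c / n for w, c in Counter(self.tokens).items()}


@dataclass
class Corpus:
    """A document collection with cached document frequencies."""

    documents: list[Document]
    doc_freq: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        df: Counter[str] = Counter()
        for doc in self.documents:
            df.update(set(doc.tokens))
        self.doc_freq = dict(df)

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


@dataclass
class ReferenceCorpus:
    """Background token-count table (the "history" corpus ``Q``)."""

    token_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.token_counts = {w: int(c) for w, c in self.token_counts.items() if c > 0}
        if not self.token_counts:
            raise ConfigurationError("reference corpus has no tokens")

    @property
    def total_tokens(self) -> int:
        return sum(self.token_counts.values())

    @property
    def vocab_size(self) -> int:
        return len(self.token_counts)

    @classmethod
    def from_documents(cls, docs: Iterable[Document]) -> "ReferenceCorpus":
        counts: Counter[str] = Counter()
        for doc in docs:
            counts.update(doc.tokens)
        return cls(dict(counts))


@dataclass(frozen=True)
class NoveltyBreakdown:
    """Per-token contributions and their total for one document score."""

    per_token: Mapping[str, float]
    total: float

    @classmethod
    def from_contributions(cls, per_token: Mapping[str, float]) -> "NoveltyBreakdown":
        return cls(per_token=dict(per_token), total=float(sum(per_token.values())))


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def _log(x: float, base: float | None) -> float:
    return math.log(x) if base is None else math.log(x, base)


def tfidf_document(
    d: Document, corpus: Corpus, log_base: float | None = None
) -> NoveltyBreakdown:
    """Summed Tf-idf of ``d`` against collection ``corpus`` (novelty to a group).

    Each distinct token contributes
    :math:`p_{w,d}\\,\\log(|D|/f_{w,D})`; document frequencies are taken from
    ``corpus``, which must contain every token of ``d`` (normally because
    ``d`` is a member of ``corpus``).  Natural log by default.
    """
    probs = d.term_probabilities  # raises ScoringError on empty doc
    n_docs = corpus.n_docs
    contributions: dict[str, float] = {}
    for w, p in probs.items():
        f = corpus.doc_freq.get(w, 0)
        if f == 0:
            raise IntegrityError(
                f"token {w!r} of document {d.id!r} is absent from the corpus "
                "document frequencies"
            )
        contributions[w] = p * _log(n_docs / f, log_base)
    return NoveltyBreakdown.from_contributions(contributions)


def communication_burden(
    d: Document,
    reference: ReferenceCorpus,
    smoothing: str = "addone",
    log_base: float | None = None,
) -> NoveltyBreakdown:
    """Summed surprisal of ``d`` against background corpus ``reference``.

    Each distinct token contributes :math:`-p_{w,d}\\,\\log \\tilde p_{w,Q}`.
    Out-of-vocabulary handling is governed by ``smoothing``:

    - ``"addone"`` (default): add-one smoothing over the union vocabulary,
      :math:`\\tilde p = (c_w + 1) / (N + V')` with :math:`V'` the size of
      the vocabulary of ``Q`` extended by the unseen token types of ``d``;
    - ``"floor"``: unseen tokens get the probability of a single count,
      :math:`1/N`; seen tokens keep their raw probability;
    - ``"strict"``: the raw formula; an unseen token raises
      :class:`DomainError`.
    """
    probs = d.term_probabilities
    counts = reference.token_counts
    total = reference.total_tokens

    if smoothing not in ("addone", "floor", "strict"):
        raise ConfigurationError(f"unknown smoothing {smoothing!r}")

    oov = [w for w in probs if w not in counts]
    if smoothing == "strict" and oov:
        raise DomainError(
            f"token {oov[0]!r} of document {d.id!r} does not occur in the "
            "reference corpus (smoothing='strict')"
        )

    if smoothing == "addone":
        denom = total + reference.vocab_size + len(oov)

        def prob(w: str) -> float:
            return (counts.get(w, 0) + 1) / denom

    elif smoothing == "floor":

        def prob(w: str) -> float:
            c = counts.get(w, 0)
            return c / total if c else 1 / total

    else:  # strict

        def prob(w: str) -> float:
            return counts[w] / total

    contributions = {w: -p * _log(prob(w), log_base) for w, p in probs.items()}
    return NoveltyBreakdown.from_contributions(contributions)


def score_corpus(
    corpus: Corpus,
    reference: ReferenceCorpus,
    smoothing: str = "addone",
    log_base: float | None = None,
) -> pd.DataFrame:
    """Score every document of ``corpus``; returns columns (id, tfidf, cb)."""
    if corpus.n_docs == 0:
        raise ScoringError("cannot score an empty corpus")
    rows = [
        {
            "id": doc.id,
            "tfidf": tfidf_document(doc, corpus, log_base=log_base).total,
            "cb": communication_burden(
                doc, reference, smoothing=smoothing, log_base=log_base
            ).total,
        }
        for doc in corpus
    ]
    return pd.DataFrame(rows, columns=["id", "tfidf", "cb"])


def novelty_to_individuals(ratings: Sequence[float]) -> float:
    """Median of a panel of ordinal ratings (novelty to individuals).

    With an even number of raters the midpoint of the two central values is
    returned.
    """
    arr = np.asarray(list(ratings), dtype=float)
    if arr.size == 0:
        raise ScoringError("cannot take the median of zero ratings")
    return float(np.median(arr))


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def corpus_from_texts(
    texts: Mapping[str, str] | Iterable[tuple[str, str]], scheme: str = "simple"
) -> Corpus:
    """Build a :class:`Corpus` from (id, raw text) pairs."""
    items = texts.items() if isinstance(texts, Mapping) else texts
    return Corpus([Document(i, tokenize(t, scheme)) for i, t in items])


def read_corpus_jsonl(path: str | Path, scheme: str = "simple") -> Corpus:
    """Read a corpus from JSONL lines of ``{"id": ..., "text": ...}``."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            docs.append(Document(str(obj.get("id", lineno)), tokenize(obj["text"], scheme)))
    return Corpus(docs)


def read_reference_corpus(path: str | Path, scheme: str = "simple") -> ReferenceCorpus:
    """Read a reference corpus from a count CSV (token,count) or JSONL texts."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table = pd.read_csv(path)
        return ReferenceCorpus(dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1])))
    return ReferenceCorpus.from_documents(read_corpus_jsonl(path, scheme))
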