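"""Synthetic survey- and review-style datasets with the causal structure the
analysis assumes.

The generator emulates a study in which each participant has

* a **knowledge test score** (binomial over test items, success probability
  from a latent uniform aptitude),
* an **area ratio** drawn from a beta distribution whose mean depends on
  knowledge through a logit link (``logit(mu) = beta_intercept +
  beta_knowledge * score``) with constant precision ``phi``,
* an **idea text** whose rare-word usage decreases with the area ratio: each
  document mixes a common-head and a rare-tail token distribution, and the
  rare-tail weight is ``sigmoid(gamma_intercept + gamma_area * area_ratio +
  noise)`` with ``gamma_area < 0`` for study-like data,
* a centred rectangular **object mask** realising the area ratio in pixels,
* and seven ordinal (1-5) **expert ratings** of the idea, each the
  discretised latent novelty plus rater noise.

A Zipfian reference ("history") corpus and a specialist corpus are generated
alongside.  A single root seed feeds an explicit per-stream seed sequence
(participants, texts, masks, ratings, reference, specialists) so each stage
is independently reproducible.

Only the *statistical* structure is emulated: documents are strings of
abstract word types, not prose, and masks are rectangles, not photographs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .arearatio import MaskAnnotation, write_mask_png
from .exceptions import ConfigurationError, DomainError
from .textnovelty import Corpus, Document, ReferenceCorpus

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_participants",
    "simulate_reference_corpus",
    "simulate_specialist_corpus",
    "simulate_idea_texts",
    "simulate_review_texts",
    "simulate_ratings",
    "simulate_masks",
    "generate_dataset",
    "write_dataset",
]

_STREAMS = ("participants", "reference", "specialists", "texts", "masks", "ratings")

_RARE_WEIGHT_COL = "latent_rare_weight"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with survey-anchored defaults.

    The default effect sizes follow the survey-scale estimates the pipeline
    is built to recover: a knowledge coefficient of 0.044 and precision
    ``phi = 5.58`` for the area-ratio model, and a negative area-ratio
    effect on rare-word usage.
    """

    n_participants: int = 200
    seed: int = 0
    knowledge_items: int = 20
    # area-ratio model (logit link)
    beta_intercept: float = -1.4
    beta_knowledge: float = 0.044
    precision_phi: float = 5.58
    # idea-novelty model (logit-scale rare-tail weight)
    gamma_intercept: float = 0.5
    gamma_area: float = -3.0
    rare_noise_sd: float = 0.5
    # corpora
    vocab_size: int = 2000
    zipf_exponent: float = 1.1
    tokens_per_doc: int = 80
    n_reference_docs: int = 300
    n_specialist_docs: int = 645
    head_fraction: float = 0.2
    # review mode: specialist-topic weight grows with standardized knowledge
    delta_knowledge: float = 2.0
    # ratings
    n_raters: int = 7
    rater_noise_sd: float = 0.8
    # images
    image_size: int = 100
    mask_fraction: float = 1.0
    # covariate marginals (instrument not fully specified; pragmatic shapes)
    female_prob: float = 0.14
    age_range: tuple[int, int] = (20, 60)

    def __post_init__(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "knowledge_items": self.knowledge_items,
            "vocab_size": self.vocab_size,
            "tokens_per_doc": self.tokens_per_doc,
            "n_reference_docs": self.n_reference_docs,
            "n_specialist_docs": self.n_specialist_docs,
            "n_raters": self.n_raters,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be a positive count, got {value}")
        if self.n_participants < 4:
            raise ConfigurationError(
                f"n_participants must be >= 4 for quantile splits, got {self.n_participants}"
            )
        if self.precision_phi <= 0:
            raise ConfigurationError(f"precision_phi must be > 0, got {self.precision_phi}")
        if self.zipf_exponent < 0:
            raise ConfigurationError(f"zipf_exponent must be >= 0, got {self.zipf_exponent}")
        if self.rater_noise_sd < 0:
            raise ConfigurationError(f"rater_noise_sd must be >= 0, got {self.rater_noise_sd}")
        if self.image_size < 8:
            raise ConfigurationError(f"image_size must be >= 8, got {self.image_size}")
        if not 0 < self.head_fraction < 1:
            raise ConfigurationError(f"head_fraction must be in (0, 1), got {self.head_fraction}")
        if not 0 <= self.mask_fraction <= 1:
            raise ConfigurationError(f"mask_fraction must be in [0, 1], got {self.mask_fraction}")
        if self.vocab_size < 10:
            raise ConfigurationError(f"vocab_size must be >= 10, got {self.vocab_size}")

    @classmethod
    def amazon_like(cls, n_participants: int = 2000, mask_fraction: float = 0.5, **kw):
        """Review-platform mode: larger n, masks only for a picture subset."""
        return cls(n_participants=n_participants, mask_fraction=mask_fraction, **kw)

    def rng(self, stream: str) -> np.random.Generator:
        """Generator for one named stream of the root seed."""
        if stream not in _STREAMS:
            raise ConfigurationError(f"unknown random stream {stream!r}")
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["age_range"] = list(self.age_range)
        return out


@dataclass
class SyntheticDataset:
    """One generated dataset: tables, corpora, masks, and the truth."""

    participants: pd.DataFrame
    idea_corpus: Corpus
    reference_corpus: ReferenceCorpus
    specialist_corpus: Corpus
    masks: list[MaskAnnotation]
    ratings: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Vocabulary helpers
# ---------------------------------------------------------------------------


def _vocab(config: SimulationConfig) -> np.ndarray:
    width = len(str(config.vocab_size))
    return np.array([f"w{r:0{width}d}" for r in range(config.vocab_size)])


def _zipf_probs(config: SimulationConfig) -> np.ndarray:
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    weights = ranks ** (-config.zipf_exponent)
    return weights / weights.sum()


def _head_tail(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    head_size = max(1, int(round(config.head_fraction * config.vocab_size)))
    head_size = min(head_size, config.vocab_size - 1)
    return np.arange(head_size), np.arange(head_size, config.vocab_size)


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------


def simulate_participants(config: SimulationConfig) -> pd.DataFrame:
    """Participant table: knowledge score, covariates, and area ratio.

    Knowledge ~ Binomial(knowledge_items, aptitude) with aptitude uniform on
    (0, 1); area ratio ~ Beta with mean ``logistic(beta_intercept +
    beta_knowledge * score)`` and precision ``phi``.  Gender is 0/1, age an
    integer in the configured range, and the four usage covariates are
    ordinal 1-5, all independent.
    """
    rng = config.rng("participants")
    n = config.n_participants
    aptitude = rng.uniform(size=n)
    score = rng.binomial(config.knowledge_items, aptitude)
    mu = expit(config.beta_intercept + config.beta_knowledge * score)
    phi = config.precision_phi
    area = rng.beta(mu * phi, (1 - mu) * phi)
    eps = 1e-9
    area = np.clip(area, eps, 1 - eps)
    lo, hi = config.age_range
    width = len(str(n))
    table = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:0{width}d}" for i in range(n)],
            "test_score": score,
            "age": rng.integers(lo, hi + 1, size=n),
            "gender": (rng.uniform(size=n) < config.female_prob).astype(int),
            "n_speakers": rng.integers(1, 6, size=n),
            "usage_frequency": rng.integers(1, 6, size=n),
            "particularity": rng.integers(1, 6, size=n),
            "self_knowledge": rng.integers(1, 6, size=n),
            "area_ratio": area,
        }
    )
    return table


def simulate_reference_corpus(config: SimulationConfig) -> ReferenceCorpus:
    """Zipfian background ("history") corpus as a token-count table."""
    rng = config.rng("reference")
    vocab = _vocab(config)
    probs = _zipf_probs(config)
    total = config.n_reference_docs * config.tokens_per_doc
    counts = rng.multinomial(total, probs)
    return ReferenceCorpus({w: int(c) for w, c in zip(vocab, counts) if c > 0})


def simulate_specialist_corpus(config: SimulationConfig) -> Corpus:
    """Specialist reference documents drawn from a dedicated topic band.

    The specialist "topic" is a contiguous band of mid-rank word types mixed
    with the common head, so specialist documents are lexically coherent and
    distinguishable from generic documents.
    """
    rng = config.rng("specialists")
    vocab = _vocab(config)
    probs = _specialist_probs(config)
    docs = []
    for j in range(config.n_specialist_docs):
        idx = rng.choice(config.vocab_size, size=config.tokens_per_doc, p=probs)
        docs.append(Document(f"S{j + 1:04d}", vocab[idx]))
    return Corpus(docs)


def _specialist_probs(config: SimulationConfig) -> np.ndarray:
    # narrow topic band: specialist documents must overlap each other far
    # more than generic Zipf text does, else cosine similarity is dominated
    # by the shared common head
    head, tail = _head_tail(config)
    band = tail[: max(1, min(50, len(tail)))]
    probs = np.zeros(config.vocab_size)
    zipf = _zipf_probs(config)
    probs[head] = 0.1 * zipf[head] / zipf[head].sum()
    probs[band] = 0.9 / len(band)
    return probs / probs.sum()


def _rare_weights(
    participants: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Latent rare-tail mixing weight per participant, in (0, 1)."""
    if _RARE_WEIGHT_COL in participants.columns:
        return participants[_RARE_WEIGHT_COL].to_numpy(dtype=float)
    area = participants["area_ratio"].to_numpy(dtype=float)
    noise = rng.normal(0.0, config.rare_noise_sd, size=len(area))
    return expit(config.gamma_intercept + config.gamma_area * area + noise)


def simulate_idea_texts(
    participants: pd.DataFrame,
    reference: ReferenceCorpus | None,
    config: SimulationConfig,
    rare_weight: np.ndarray | None = None,
) -> Corpus:
    """One idea document per participant mixing common-head and rare-tail words.

    Tokens are drawn from the rare-tail distribution with the participant's
    latent rare weight and from the common-head distribution otherwise, so
    true novelty is negatively coupled to the area ratio when
    ``gamma_area < 0``.  ``rare_weight`` overrides the latent weights
    (e.g. to force them to 0 or 1).
    """
    if len(participants) == 0:
        raise DomainError("participant table is empty")
    rng = config.rng("texts")
    vocab = _vocab(config)
    zipf = _zipf_probs(config)
    head, tail = _head_tail(config)
    head_probs = zipf[head] / zipf[head].sum()
    if rare_weight is None:
        weights = _rare_weights(participants, config, rng)
    else:
        weights = np.broadcast_to(np.asarray(rare_weight, dtype=float), (len(participants),))
    docs = []
    for pid, w in zip(participants["participant_id"], weights):
        from_tail = rng.uniform(size=config.tokens_per_doc) < w
        n_tail = int(from_tail.sum())
        toks = np.empty(config.tokens_per_doc, dtype=vocab.dtype)
        toks[from_tail] = vocab[rng.choice(tail, size=n_tail)]
        toks[~from_tail] = vocab[
            rng.choice(head, size=config.tokens_per_doc - n_tail, p=head_probs)
        ]
        docs.append(Document(str(pid), toks))
    return Corpus(docs)


def simulate_review_texts(
    participants: pd.DataFrame, config: SimulationConfig
) -> Corpus:
    """Review-style documents whose specialist-topic weight grows with knowledge.

    Each token comes from the specialist topic distribution with probability
    ``sigmoid(delta_knowledge * z)`` (``z`` the standardized test score) and
    from the generic Zipf distribution otherwise, so participants with more
    knowledge write more specialist-like reviews.
    """
    if len(participants) == 0:
        raise DomainError("participant table is empty")
    rng = config.rng("texts")
    vocab = _vocab(config)
    zipf = _zipf_probs(config)
    spec_probs = _specialist_probs(config)
    score = participants["test_score"].to_numpy(dtype=float)
    sd = score.std() or 1.0
    z = (score - score.mean()) / sd
    weights = expit(config.delta_knowledge * z)
    docs = []
    for pid, w in zip(participants["participant_id"], weights):
        probs = w * spec_probs + (1 - w) * zipf
        idx = rng.choice(config.vocab_size, size=config.tokens_per_doc, p=probs)
        docs.append(Document(str(pid), vocab[idx]))
    return Corpus(docs)


def simulate_ratings(
    participants: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Ordinal 1-5 ratings, one column per rater.

    The latent novelty is the participant's rare-tail weight mapped onto the
    1-5 scale; each rater reports ``round(latent + noise)`` clipped to
    [1, 5].  With ``rater_noise_sd = 0`` all raters coincide with the
    discretised latent value.
    """
    if config.n_raters < 1:
        raise ConfigurationError("n_raters must be >= 1")
    rng = config.rng("ratings")
    weights = _rare_weights(participants, config, rng)
    latent = 1.0 + 4.0 * weights
    n = len(participants)
    data = {"participant_id": participants["participant_id"].to_numpy()}
    for j in range(config.n_raters):
        noisy = latent + rng.normal(0.0, config.rater_noise_sd, size=n)
        data[f"rater_{j + 1}"] = np.clip(np.rint(noisy), 1, 5).astype(int)
    return pd.DataFrame(data)


def simulate_masks(
    participants: pd.DataFrame, config: SimulationConfig
) -> list[MaskAnnotation]:
    """Centred near-rectangular binary masks realising each area ratio.

    The object occupies exactly ``round(ratio * S^2)`` pixels (full-width
    centred rows plus one centred partial row), so the recomputed pixel
    fraction matches the requested ratio to within one pixel.
    """
    size = config.image_size
    masks = []
    for pid, ratio in zip(participants["participant_id"], participants["area_ratio"]):
        masks.append(_rect_mask(str(pid), float(ratio), size))
    return masks


def _rect_mask(image_id: str, ratio: float, size: int) -> MaskAnnotation:
    if not 0 <= ratio <= 1:
        raise DomainError(f"area ratio {ratio} outside [0, 1]")
    target = int(round(ratio * size * size))
    grid = np.zeros((size, size), dtype=bool)
    if target > 0:
        n_full, rem = divmod(target, size)
        n_rows = n_full + (1 if rem else 0)
        top = (size - n_rows) // 2
        grid[top : top + n_full, :] = True
        if rem:
            left = (size - rem) // 2
            grid[top + n_full, left : left + rem] = True
    return MaskAnnotation(image_id=image_id, width=size, height=size, mask=grid)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete coupled dataset from one config.

    The latent rare-tail weight is drawn once (texts stream) and shared by
    the idea texts and the expert ratings, so both express the same true
    novelty.
    """
    participants = simulate_participants(config)
    reference = simulate_reference_corpus(config)
    specialists = simulate_specialist_corpus(config)
    weights = _rare_weights(participants, config, config.rng("texts"))
    participants = participants.assign(**{_RARE_WEIGHT_COL: weights})
    ideas = simulate_idea_texts(participants, reference, config)
    ratings = simulate_ratings(participants, config)
    n_masked = int(round(config.mask_fraction * len(participants)))
    masks = simulate_masks(participants.iloc[:n_masked], config)
    truth = config.as_dict()
    return SyntheticDataset(
        participants=participants,
        idea_corpus=ideas,
        reference_corpus=reference,
        specialist_corpus=specialists,
        masks=masks,
        ratings=ratings,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset to disk: CSV tables, JSONL corpora, PNG masks, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["participants"] = outdir / "participants.csv"
    dataset.participants.to_csv(paths["participants"], index=False)
    paths["ratings"] = outdir / "ratings.csv"
    dataset.ratings.to_csv(paths["ratings"], index=False)

    paths["ideas"] = outdir / "ideas.jsonl"
    with open(paths["ideas"], "w", encoding="utf-8") as fh:
        for doc in dataset.idea_corpus:
            fh.write(json.dumps({"id": doc.id, "text": " ".join(doc.tokens)}) + "\n")
    paths["specialists"] = outdir / "specialists.jsonl"
    with open(paths["specialists"], "w", encoding="utf-8") as fh:
        for doc in dataset.specialist_corpus:
            fh.write(json.dumps({"id": doc.id, "text": " ".join(doc.tokens)}) + "\n")

    paths["reference"] = outdir / "reference_counts.csv"
    ref = pd.DataFrame(
        sorted(dataset.reference_corpus.token_counts.items()), columns=["token", "count"]
    )
    ref.to_csv(paths["reference"], index=False)

    mask_dir = outdir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for mask in dataset.masks:
        write_mask_png(mask, mask_dir / f"{mask.image_id}.png")
    paths["masks"] = mask_dir

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(dataset.truth, fh, indent=2)
    return paths
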