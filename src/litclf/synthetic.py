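"""Seeded generators for synthetic labeled corpora and point fixtures.

The corpus generator emulates the structure a bag-of-words classifier
assumes: each class draws a fraction *s* (the signal) of its tokens from
a private pool of class-specific marker terms and the rest from a shared
Zipf-distributed background vocabulary, so classes differ exactly in the
frequency of class-specific vocabulary.  Stop-words and punctuation are
injected at configurable rates so the preprocessing chain is actually
exercised, and document lengths follow a negative-binomial distribution
to mimic abstract-length variability (mean 150 tokens by default; use
~3000 for full-text-like documents).

With s = 0 the class-conditional token distributions coincide and no
classifier can beat chance; as s grows the classes become separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Corpus, Document

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "default_class_specs",
    "generate_corpus",
    "generate_blobs",
]

_PUNCT = (",", ".", ";", ":", "!", "?", '"', "(", ")")

# injected function words (all in the bundled stop-word list)
_STOPWORDS = (
    "the", "of", "and", "to", "in", "was", "with", "for", "this", "that",
    "were", "is", "by", "from", "on", "as", "at", "be", "or", "an",
)


@dataclass(frozen=True)
class ClassSpec:
    """One class of documents: its label, size, marker terms and signal.

    ``signal`` is the probability mass a document of this class puts on
    its own marker terms; the remaining 1 - signal goes to the shared
    background vocabulary.
    """

    label: str
    n_docs: int
    terms: tuple[str, ...]
    signal: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal <= 1.0):
            raise ValueError(f"signal must be in [0, 1], got {self.signal}")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not self.terms:
            raise ValueError("each class needs at least one marker term")


@dataclass(frozen=True)
class GeneratorConfig:
    shared_vocab_size: int = 500
    stopword_rate: float = 0.2
    punctuation_rate: float = 0.1
    mean_length: float = 150.0
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.stopword_rate, self.punctuation_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.mean_length < 1:
            raise ValueError("mean_length must be >= 1")
        if self.shared_vocab_size < 1 or self.dispersion <= 0:
            raise ValueError("invalid shared_vocab_size or dispersion")


def default_class_specs(
    n_classes: int = 3,
    n_per_class: int = 200,
    signal: float = 0.5,
    n_terms: int = 15,
) -> list[ClassSpec]:
    """Balanced classes with digit-bearing marker terms.

    Marker terms carry digits (like gene symbols), which keeps them
    disjoint across classes by construction and stable under stemming.
    """
    specs = []
    for c in range(n_classes):
        label = f"class{chr(ord('a') + c)}"
        terms = tuple(f"marker{c}{j:02d}" for j in range(n_terms))
        specs.append(ClassSpec(label, n_per_class, terms, signal))
    return specs


def _shared_vocabulary(size: int, rng: np.random.Generator) -> list[str]:
    """Pronounceable alphabetic background words (these do get stemmed)."""
    consonants = np.array(list("bcdfghjklmnpqrtvwz"))
    vowels = np.array(list("aeiou"))
    words: list[str] = []
    seen = set()
    while len(words) < size:
        n_syll = int(rng.integers(2, 5))
        w = "".join(
            rng.choice(consonants) + rng.choice(vowels) for _ in range(n_syll)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def generate_corpus(
    specs: Optional[Sequence[ClassSpec]] = None,
    config: Optional[GeneratorConfig] = None,
) -> Corpus:
    """Generate a labeled corpus; identical seeds give identical corpora."""
    config = config or GeneratorConfig()
    if specs is None:
        specs = default_class_specs()
    if len(specs) < 2:
        raise ValueError("need at least 2 classes")
    all_terms: set[str] = set()
    for spec in specs:
        overlap = all_terms.intersection(spec.terms)
        if overlap:
            raise ValueError(
                f"discriminative vocabularies overlap: {sorted(overlap)[:5]}"
            )
        all_terms.update(spec.terms)

    rng = np.random.default_rng(config.seed)
    shared = _shared_vocabulary(config.shared_vocab_size, rng)
    ranks = np.arange(1, len(shared) + 1, dtype=float)
    zipf = 1.0 / ranks  # classic Zipf: frequency ~ 1/rank
    zipf /= zipf.sum()

    # negative binomial with mean mu and dispersion r: p = r / (r + mu)
    r = config.dispersion
    p_len = r / (r + config.mean_length)

    docs = []
    counter = 0
    for spec in specs:
        own = np.asarray(spec.terms)
        for _ in range(spec.n_docs):
            length = max(1, int(rng.negative_binomial(r, p_len)))
            words = []
            for _ in range(length):
                u = rng.random()
                if u < config.stopword_rate:
                    words.append(_STOPWORDS[int(rng.integers(len(_STOPWORDS)))])
                elif rng.random() < spec.signal:
                    words.append(str(rng.choice(own)))
                else:
                    words.append(shared[int(rng.choice(len(shared), p=zipf))])
            pieces = []
            for w in words:
                if rng.random() < config.punctuation_rate:
                    w = w + _PUNCT[int(rng.integers(len(_PUNCT)))]
                pieces.append(w)
            text = " ".join(pieces)
            if pieces:
                text = text[0].upper() + text[1:] + "."
            docs.append(
                Document(doc_id=f"d{counter:06d}", text=text, label=spec.label)
            )
            counter += 1
    return Corpus(docs)


def generate_blobs(
    n_per_class: int,
    means: Sequence[Sequence[float]] = ((-2.0, 0.0), (2.0, 0.0)),
    sigma: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian point clusters for linear-classifier unit tests.

    Returns (X, y) with X of shape (n_classes * n_per_class, dim) and
    integer labels; clusters are linearly separable when the inter-mean
    distance is large relative to sigma.
    """
    means = np.asarray(means, dtype=float)
    if len(means) < 2 or len(np.unique(means, axis=0)) != len(means):
        raise ValueError("means must be >= 2 distinct points")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [m + sigma * rng.standard_normal((n_per_class, means.shape[1]))
         for m in means]
    )
    y = np.repeat(np.arange(len(means)), n_per_class)
    return X, y
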