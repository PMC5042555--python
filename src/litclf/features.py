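"""Unigram/bigram vocabularies and sparse TF-IDF feature vectors.

Every document is mapped to an equal-length sparse vector over a fixed
vocabulary of stems and hyphen-joined stem pairs.  The weight of term *t*
in document *d* is

    W_{t,d} = TF_{t,d} * log10(N / DF_t)

with TF the raw in-document count, N the corpus size and DF_t the number
of documents containing *t*.  A term occurring in every document gets
weight zero regardless of TF (the ubiquitous-term property); so does an
absent term.  Document frequencies are counted on the corpus the
vocabulary is built from — in a train/test protocol, the training portion
only — and terms outside the vocabulary are dropped at vectorization time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .preprocess import TokenSequence

__all__ = [
    "Vocabulary",
    "FeatureVector",
    "extract_ngrams",
    "build_vocabulary",
    "tfidf_weight",
    "vectorize_document",
    "vectorize_corpus",
    "vectors_to_csr",
    "write_svmlight",
    "read_svmlight",
    "write_vocabulary",
    "read_vocabulary",
]

BIGRAM_JOIN = "-"


def extract_ngrams(tokens: TokenSequence | Sequence[str], orders: Iterable[int] = (1, 2)) -> list[str]:
    """List the n-grams of a token sequence: all unigrams in token order,
    then all bigrams (adjacent pairs joined with '-'), and so on."""
    orders = sorted(set(orders))
    if not orders:
        raise ValueError("orders must be a non-empty set of n-gram orders")
    if any(k < 1 for k in orders):
        raise ValueError(f"n-gram orders must be >= 1, got {orders}")
    toks = list(tokens)
    out: list[str] = []
    for k in orders:
        if k == 1:
            out.extend(toks)
        else:
            out.extend(
                BIGRAM_JOIN.join(toks[i : i + k]) for i in range(len(toks) - k + 1)
            )
    return out


@dataclass(frozen=True)
class Vocabulary:
    """Term -> column-index map with per-term document frequencies.

    Indices are assigned in lexicographic term order, so rebuilding from
    the same corpus always yields the identical mapping.
    """

    index: dict[str, int]
    df: dict[str, int]
    n_docs: int
    ngram_orders: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if sorted(self.index.values()) != list(range(len(self.index))):
            raise ValueError("vocabulary positions must be a bijection onto 0..d-1")
        for term, df_t in self.df.items():
            if term in self.index and not (1 <= df_t <= self.n_docs):
                raise ValueError(f"DF of {term!r} is {df_t}, outside [1, {self.n_docs}]")

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def idf(self, term: str) -> float:
        return math.log10(self.n_docs / self.df[term])

    def terms(self) -> list[str]:
        """Terms in column order."""
        return sorted(self.index, key=self.index.__getitem__)


def build_vocabulary(
    token_seqs: Sequence[TokenSequence | Sequence[str]],
    orders: Iterable[int] = (1, 2),
    min_df: int = 2,
) -> Vocabulary:
    """Count document frequencies over n-grams and index the surviving terms.

    ``min_df`` implements rare-word removal: a term must appear in at least
    that many documents to receive a column (default 2).
    """
    if not token_seqs:
        raise ValueError("cannot build a vocabulary from an empty collection")
    if min_df < 1:
        raise ValueError(f"min_df must be >= 1, got {min_df}")
    orders = frozenset(orders)
    df: dict[str, int] = {}
    for seq in token_seqs:
        for term in set(extract_ngrams(seq, orders)):
            df[term] = df.get(term, 0) + 1
    kept = sorted(t for t, c in df.items() if c >= min_df)
    return Vocabulary(
        index={t: i for i, t in enumerate(kept)},
        df={t: df[t] for t in kept},
        n_docs=len(token_seqs),
        ngram_orders=orders,
    )


def tfidf_weight(tf: float, df: int, n_docs: int) -> float:
    """TF-IDF weight TF * log10(N/DF); 0 when the term is absent (TF=0)."""
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    if tf < 0 or df < 0 or df > n_docs:
        raise ValueError(f"invalid counts tf={tf}, df={df}, n_docs={n_docs}")
    if tf == 0:
        return 0.0
    if df == 0:
        raise ValueError("term has tf > 0 but df = 0")
    return tf * math.log10(n_docs / df)


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-dimension sparse TF-IDF vector for one document.

    Zero weights are omitted from ``entries`` but the dimension is the full
    vocabulary size, so all vectors from one vocabulary are equal-length.
    """

    dimension: int
    entries: dict[int, float]
    doc_id: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for pos, w in self.entries.items():
            if not (0 <= pos < self.dimension):
                raise ValueError(f"position {pos} outside dimension {self.dimension}")
            if w <= 0:
                raise ValueError(f"stored weights must be > 0, got {w} at {pos}")

    def toarray(self) -> np.ndarray:
        out = np.zeros(self.dimension)
        for pos, w in self.entries.items():
            out[pos] = w
        return out


def vectorize_document(
    tokens: TokenSequence | Sequence[str],
    vocab: Vocabulary,
    label: Optional[str] = None,
) -> FeatureVector:
    """TF-IDF vector of one document under a fixed vocabulary.

    Terms absent from the vocabulary are ignored; terms with DF = N store
    nothing (their weight is exactly zero).
    """
    tf: dict[str, int] = {}
    for term in extract_ngrams(tokens, vocab.ngram_orders):
        if term in vocab:
            tf[term] = tf.get(term, 0) + 1
    entries = {}
    for term, count in tf.items():
        w = tfidf_weight(count, vocab.df[term], vocab.n_docs)
        if w > 0:
            entries[vocab.index[term]] = w
    doc_id = getattr(tokens, "doc_id", None)
    return FeatureVector(len(vocab), entries, doc_id=doc_id, label=label)


def vectorize_corpus(
    token_seqs: Sequence[TokenSequence],
    vocab: Vocabulary,
    labels: Optional[Sequence[Optional[str]]] = None,
) -> list[FeatureVector]:
    if labels is None:
        labels = [None] * len(token_seqs)
    if len(labels) != len(token_seqs):
        raise ValueError("labels and token sequences differ in length")
    return [
        vectorize_document(seq, vocab, label=lab)
        for seq, lab in zip(token_seqs, labels)
    ]


def vectors_to_csr(vectors: Sequence[FeatureVector]) -> sp.csr_matrix:
    """Stack feature vectors into an (n_docs, d) CSR matrix."""
    if not vectors:
        raise ValueError("no vectors to stack")
    d = vectors[0].dimension
    if any(v.dimension != d for v in vectors):
        raise ValueError("vectors have inconsistent dimensions")
    rows, cols, data = [], [], []
    for i, v in enumerate(vectors):
        for pos, w in v.entries.items():
            rows.append(i)
            cols.append(pos)
            data.append(w)
    return sp.csr_matrix((data, (rows, cols)), shape=(len(vectors), d))


# --- SVMlight-style sparse export (label idx:value ..., 1-based indices) ---

def write_svmlight(
    vectors: Sequence[FeatureVector],
    path: str | Path,
    label_to_int: Optional[dict[str, int]] = None,
) -> dict[str, int]:
    """Write vectors in SVMlight sparse format; returns the label encoding."""
    if label_to_int is None:
        labels = sorted({v.label for v in vectors if v.label is not None})
        label_to_int = {lab: i for i, lab in enumerate(labels)}
    with open(path, "w", encoding="utf-8") as handle:
        for v in vectors:
            lab = label_to_int.get(v.label, -1) if v.label is not None else -1
            cells = " ".join(
                f"{pos + 1}:{v.entries[pos]:.10g}" for pos in sorted(v.entries)
            )
            handle.write(f"{lab} {cells}".rstrip() + "\n")
    return label_to_int


def read_svmlight(path: str | Path, dimension: int) -> tuple[list[FeatureVector], list[int]]:
    vectors, labels = [], []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            parts = line.split()
            if not parts:
                continue
            labels.append(int(parts[0]))
            entries = {}
            for cell in parts[1:]:
                idx, val = cell.split(":")
                entries[int(idx) - 1] = float(val)
            vectors.append(FeatureVector(dimension, entries))
    return vectors, labels


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Sidecar: one ``term<TAB>index<TAB>df`` line per term, plus a header
    carrying N and the n-gram orders."""
    with open(path, "w", encoding="utf-8") as handle:
        orders = ",".join(str(k) for k in sorted(vocab.ngram_orders))
        handle.write(f"#n_docs={vocab.n_docs}\torders={orders}\n")
        for term in vocab.terms():
            handle.write(f"{term}\t{vocab.index[term]}\t{vocab.df[term]}\n")


def read_vocabulary(path: str | Path) -> Vocabulary:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().lstrip("#").strip()
        fields = dict(kv.split("=") for kv in header.split("\t"))
        n_docs = int(fields["n_docs"])
        orders = frozenset(int(k) for k in fields["orders"].split(","))
        index, df = {}, {}
        for line in handle:
            term, idx, df_t = line.rstrip("\n").split("\t")
            index[term] = int(idx)
            df[term] = int(df_t)
    return Vocabulary(index=index, df=df, n_docs=n_docs, ngram_orders=orders)
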