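"""Reading, writing and splitting labeled document corpora.

Two on-disk formats are supported:

* MEDLINE flat files (NLM tagged records, ``PMID-``/``TI``/``AB`` fields),
  parsed with Biopython's :mod:`Bio.Medline`.  MEDLINE records carry no
  class assignment, so labels arrive through a sidecar two-column file
  (doc_id TAB label).
* A simple labeled-corpus format in two dialects: JSON Lines
  (``{"id": ..., "text": ..., "label": ...}`` per line) and CSV with an
  ``id,text,label`` header and RFC-4180 quoting.
"""

from __future__ import annotations

import csv
import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import Medline

__all__ = [
    "Document",
    "Corpus",
    "read_medline",
    "read_labels",
    "read_labeled",
    "write_labeled",
    "train_test_split",
]


@dataclass(frozen=True)
class Document:
    """One text unit (abstract or article) with an optional class label."""

    doc_id: str
    text: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("Document doc_id must be non-empty")
        if not self.text:
            warnings.warn(f"document {self.doc_id!r} has empty text", stacklevel=3)


class Corpus:
    """An ordered collection of :class:`Document` with unique ids.

    ``classes`` is always exactly the set of non-null labels present; document
    order is preserved through read/write round-trips.
    """

    def __init__(self, documents: Iterable[Document] = ()) -> None:
        self._docs: list[Document] = []
        self._ids: set[str] = set()
        for doc in documents:
            self.add(doc)

    def add(self, doc: Document) -> None:
        if doc.doc_id in self._ids:
            raise ValueError(f"duplicate document id {doc.doc_id!r}")
        self._ids.add(doc.doc_id)
        self._docs.append(doc)

    @property
    def documents(self) -> tuple[Document, ...]:
        return tuple(self._docs)

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(d.label for d in self._docs if d.label is not None)

    def labels(self) -> list[Optional[str]]:
        return [d.label for d in self._docs]

    def with_labels(self, labels: dict[str, str]) -> "Corpus":
        """Return a copy with labels attached from a doc_id -> label map."""
        missing = [d.doc_id for d in self._docs if d.doc_id not in labels]
        if missing:
            raise KeyError(f"no label supplied for document(s): {missing[:5]}")
        return Corpus(
            Document(d.doc_id, d.text, labels[d.doc_id]) for d in self._docs
        )

    def subset(self, indices: Sequence[int]) -> "Corpus":
        return Corpus(self._docs[i] for i in indices)

    def __len__(self) -> int:
        return len(self._docs)

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs)

    def __getitem__(self, i: int) -> Document:
        return self._docs[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._docs == other._docs

    def __repr__(self) -> str:
        return f"<Corpus of {len(self)} documents, classes={sorted(self.classes)}>"


def read_medline(path: str | Path) -> Corpus:
    """Read a MEDLINE flat file into an unlabeled :class:`Corpus`.

    One document per record; the text is the title (TI) and abstract (AB)
    joined by a single space.  The PMID becomes the document id.  A record
    without a PMID, or two records sharing one, is an error.
    """
    path = Path(path)
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for idx, rec in enumerate(Medline.parse(handle)):
            pmid = rec.get("PMID")
            if not pmid:
                raise ValueError(f"MEDLINE record #{idx} in {path} lacks a PMID")
            if pmid in seen:
                raise ValueError(f"duplicate PMID {pmid!r} in {path}")
            seen.add(pmid)
            parts = [rec.get("TI", ""), rec.get("AB", "")]
            text = " ".join(p for p in parts if p)
            docs.append(Document(doc_id=pmid, text=text))
    return Corpus(docs)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a sidecar label file: one ``doc_id<TAB>label`` pair per line."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                doc_id, label = line.split("\t")
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: expected 'doc_id<TAB>label', got {line!r}"
                ) from None
            labels[doc_id] = label
    return labels


_FIELDS = ("id", "text", "label")


def read_labeled(path: str | Path, dialect: str = "jsonl") -> Corpus:
    """Read a labeled corpus in the JSONL or CSV dialect."""
    path = Path(path)
    if dialect == "jsonl":
        return _read_jsonl(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'jsonl' or 'csv')")


def _read_jsonl(path: Path) -> Corpus:
    docs = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            rec = json.loads(line)
            for f in _FIELDS:
                if f not in rec:
                    raise ValueError(f"{path}:{lineno}: record missing field {f!r}")
            docs.append(Document(str(rec["id"]), rec["text"], rec["label"]))
    return Corpus(docs)


def _read_csv(path: Path) -> Corpus:
    docs = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        for lineno, rec in enumerate(reader, 2):  # line 1 is the header
            for f in _FIELDS:
                if rec.get(f) is None:
                    raise ValueError(f"{path}:{lineno}: record missing field {f!r}")
            docs.append(Document(rec["id"], rec["text"], rec["label"]))
    return Corpus(docs)


def write_labeled(corpus: Corpus, path: str | Path, dialect: str = "jsonl") -> None:
    """Write a corpus in the labeled JSONL or CSV dialect."""
    path = Path(path)
    if dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as handle:
            for d in corpus:
                json.dump(
                    {"id": d.doc_id, "text": d.text, "label": d.label},
                    handle,
                    ensure_ascii=False,
                )
                handle.write("\n")
    elif dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(_FIELDS)
            for d in corpus:
                writer.writerow([d.doc_id, d.text, d.label])
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'jsonl' or 'csv')")


def train_test_split(
    corpus: Corpus, train_fraction: float, seed: int
) -> tuple[Corpus, Corpus]:
    """Randomly split a corpus into disjoint training and test parts.

    The training part receives ``round(n * train_fraction)`` documents
    (round-half-up) after a seeded uniform shuffle.  The same seed always
    produces the same split.
    """
    if len(corpus) == 0:
        raise ValueError("cannot split an empty corpus")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(corpus)
    # round-half-up, which round() does not do for .5 ties
    n_train = int(n * train_fraction + 0.5)
    rng = random.Random(seed)
    order = list(range(n))
    rng.shuffle(order)
    return corpus.subset(sorted(order[:n_train])), corpus.subset(
        sorted(order[n_train:])
    )
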