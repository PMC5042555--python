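"""Text preprocessing: normalization, tokenization, stop words, stemming.

The chain mirrors standard bag-of-words preparation for biomedical
abstracts: every character outside ``[a-z0-9]`` and whitespace is replaced
by a space (hyphens included, so "p53-mediated" splits into two tokens
while digits survive for gene symbols like p53), text is lower-cased,
split on whitespace, filtered against a stop-word list, optionally run
through a repeated-character collapse, and finally Porter-stemmed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from ._porter import porter_stem
from .corpus_io import Document

__all__ = [
    "TokenSequence",
    "StopwordList",
    "normalize_text",
    "tokenize",
    "remove_stopwords",
    "collapse_repeats",
    "porter_stem",
    "preprocess_document",
    "load_stopwords",
    "default_stopwords",
]

_NON_ALNUM = re.compile(r"[^a-z0-9\s]")
_HAS_DIGIT = re.compile(r"\d")
_REPEAT_RUN = re.compile(r"(.)\1{2,}")


@dataclass(frozen=True)
class TokenSequence:
    """Ordered lowercase tokens originating from one document."""

    tokens: tuple[str, ...]
    doc_id: Optional[str] = None

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class StopwordList:
    terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = [t for t in self.terms if t != t.lower() or not t]
        if bad:
            raise ValueError(f"stopwords must be lowercase and non-empty: {bad[:5]}")

    def __contains__(self, token: str) -> bool:
        return token in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def normalize_text(text: str) -> str:
    """Lower-case and replace every character outside [a-z0-9] and
    whitespace with a single space.  Idempotent and total."""
    return _NON_ALNUM.sub(" ", text.lower())


def tokenize(text: str, doc_id: Optional[str] = None) -> TokenSequence:
    """Split normalized text on whitespace runs, dropping empties."""
    return TokenSequence(tuple(text.split()), doc_id=doc_id)


def remove_stopwords(tokens: TokenSequence, stopwords: StopwordList) -> TokenSequence:
    return TokenSequence(
        tuple(t for t in tokens if t not in stopwords), doc_id=tokens.doc_id
    )


def collapse_repeats(token: str) -> str:
    """Collapse any run of three or more identical characters to one
    ("coooool" -> "col").  Runs of exactly two are legitimate English
    spelling and are preserved."""
    return _REPEAT_RUN.sub(r"\1", token)


def _stem_token(token: str) -> str:
    # gene symbols and other digit-bearing tokens pass through unstemmed
    if _HAS_DIGIT.search(token):
        return token
    return porter_stem(token)


def preprocess_document(
    doc: Document,
    stopwords: Optional[StopwordList] = None,
    collapse: bool = False,
) -> TokenSequence:
    """Full chain: normalize -> tokenize -> stop-word removal ->
    (optional repeat collapse) -> Porter stemming."""
    if stopwords is None:
        stopwords = default_stopwords()
    tokens = tokenize(normalize_text(doc.text), doc_id=doc.doc_id)
    tokens = remove_stopwords(tokens, stopwords)
    out = []
    for t in tokens:
        if collapse:
            t = collapse_repeats(t)
        out.append(_stem_token(t))
    return TokenSequence(tuple(out), doc_id=doc.doc_id)


def load_stopwords(path: str | Path) -> StopwordList:
    """Load a stop-word file: one lowercase term per line, '#' comments."""
    terms = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            term = line.split("#", 1)[0].strip()
            if term:
                terms.add(term)
    return StopwordList(frozenset(terms))


_DEFAULT: Optional[StopwordList] = None


def default_stopwords() -> StopwordList:
    """The bundled English stop-word list (data/stopwords_en.txt)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = (
            resources.files("litclf").joinpath("data/stopwords_en.txt").read_text()
        )
        terms = {
            t
            for line in text.splitlines()
            if (t := line.split("#", 1)[0].strip())
        }
        _DEFAULT = StopwordList(frozenset(terms))
    return _DEFAULT
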