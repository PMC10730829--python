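"""Bag-of-words features over word and character n-grams.

A transcript is a token sequence.  Tokens are normalised (lower-cased,
leading/trailing punctuation stripped); word n-grams are built over the
normalised sequence and character n-grams within word boundaries, each word
padded with a ``#`` marker on both sides (so ``abc`` yields the 3-grams
``#ab``, ``abc``, ``bc#``).  The vocabulary is fixed after being built on the
training folds: features below a document-frequency threshold are dropped
and, if a cap is exceeded, the highest-document-frequency features are kept
with a lexicographic tie-break.

Word-level occlusion removes every instance of a word *before* n-gram
extraction, so all word and character n-grams touching the word disappear
from the encoding — the primitive behind the occlusion explainability
analysis.
"""

from __future__ import annotations

import json
import string
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Vocabulary",
    "FeatureVector",
    "normalize_token",
    "tokenize",
    "build_vocabulary",
    "vectorize",
    "vectorize_corpus",
    "occlude_word",
]

BOUNDARY = "#"
_STRIP = string.punctuation + string.whitespace


def normalize_token(token: str) -> str:
    return token.strip(_STRIP).lower()


def tokenize(text: str) -> list[str]:
    """Whitespace tokenizer with punctuation stripping; drops empty tokens."""
    return [t for t in (normalize_token(p) for p in text.split()) if t]


def _word_ngrams(words: Sequence[str], n_range: tuple[int, int]) -> Iterable[str]:
    lo, hi = n_range
    for n in range(lo, hi + 1):
        for i in range(len(words) - n + 1):
            yield " ".join(words[i : i + n])


def _char_ngrams(words: Sequence[str], n_range: tuple[int, int]) -> Iterable[str]:
    lo, hi = n_range
    for w in words:
        padded = BOUNDARY + w + BOUNDARY
        for n in range(lo, hi + 1):
            for i in range(len(padded) - n + 1):
                yield padded[i : i + n]


@dataclass
class Vocabulary:
    """Fixed, ordered n-gram lexicon mapping features to columns.

    Feature keys are ``("word", gram)`` / ``("char", gram)`` tuples; ``index``
    is a bijection onto ``0..size-1``.
    """

    word_ngrams: list[str]
    char_ngrams: list[str]
    index: dict[tuple[str, str], int]
    doc_freq: dict[tuple[str, str], int]
    word_n_range: tuple[int, int]
    char_n_range: Optional[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.index)

    def word_unigrams(self) -> list[str]:
        return [g for g in self.word_ngrams if " " not in g]

    def to_json(self, path: str | Path) -> None:
        entries = [
            {"type": kind, "feature": gram, "column": col, "doc_freq": self.doc_freq[(kind, gram)]}
            for (kind, gram), col in sorted(self.index.items(), key=lambda kv: kv[1])
        ]
        payload = {
            "word_n_range": list(self.word_n_range),
            "char_n_range": list(self.char_n_range) if self.char_n_range else None,
            "provenance": self.provenance,
            "features": entries,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        index, doc_freq, words, chars = {}, {}, [], []
        for e in payload["features"]:
            key = (e["type"], e["feature"])
            index[key] = e["column"]
            doc_freq[key] = e["doc_freq"]
            (words if e["type"] == "word" else chars).append(e["feature"])
        return cls(
            word_ngrams=words,
            char_ngrams=chars,
            index=index,
            doc_freq=doc_freq,
            word_n_range=tuple(payload["word_n_range"]),
            char_n_range=tuple(payload["char_n_range"]) if payload["char_n_range"] else None,
            provenance=payload.get("provenance", {}),
        )


@dataclass
class FeatureVector:
    values: np.ndarray  # length-V non-negative counts
    call_id: Optional[str] = None


def _doc_features(tokens: Sequence[str], word_n_range, char_n_range) -> Counter:
    words = [normalize_token(t) for t in tokens]
    words = [w for w in words if w]
    feats: Counter = Counter()
    for g in _word_ngrams(words, word_n_range):
        feats[("word", g)] += 1
    if char_n_range is not None:
        for g in _char_ngrams(words, char_n_range):
            feats[("char", g)] += 1
    return feats


def build_vocabulary(
    transcripts: Iterable[Sequence[str]],
    word_n_range: tuple[int, int] = (1, 2),
    char_n_range: Optional[tuple[int, int]] = (3, 5),
    min_doc_freq: int = 5,
    max_features: int = 50_000,
) -> Vocabulary:
    """Build a fixed vocabulary from a training corpus.

    Document-frequency filtering (``min_doc_freq``) followed, if needed, by a
    cap at ``max_features`` keeping the highest-document-frequency features
    with lexicographic tie-break.  Deterministic in its inputs.
    """
    df: Counter = Counter()
    n_docs = 0
    for tokens in transcripts:
        n_docs += 1
        df.update(_doc_features(tokens, word_n_range, char_n_range).keys())
    if n_docs == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    kept = [(key, c) for key, c in df.items() if c >= min_doc_freq]
    if len(kept) > max_features:
        kept.sort(key=lambda kc: (-kc[1], kc[0]))
        kept = kept[:max_features]
    # Stable column order: words first, then chars, lexicographic within kind.
    kept.sort(key=lambda kc: kc[0])
    index = {key: col for col, (key, _) in enumerate(kept)}
    doc_freq = dict(kept)
    return Vocabulary(
        word_ngrams=[g for (kind, g) in index if kind == "word"],
        char_ngrams=[g for (kind, g) in index if kind == "char"],
        index=index,
        doc_freq=doc_freq,
        word_n_range=word_n_range,
        char_n_range=char_n_range,
        provenance={
            "n_documents": n_docs,
            "min_doc_freq": min_doc_freq,
            "max_features": max_features,
            "n_candidates": len(df),
        },
    )


def _doc_column_counts(tokens: Sequence[str], vocab: Vocabulary) -> Counter:
    feats = _doc_features(tokens, vocab.word_n_range, vocab.char_n_range)
    cols: Counter = Counter()
    for key, c in feats.items():
        col = vocab.index.get(key)
        if col is not None:
            cols[col] += c
    return cols


def vectorize(tokens: Sequence[str], vocab: Vocabulary, call_id: Optional[str] = None) -> FeatureVector:
    """Encode one transcript as a dense count vector over the vocabulary."""
    values = np.zeros(vocab.size)
    for col, c in _doc_column_counts(tokens, vocab).items():
        values[col] = c
    return FeatureVector(values=values, call_id=call_id)


def vectorize_corpus(transcripts: Iterable[Sequence[str]], vocab: Vocabulary) -> sparse.csr_matrix:
    """Encode a corpus as a sparse (n_docs x vocabulary size) count matrix."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for tokens in transcripts:
        cols = _doc_column_counts(tokens, vocab)
        indices.extend(cols.keys())
        data.extend(cols.values())
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64), np.asarray(indices, dtype=np.int32), np.asarray(indptr, dtype=np.int64)),
        shape=(len(indptr) - 1, vocab.size),
    )


def occlude_word(tokens: Sequence[str], word: str) -> list[str]:
    """Remove every instance of ``word`` (normalised comparison), preserving order."""
    target = normalize_token(word)
    return [t for t in tokens if normalize_token(t) != target]
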