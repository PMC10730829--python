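"""Occlusion explainability: word impact and signed-square ranking scores.

A word's impact on one transcript is the mean, over the N ensemble members,
of the drop in the raw logit when every instance of the word is removed
before vectorisation (so all word and character n-grams touching it vanish):

    i(d, w) = (1/N) * sum_n [ z(n, d) - z(n, d, w-occluded) ]

Logits, not sigmoid scores, are differenced: near-saturated scores would
squash any difference towards zero.  Words are ranked for inspection by the
sum of signed squares over the documents of the analysed prediction group,

    r(w) = sum_d sgn(i(d, w)) * i(d, w)^2

which favours rare, high-impact words over common, low-impact ones.  The
analysed groups are the model's predicted-stroke and predicted-non-stroke
calls; the run with the median validation F1 (of an odd number of seeded
runs) supplies the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

from .classifier import EnsembleModel
from .features import Vocabulary, normalize_token, occlude_word, vectorize_corpus

__all__ = [
    "WordScore",
    "OcclusionReport",
    "impact_score",
    "ranking_score",
    "occlusion_report",
    "top_words",
    "select_median_model",
]


def impact_score(
    ensemble: EnsembleModel, vocab: Vocabulary, tokens: Sequence[str], word: str
) -> float:
    """Impact of one word on one document; exactly 0 when the word is absent."""
    target = normalize_token(word)
    if all(normalize_token(t) != target for t in tokens):
        return 0.0
    X = vectorize_corpus([tokens, occlude_word(tokens, word)], vocab)
    z = ensemble.member_logits(X)  # (N, 2)
    return float(np.mean(z[:, 0] - z[:, 1]))


def ranking_score(impacts: Sequence[float]) -> float:
    """Sum of signed squares of the per-document impacts."""
    arr = np.asarray(list(impacts), dtype=np.float64)
    return float(np.sum(np.sign(arr) * arr**2))


@dataclass
class WordScore:
    rank_score: float
    occurrences: int  # number of analysed documents containing the word
    mean_impact: float


@dataclass
class OcclusionReport:
    per_word: dict[str, WordScore]
    per_doc_impacts: dict[tuple[str, str], float]  # (doc_id, word) -> impact
    D: int  # documents in the analysed prediction group
    group: str  # "stroke_predictions" | "non_stroke_predictions"


def occlusion_report(
    ensemble: EnsembleModel,
    vocab: Vocabulary,
    documents: Mapping[str, Sequence[str]],
    group: str,
    candidate_words: Optional[Sequence[str]] = None,
    batch_size: int = 4096,
) -> OcclusionReport:
    """Impact and ranking scores over one prediction group.

    ``documents`` maps document id to token sequence for the analysed group.
    Candidate words default to the vocabulary's word unigrams; per document,
    only candidates actually present are occluded (absent words have impact
    exactly zero and contribute nothing to the ranking sum).
    """
    if candidate_words is None:
        candidate_words = vocab.word_unigrams()
    candidates = {normalize_token(w) for w in candidate_words}

    doc_ids = list(documents.keys())
    doc_tokens = {d: list(documents[d]) for d in doc_ids}
    base_X = vectorize_corpus([doc_tokens[d] for d in doc_ids], vocab)
    base_z = ensemble.member_logits(base_X).mean(axis=0)  # (D,)
    base_by_doc = dict(zip(doc_ids, base_z))

    # Enumerate (doc, word) occlusion variants, batched through the ensemble.
    variants: list[tuple[str, str]] = []
    for d in doc_ids:
        present = {normalize_token(t) for t in doc_tokens[d]} & candidates
        variants.extend((d, w) for w in sorted(present))

    per_doc_impacts: dict[tuple[str, str], float] = {}
    for start in range(0, len(variants), batch_size):
        chunk = variants[start : start + batch_size]
        X = vectorize_corpus([occlude_word(doc_tokens[d], w) for d, w in chunk], vocab)
        z_occ = ensemble.member_logits(X).mean(axis=0)
        for (d, w), z in zip(chunk, z_occ):
            per_doc_impacts[(d, w)] = float(base_by_doc[d] - z)

    per_word: dict[str, list[float]] = {}
    for (d, w), impact in per_doc_impacts.items():
        per_word.setdefault(w, []).append(impact)
    scores = {
        w: WordScore(
            rank_score=ranking_score(impacts),
            occurrences=len(impacts),
            mean_impact=float(np.mean(impacts)),
        )
        for w, impacts in per_word.items()
    }
    return OcclusionReport(per_word=scores, per_doc_impacts=per_doc_impacts, D=len(doc_ids), group=group)


def top_words(
    report: OcclusionReport, k: int = 30, direction: str = "positive"
) -> list[tuple[str, float, int, float]]:
    """Top-k words by ranking score, with occurrence counts.

    ``direction="positive"`` sorts descending (stroke-indicating words on the
    predicted-stroke group); ``"negative"`` ascending.  Ties break
    lexicographically; a k larger than the vocabulary truncates.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    sign = -1.0 if direction == "positive" else 1.0
    ranked = sorted(report.per_word.items(), key=lambda kv: (sign * kv[1].rank_score, kv[0]))
    return [
        (w, s.rank_score, s.occurrences, s.mean_impact) for w, s in ranked[: min(k, len(ranked))]
    ]


def select_median_model(validation_f1s: Sequence[float]) -> int:
    """Index of the run with the median validation F1 (odd run count).

    With ties, the first run index attaining the median value is returned;
    an even run count is rejected (supply an explicit tie rule instead).
    """
    f1s = list(validation_f1s)
    if len(f1s) % 2 == 0:
        raise ValueError(
            f"median-run selection needs an odd number of runs, got {len(f1s)}; "
            "drop or add a run, or pick explicitly"
        )
    median = sorted(f1s)[len(f1s) // 2]
    for i, v in enumerate(f1s):
        if v == median:
            return i
    raise AssertionError("unreachable")
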