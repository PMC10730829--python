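"""Word impact (logit-difference) and signed-square ranking scores."""

import numpy as np
import pytest

from strokecall.classifier import EnsembleModel, MLPConfig, TrainedMember
from strokecall.features import build_vocabulary, vectorize
from strokecall.mlp import DenseNet, sigmoid
from strokecall.occlusion import (
    impact_score,
    occlusion_report,
    ranking_score,
    select_median_model,
    top_words,
)

WORDS = ["stroke", "left", "fever", "knee", "filler"]


def _linear_member(weights: dict[str, float], vocab, bias: float = 0.0) -> TrainedMember:
    """A member with hand-set linear weights (no hidden layer)."""
    net = DenseNet(n_features=vocab.size, hidden_sizes=(), seed=0)
    w = np.zeros((vocab.size, 1))
    for word, value in weights.items():
        w[vocab.index[("word", word)], 0] = value
    net.W = [w]
    net.b = [np.array([bias])]
    cfg = MLPConfig(hidden_sizes=())
    return TrainedMember(net=net, config=cfg, best_stop_f1=1.0, stop_f1_trajectory=[], n_epochs=0)


@pytest.fixture(scope="module")
def linear_setup():
    vocab = build_vocabulary([WORDS], word_n_range=(1, 1), char_n_range=None, min_doc_freq=1)
    m1 = _linear_member({"stroke": 2.0, "left": 1.0, "fever": -1.5, "knee": -0.5}, vocab)
    m2 = _linear_member({"stroke": 3.0, "left": 0.5, "fever": -2.5, "knee": -1.0}, vocab, bias=0.2)
    ensemble = EnsembleModel(members=[m1, m2], member_configs=[m1.config, m2.config], fold_assignment=[0, 1])
    return vocab, ensemble


def test_absent_word_has_exactly_zero_impact(linear_setup):
    vocab, ens = linear_setup
    assert impact_score(ens, vocab, ["stroke", "left"], "fever") == 0.0


def test_impact_is_mean_member_logit_difference(linear_setup):
    vocab, ens = linear_setup
    # Occluding "stroke" from [stroke, left] drops member logits by (2.0, 3.0).
    assert impact_score(ens, vocab, ["stroke", "left"], "stroke") == pytest.approx(2.5, abs=1e-12)
    # Duplicated words: both instances removed.
    assert impact_score(ens, vocab, ["stroke", "stroke"], "stroke") == pytest.approx(5.0, abs=1e-12)
    # Negative-weight word: negative impact.
    assert impact_score(ens, vocab, ["fever", "left"], "fever") == pytest.approx(-2.0, abs=1e-12)


def test_occluding_every_token_leaves_bias_logit(linear_setup):
    vocab, ens = linear_setup
    doc = ["stroke", "stroke"]
    base = ens.member_logits(vectorize(doc, vocab).values[None, :]).mean()
    empty = ens.member_logits(np.zeros((1, vocab.size))).mean()
    assert impact_score(ens, vocab, doc, "stroke") == pytest.approx(base - empty, abs=1e-12)


@pytest.mark.parametrize(
    "impacts,expected",
    [([0.5, -0.5], 0.0), ([2.0], 4.0), ([-3.0, 1.0], -8.0)],
)
def test_ranking_score_signed_squares(impacts, expected):
    assert ranking_score(impacts) == pytest.approx(expected)


@pytest.fixture(scope="module")
def linear_report(linear_setup):
    vocab, ens = linear_setup
    docs = {
        "d1": ["stroke", "left", "filler"],
        "d2": ["stroke", "filler"],
        "d3": ["fever", "knee", "filler"],
        "d4": ["left", "fever"],
    }
    return docs, occlusion_report(ens, vocab, docs, group="stroke_predictions")


def test_report_counts_documents_containing_each_word(linear_report):
    docs, report = linear_report
    assert report.D == 4
    assert report.per_word["stroke"].occurrences == 2
    assert report.per_word["fever"].occurrences == 2
    assert report.per_word["filler"].occurrences == 3


def test_report_matches_brute_force_recomputation(linear_setup, linear_report):
    """Independent loop: re-vectorise every (doc, word) pair from scratch."""
    vocab, ens = linear_setup
    docs, report = linear_report
    for d, tokens in docs.items():
        for w in set(tokens):
            kept = [t for t in tokens if t != w]
            z_full = np.mean([m.logits(vectorize(tokens, vocab).values[None, :]) for m in ens.members])
            z_occ = np.mean([m.logits(vectorize(kept, vocab).values[None, :]) for m in ens.members])
            assert report.per_doc_impacts[(d, w)] == pytest.approx(z_full - z_occ, abs=1e-12)
    for w, ws in report.per_word.items():
        impacts = [v for (d, w2), v in report.per_doc_impacts.items() if w2 == w]
        assert ws.rank_score == pytest.approx(
            sum(np.sign(i) * i**2 for i in impacts), abs=1e-12
        )


def test_rank_score_is_document_order_invariant(linear_setup, linear_report):
    vocab, ens = linear_setup
    docs, report = linear_report
    reordered = dict(reversed(list(docs.items())))
    other = occlusion_report(ens, vocab, reordered, group="stroke_predictions")
    for w in report.per_word:
        assert other.per_word[w].rank_score == pytest.approx(report.per_word[w].rank_score, abs=1e-12)


def test_top_words_directions_and_truncation(linear_report):
    _, report = linear_report
    pos = top_words(report, k=2, direction="positive")
    assert [w for w, *_ in pos] == ["stroke", "left"]
    neg = top_words(report, k=2, direction="negative")
    assert neg[0][0] == "fever"
    assert len(top_words(report, k=100, direction="positive")) == len(report.per_word)
    with pytest.raises(ValueError):
        top_words(report, direction="sideways")


def test_negating_logits_swaps_positive_and_negative_lists(linear_setup, linear_report):
    vocab, ens = linear_setup
    docs, report = linear_report
    flipped_members = []
    for m in ens.members:
        net = DenseNet(n_features=vocab.size, hidden_sizes=(), seed=0)
        net.W = [-m.net.W[0]]
        net.b = [-m.net.b[0]]
        flipped_members.append(
            TrainedMember(net=net, config=m.config, best_stop_f1=0.0, stop_f1_trajectory=[], n_epochs=0)
        )
    flipped = EnsembleModel(flipped_members, [m.config for m in ens.members], [0, 1])
    flipped_report = occlusion_report(flipped, vocab, docs, group="non_stroke_predictions")
    pos = [w for w, *_ in top_words(report, k=10, direction="positive")]
    neg_flipped = [w for w, *_ in top_words(flipped_report, k=10, direction="negative")]
    assert pos == neg_flipped


def test_impact_uses_logits_not_sigmoid_scores(linear_setup):
    """On a saturated document the logit-space impact stays large while the
    score-space difference collapses towards zero."""
    vocab, _ = linear_setup
    strong = _linear_member({"stroke": 10.0, "left": 10.0}, vocab)
    ens = EnsembleModel([strong], [strong.config], [0])
    doc = ["stroke", "left", "left"]
    imp = impact_score(ens, vocab, doc, "stroke")
    assert imp == pytest.approx(10.0, abs=1e-9)
    x_full = vectorize(doc, vocab).values[None, :]
    x_occ = vectorize(["left", "left"], vocab).values[None, :]
    score_diff = sigmoid(strong.logits(x_full)) - sigmoid(strong.logits(x_occ))
    assert abs(score_diff) < 1e-4


@pytest.mark.parametrize(
    "f1s,expected",
    [([0.3, 0.5, 0.4], 2), ([0.7, 0.7, 0.7], 0)],
)
def test_median_model_selection(f1s, expected):
    assert select_median_model(f1s) == expected


def test_median_model_is_sixth_order_statistic_of_eleven():
    rng = np.random.default_rng(0)
    f1s = rng.random(11).tolist()
    idx = select_median_model(f1s)
    assert f1s[idx] == sorted(f1s)[5]


def test_even_run_count_rejected():
    with pytest.raises(ValueError, match="odd"):
        select_median_model([0.1, 0.2])
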