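"""Metrics, curves, permutation tests and bootstrap confidence intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecall.evaluation import (
    ConfusionCounts,
    aggregate_confusion,
    aggregate_runs,
    bootstrap_ci,
    compute_metrics,
    independent_permutation_test,
    paired_permutation_test,
    roc_and_pr_curves,
)


# ----------------------------------------------------------------- metrics
def test_metrics_hand_computed_small_case():
    m = compute_metrics(ConfusionCounts(tp=5, fp=0, fn=5, tn=90))
    assert m.sensitivity == 0.5
    assert m.ppv == 1.0
    assert m.fpr == 0.0
    assert m.f1 == pytest.approx(2 / 3)


def test_metrics_triage_scale_case():
    """Imbalanced confusion matrix typical of helpline triage."""
    m = compute_metrics(ConfusionCounts(tp=40, fp=194, fn=36, tn=34130))
    assert m.sensitivity == pytest.approx(40 / 76)
    assert m.ppv == pytest.approx(40 / 234)
    assert m.for_ == pytest.approx(36 / 34166)
    assert m.fpr == pytest.approx(194 / 34324)


def test_undefined_metrics_are_flagged():
    m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=10, tn=90))
    assert m.sensitivity == 0.0
    assert np.isnan(m.ppv) and "ppv" in m.undefined
    z = compute_metrics(ConfusionCounts(0, 0, 0, 0))
    assert set(z.undefined) == {"f1", "sensitivity", "ppv", "for", "fpr"}


@settings(max_examples=100, deadline=None)
@given(st.tuples(*[st.integers(min_value=0, max_value=500)] * 4))
def test_metric_identities(counts):
    tp, fp, fn, tn = counts
    m = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
    if fn + tn > 0:
        npv = tn / (fn + tn)
        assert m.for_ + npv == pytest.approx(1.0)
    if fp + tn > 0:
        specificity = tn / (fp + tn)
        assert m.fpr + specificity == pytest.approx(1.0)
    if not np.isnan(m.f1) and not np.isnan(m.ppv) and not np.isnan(m.sensitivity) and (m.ppv + m.sensitivity) > 0:
        assert m.f1 == pytest.approx(2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity))


# ------------------------------------------------------------------ curves
def test_roc_endpoints_and_perfect_separation():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([True, True, False, False])
    c = roc_and_pr_curves(scores, labels)
    assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
    assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
    assert any(f == 0.0 and t == 1.0 for f, t in zip(c.fpr, c.tpr))
    assert c.auroc == 1.0


def test_pr_full_recall_endpoint_is_prevalence():
    rng = np.random.default_rng(0)
    labels = rng.random(500) < 0.2
    c = roc_and_pr_curves(rng.random(500), labels)
    assert c.recall[-1] == 1.0
    assert c.precision[-1] == pytest.approx(labels.mean())


def test_score_negation_reflects_auroc():
    rng = np.random.default_rng(1)
    scores = rng.random(800)
    labels = rng.random(800) < (0.2 + 0.5 * scores)
    a = roc_and_pr_curves(scores, labels).auroc
    b = roc_and_pr_curves(1 - scores, labels).auroc
    assert a + b == pytest.approx(1.0, abs=1e-9)


def test_random_scores_auroc_near_half():
    rng = np.random.default_rng(2)
    labels = rng.random(4000) < 0.3
    c = roc_and_pr_curves(rng.random(4000), labels)
    assert c.auroc == pytest.approx(0.5, abs=0.04)


def test_roc_matches_sklearn_oracle():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(3)
    scores = np.round(rng.random(300), 2)
    labels = rng.random(300) < (0.1 + 0.7 * scores)
    ours = roc_and_pr_curves(scores, labels)
    assert ours.auroc == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-12)
    fpr, tpr, _ = sk.roc_curve(labels, scores, drop_intermediate=False)
    assert np.allclose(ours.fpr, fpr) and np.allclose(ours.tpr, tpr)


def test_single_class_curves_rejected():
    with pytest.raises(ValueError):
        roc_and_pr_curves(np.array([0.1, 0.9]), np.array([True, True]))


# ------------------------------------------------------------- paired test
def test_identical_systems_give_p_near_one():
    rng = np.random.default_rng(4)
    labels = rng.random(300) < 0.3
    pred = rng.random(300) < 0.4
    res = paired_permutation_test(pred, pred, labels, metric="f1", n_perm=500, seed=0)
    assert res.observed_stat == 0.0
    assert res.p_value > 0.49


def test_perfect_vs_random_is_highly_significant():
    rng = np.random.default_rng(5)
    labels = rng.random(500) < 0.3
    random_pred = rng.random(500) < 0.5
    res = paired_permutation_test(labels, random_pred, labels, metric="f1", n_perm=5000, seed=1)
    assert res.p_value < 0.001


def test_paired_length_mismatch_rejected():
    with pytest.raises(ValueError):
        paired_permutation_test(np.ones(5, bool), np.ones(4, bool), np.ones(5, bool))


def test_paired_multirun_broadcast_and_determinism():
    rng = np.random.default_rng(6)
    labels = rng.random(200) < 0.3
    runs = rng.random((3, 200)) < 0.4
    single = rng.random(200) < 0.4
    a = paired_permutation_test(runs, single, labels, metric="sensitivity", n_perm=300, seed=2)
    b = paired_permutation_test(runs, single, labels, metric="sensitivity", n_perm=300, seed=2)
    assert a.p_value == b.p_value
    assert a.test_type == "paired"


def _null_pair(rng, n=400):
    labels = rng.random(n) < 0.3
    u_a, u_b = rng.random(n), rng.random(n)
    pred_a = np.where(labels, u_a < 0.7, u_a < 0.2)
    pred_b = np.where(labels, u_b < 0.7, u_b < 0.2)
    return labels, pred_a, pred_b


def test_paired_type_i_error_quick():
    """~5% rejections under H0 (coarse 100-replicate check)."""
    rng = np.random.default_rng(7)
    rejections = 0
    for i in range(100):
        labels, a, b = _null_pair(rng)
        res = paired_permutation_test(a, b, labels, metric="f1", n_perm=400, seed=1000 + i)
        rejections += res.p_value < 0.05
    assert 0 <= rejections <= 12


# -------------------------------------------------------- independent test
def test_independent_empty_group_rejected():
    with pytest.raises(ValueError):
        independent_permutation_test(
            np.ones(5, bool), np.ones(5, bool), np.zeros(0, bool), np.zeros(0, bool)
        )


def test_independent_extreme_separation_hits_smoothing_floor():
    n = 200
    labels = np.tile([True, False], n // 2)
    perfect = labels.copy()
    inverted = ~labels
    res = independent_permutation_test(
        perfect, labels, inverted, labels, metric="sensitivity", n_perm=999, seed=0
    )
    assert res.p_value <= 1 / (1 + 999) + 0.01


def test_independent_type_i_error_quick():
    rng = np.random.default_rng(8)
    rejections = 0
    for i in range(100):
        labels_x, a, _ = _null_pair(rng, n=250)
        labels_y, b, _ = _null_pair(rng, n=200)
        res = independent_permutation_test(
            a, labels_x, b, labels_y, metric="sensitivity", n_perm=400, seed=2000 + i
        )
        rejections += res.p_value < 0.05
    assert 0 <= rejections <= 12


# ----------------------------------------------------------------- bootstrap
def test_bootstrap_constant_perfect_predictions():
    labels = np.array([True] * 20 + [False] * 80)
    ci = bootstrap_ci(labels.copy(), labels, metric="sensitivity", n_boot=200, seed=0)
    assert (ci.low, ci.high) == (1.0, 1.0)


def test_bootstrap_matches_normal_approximation_for_proportion():
    """Sensitivity of Bernoulli predictions on all-positive labels is a plain
    proportion; percentile bootstrap ~ normal-approximation interval."""
    rng = np.random.default_rng(9)
    n = 1000
    labels = np.ones(n, dtype=bool)
    pred = rng.random(n) < 0.5
    p_hat = pred.mean()
    ci = bootstrap_ci(pred, labels, metric="sensitivity", n_boot=4000, seed=1)
    half = 1.96 * np.sqrt(p_hat * (1 - p_hat) / n)
    assert ci.low == pytest.approx(p_hat - half, abs=0.01)
    assert ci.high == pytest.approx(p_hat + half, abs=0.01)


def test_bootstrap_stability_under_more_replicates():
    rng = np.random.default_rng(10)
    labels = rng.random(600) < 0.3
    pred = np.where(labels, rng.random(600) < 0.7, rng.random(600) < 0.1)
    a = bootstrap_ci(pred, labels, metric="f1", n_boot=2000, seed=3)
    b = bootstrap_ci(pred, labels, metric="f1", n_boot=4000, seed=4)
    assert a.low == pytest.approx(b.low, abs=0.02)
    assert a.high == pytest.approx(b.high, abs=0.02)


def test_bootstrap_reports_skipped_replicates():
    labels = np.array([True] + [False] * 99)
    pred = np.zeros(100, dtype=bool)
    pred[0] = True  # PPV undefined whenever the one predicted-positive call is not resampled
    ci = bootstrap_ci(pred, labels, metric="ppv", n_boot=300, seed=5)
    assert ci.n_skipped > 0
    assert ci.n_boot + ci.n_skipped == 300


# --------------------------------------------------------------- aggregation
def test_aggregate_runs_means():
    a = compute_metrics(ConfusionCounts(6, 4, 4, 86))
    b = compute_metrics(ConfusionCounts(7, 3, 3, 87))
    agg = aggregate_runs([a, b])
    assert agg.sensitivity == pytest.approx((0.6 + 0.7) / 2)
    assert agg.n_runs == 2
    single = aggregate_runs([a])
    assert single.as_dict() == pytest.approx(a.as_dict())


def test_aggregate_confusion_rounded_mean_sums_close():
    counts = [ConfusionCounts(5, 10, 5, 80), ConfusionCounts(6, 9, 4, 81), ConfusionCounts(4, 12, 6, 78)]
    agg = aggregate_confusion(counts)
    assert abs(agg.total - 100) <= 2
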