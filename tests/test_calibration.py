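"""Threshold matching, harmonic-mean calibration and logit-centred ensembling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecall.calibration import (
    ThresholdSet,
    ensemble_score,
    find_matching_thresholds,
    harmonic_threshold,
)
from strokecall.evaluation import metric_from_predictions, roc_and_pr_curves
from strokecall.mlp import logit, sigmoid


# ---------------------------------------------------------------- thresholds
def test_matching_thresholds_on_perfectly_separating_scores():
    scores = np.array([0.9] * 10 + [0.1] * 90)
    labels = np.array([True] * 10 + [False] * 90)
    t_sens, t_ppv = find_matching_thresholds(scores, labels, ref_sens=0.9, ref_ppv=0.9)
    assert t_sens == 0.9 and t_ppv == 0.9


def test_zero_reference_sensitivity_gives_threshold_one():
    scores = np.array([0.2, 0.8, 0.6, 0.3])
    labels = np.array([False, True, True, False])
    t_sens, _ = find_matching_thresholds(scores, labels, ref_sens=0.0, ref_ppv=0.5)
    assert t_sens == 1.0


def test_prevalence_reference_ppv_gives_near_zero_threshold():
    rng = np.random.default_rng(0)
    scores = rng.random(2000)
    labels = rng.random(2000) < 0.3
    prevalence = labels.mean()
    _, t_ppv = find_matching_thresholds(scores, labels, ref_sens=0.5, ref_ppv=prevalence)
    assert t_ppv <= np.quantile(scores, 0.05)


def test_unattainable_ppv_raises_with_maximum():
    scores = np.array([0.6, 0.5, 0.4, 0.3])
    labels = np.array([False, False, True, False])  # max PPV = 1/3
    with pytest.raises(ValueError, match="maximum attainable"):
        find_matching_thresholds(scores, labels, ref_sens=0.5, ref_ppv=0.9)


def test_threshold_scan_matches_exhaustive_oracle():
    """Largest/smallest qualifying thresholds agree with a brute-force scan."""
    rng = np.random.default_rng(5)
    scores = np.round(rng.random(300), 2)  # ties on purpose
    labels = rng.random(300) < (0.2 + 0.6 * scores)
    ref_sens, ref_ppv = 0.6, 0.5
    t_sens, t_ppv = find_matching_thresholds(scores, labels, ref_sens, ref_ppv)
    grid = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    sens_ok = []
    ppv_ok = []
    for t in grid:
        pred = scores >= t
        tp = np.sum(pred & labels)
        sens_ok.append(t if tp / labels.sum() >= ref_sens else None)
        ppv_ok.append(t if pred.sum() and tp / pred.sum() >= ref_ppv else None)
    assert t_sens == max(t for t in sens_ok if t is not None)
    assert t_ppv == min(t for t in ppv_ok if t is not None)


# ------------------------------------------------------------ harmonic mean
def test_harmonic_mean_closed_forms():
    assert harmonic_threshold(0.2, 0.8) == pytest.approx(0.32)
    assert harmonic_threshold(0.5, 1.0) == pytest.approx(2 / 3)


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=1e-6, max_value=1.0))
def test_harmonic_mean_identity(t):
    assert harmonic_threshold(t, t) == pytest.approx(t)


def test_harmonic_mean_rejects_nonpositive_and_out_of_range():
    with pytest.raises(ValueError):
        harmonic_threshold(0.0, 0.5)
    with pytest.raises(ValueError):
        harmonic_threshold(0.5, 1.2)


def test_harmonic_mean_brackets_inputs():
    tau = harmonic_threshold(0.3, 0.7)
    assert 0.3 <= tau <= 0.7


# ------------------------------------------------------------- ensembling
def test_centring_identity_members_at_their_thresholds():
    tau = np.array([0.2, 0.5, 0.7, 0.31, 0.62])
    ts = ThresholdSet(tau=tau, t_sens=tau, t_ppv=tau, reference_sens=0.5, reference_ppv=0.2)
    z = logit(tau)[:, None]
    score = ensemble_score(z, ts)
    assert abs(score.score[0] - 0.5) < 1e-12


def test_single_member_reduces_to_plain_thresholding():
    rng = np.random.default_rng(1)
    scores = rng.random(500)
    tau = 0.37
    ts = ThresholdSet(
        tau=np.array([tau]), t_sens=np.array([tau]), t_ppv=np.array([tau]),
        reference_sens=0.5, reference_ppv=0.2,
    )
    ens = ensemble_score(logit(scores)[None, :], ts)
    assert np.array_equal(ens.predictions, scores >= tau)


def test_two_member_closed_form():
    ts = ThresholdSet(
        tau=np.array([0.5, 0.5]), t_sens=np.array([0.5, 0.5]), t_ppv=np.array([0.5, 0.5]),
        reference_sens=0.5, reference_ppv=0.2,
    )
    out = ensemble_score(np.array([[2.0], [0.0]]), ts)
    assert out.centred_logits.mean() == pytest.approx(1.0)
    assert out.score[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-9)


def test_threshold_outside_unit_interval_rejected():
    ts = ThresholdSet(
        tau=np.array([1.0]), t_sens=np.array([1.0]), t_ppv=np.array([1.0]),
        reference_sens=0.5, reference_ppv=0.2,
    )
    with pytest.raises(ValueError):
        ensemble_score(np.array([[0.0]]), ts)


def test_raising_a_member_logit_never_lowers_the_score():
    rng = np.random.default_rng(2)
    z = rng.normal(size=(5, 40))
    tau = np.full(5, 0.4)
    ts = ThresholdSet(tau=tau, t_sens=tau, t_ppv=tau, reference_sens=0.5, reference_ppv=0.2)
    base = ensemble_score(z, ts).score
    for n in range(5):
        bumped = z.copy()
        bumped[n] += 0.5
        assert (ensemble_score(bumped, ts).score >= base - 1e-12).all()


# ------------------------------------------- calibration on a score fixture
@pytest.fixture(scope="module")
def member_fixture():
    """Five correlated members: shared signal logit plus member noise."""
    rng = np.random.default_rng(9)
    n = 4000
    labels = rng.random(n) < 0.1
    signal = np.where(labels, 1.8, -1.8) + rng.normal(0, 1.2, n)
    member_logits = signal[None, :] + rng.normal(0, 0.7, (5, n)) + rng.normal(0, 0.2, (5, 1))
    return member_logits, labels


def test_ensemble_roc_dominates_members(member_fixture):
    member_logits, labels = member_fixture
    ts = ThresholdSet.calibrate(sigmoid(member_logits), labels, 0.527, 0.171)
    ens = ensemble_score(member_logits, ts)
    ens_curve = roc_and_pr_curves(ens.score, labels)
    grid = np.linspace(0.02, 0.6, 15)
    ens_tpr = np.interp(grid, ens_curve.fpr, ens_curve.tpr)
    for n in range(member_logits.shape[0]):
        c = roc_and_pr_curves(sigmoid(member_logits[n]), labels)
        member_tpr = np.interp(grid, c.fpr, c.tpr)
        assert (ens_tpr >= member_tpr - 0.02).all()


def test_ensemble_sensitivity_bracketed_by_member_operating_points(member_fixture):
    """At the centred threshold 0.5, ensemble sensitivity and PPV lie inside
    the band spanned by each member's t_sens and t_ppv operating points."""
    member_logits, labels = member_fixture
    scores = sigmoid(member_logits)
    ts = ThresholdSet.calibrate(scores, labels, 0.527, 0.171)
    ens = ensemble_score(member_logits, ts)
    ens_sens = metric_from_predictions("sensitivity", ens.predictions, labels)
    ens_ppv = metric_from_predictions("ppv", ens.predictions, labels)
    for n in range(scores.shape[0]):
        ops = {}
        for name, t in (("t_sens", ts.t_sens[n]), ("t_ppv", ts.t_ppv[n])):
            pred = scores[n] >= t
            ops[name] = (
                metric_from_predictions("sensitivity", pred, labels),
                metric_from_predictions("ppv", pred, labels),
            )
        sens_lo = min(ops["t_sens"][0], ops["t_ppv"][0])
        sens_hi = max(ops["t_sens"][0], ops["t_ppv"][0])
        assert sens_lo - 0.05 <= ens_sens <= sens_hi + 0.05
        ppv_lo = min(ops["t_sens"][1], ops["t_ppv"][1])
        ppv_hi = max(ops["t_sens"][1], ops["t_ppv"][1])
        assert ppv_lo - 0.05 <= ens_ppv <= ppv_hi + 0.05
    # The calibrated tau always lies between its two operating points.
    assert ((ts.tau >= np.minimum(ts.t_sens, ts.t_ppv)) & (ts.tau <= np.maximum(ts.t_sens, ts.t_ppv))).all()
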