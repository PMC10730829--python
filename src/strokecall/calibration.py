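"""Per-member threshold calibration and logit-centred ensembling.

Each ensemble member gets its own decision threshold tau_n, the harmonic mean
of two operating points found on the calibration split: t_sens, the largest
threshold whose sensitivity still reaches the call-takers' sensitivity, and
t_ppv, the smallest threshold whose PPV reaches the call-takers' PPV.  This
pins each member to a sensitivity/PPV trade-off comparable to human triage.

Because tau_n differs across members, raw score averaging would be
meaningless; instead each member's logit is centred by subtracting
logit(tau_n), giving every member the common decision threshold 0.5, and the
ensemble score is the sigmoid of the mean centred logit.  (The original
supplementary equations are not public; these formulas are reconstructed
from the main-text description.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mlp import logit, sigmoid

__all__ = [
    "ThresholdSet",
    "EnsembleScore",
    "find_matching_thresholds",
    "harmonic_threshold",
    "ensemble_score",
]


def find_matching_thresholds(
    scores: np.ndarray,
    labels: np.ndarray,
    ref_sens: float,
    ref_ppv: float,
) -> tuple[float, float]:
    """Operating points matching reference sensitivity and PPV.

    Decisions are ``score >= t``.  Searching the finite grid of observed
    scores plus {0, 1}: ``t_sens`` is the largest threshold with sensitivity
    >= ``ref_sens``; ``t_ppv`` the smallest threshold with attainable PPV
    >= ``ref_ppv``.  Raises ``ValueError`` naming the maximum attainable PPV
    when the reference PPV cannot be reached at any threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("calibration requires at least one positive and one negative label")

    grid = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order].astype(np.int64)
    cum_pos = np.concatenate([[0], np.cumsum(sorted_pos)])
    # At threshold t, predictions are scores >= t.
    first_ge = np.searchsorted(sorted_scores, grid, side="left")
    tp = n_pos - cum_pos[first_ge]
    predicted = scores.size - first_ge
    sens = tp / n_pos
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(predicted > 0, tp / np.maximum(predicted, 1), np.nan)

    ok_sens = sens >= ref_sens
    t_sens = float(grid[np.flatnonzero(ok_sens)[-1]])  # sens(0) = 1, never empty
    ok_ppv = (predicted > 0) & (ppv >= ref_ppv)
    hits = np.flatnonzero(ok_ppv)
    if hits.size == 0:
        raise ValueError(
            f"reference PPV {ref_ppv} unattainable: maximum attainable PPV is {np.nanmax(ppv):.6g}"
        )
    t_ppv = float(grid[hits[0]])
    return t_sens, t_ppv


def harmonic_threshold(t_sens: float, t_ppv: float) -> float:
    """Harmonic mean of the two matched operating points: 2ab / (a + b)."""
    if t_sens <= 0 or t_ppv <= 0:
        raise ValueError(f"thresholds must be positive, got ({t_sens}, {t_ppv})")
    if t_sens > 1 or t_ppv > 1:
        raise ValueError(f"thresholds must lie in (0, 1], got ({t_sens}, {t_ppv})")
    return 2.0 * t_sens * t_ppv / (t_sens + t_ppv)


@dataclass
class ThresholdSet:
    """Calibrated per-member thresholds tau_n with their operating points."""

    tau: np.ndarray  # (N,)
    t_sens: np.ndarray  # (N,)
    t_ppv: np.ndarray  # (N,)
    reference_sens: float
    reference_ppv: float

    @classmethod
    def calibrate(
        cls,
        member_scores: np.ndarray,
        labels: np.ndarray,
        reference_sens: float,
        reference_ppv: float,
    ) -> "ThresholdSet":
        """Calibrate each member of a (N, n_calls) score matrix."""
        t_sens_list, t_ppv_list, tau_list = [], [], []
        for row in np.atleast_2d(member_scores):
            ts, tp = find_matching_thresholds(row, labels, reference_sens, reference_ppv)
            t_sens_list.append(ts)
            t_ppv_list.append(tp)
            tau_list.append(harmonic_threshold(ts, tp))
        return cls(
            tau=np.array(tau_list),
            t_sens=np.array(t_sens_list),
            t_ppv=np.array(t_ppv_list),
            reference_sens=reference_sens,
            reference_ppv=reference_ppv,
        )

    def to_dict(self) -> dict:
        return {
            "tau": self.tau.tolist(),
            "t_sens": self.t_sens.tolist(),
            "t_ppv": self.t_ppv.tolist(),
            "reference_sens": self.reference_sens,
            "reference_ppv": self.reference_ppv,
        }


@dataclass
class EnsembleScore:
    """Centred ensemble output with the common decision threshold 0.5."""

    centred_logits: np.ndarray  # (N, n)
    score: np.ndarray  # (n,)

    decision_threshold: float = 0.5

    @property
    def predictions(self) -> np.ndarray:
        return self.score >= self.decision_threshold


def ensemble_score(member_logits: np.ndarray, thresholds: ThresholdSet) -> EnsembleScore:
    """Combine member logits: score = sigmoid(mean_n (z_n - logit(tau_n))).

    If every member sits exactly at its threshold the ensemble score is 0.5.
    """
    z = np.atleast_2d(np.asarray(member_logits, dtype=np.float64))
    tau = np.asarray(thresholds.tau, dtype=np.float64)
    if np.any((tau <= 0.0) | (tau >= 1.0)):
        raise ValueError(f"thresholds must lie strictly inside (0, 1), got {tau}")
    if tau.shape[0] != z.shape[0]:
        raise ValueError("one threshold per member is required")
    centred = z - logit(tau)[:, None]
    return EnsembleScore(centred_logits=centred, score=sigmoid(centred.mean(axis=0)))
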