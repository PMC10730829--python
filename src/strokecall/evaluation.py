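"""Metrics, curves, approximate permutation tests and bootstrap CIs.

Reported metrics are F1, sensitivity, PPV, FOR (1 - NPV) and FPR
(1 - specificity): on a heavily imbalanced call stream NPV and specificity
are both >99% and their complements are the informative quantities.

Significance testing follows the study design: one-sided *paired* approximate
permutation tests for comparisons on the same calls (each call's prediction
pair is swapped independently with probability 1/2 under the null; when a
system has several seeded training runs, one swap mask is shared across runs
and the statistic is the run-averaged metric difference) and one-sided
*independent* approximate permutation tests across disjoint subsets (calls
reassigned between groups preserving group sizes).  P-values use add-one
smoothing, p = (1 + #{null >= observed}) / (1 + n_perm).  Confidence
intervals are percentile bootstrap over calls, metrics averaged over runs
within each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "PermutationResult",
    "BootstrapCI",
    "CurveSet",
    "compute_metrics",
    "metric_from_predictions",
    "roc_and_pr_curves",
    "paired_permutation_test",
    "independent_permutation_test",
    "bootstrap_ci",
    "aggregate_runs",
    "aggregate_confusion",
    "METRICS",
]

METRICS = ("f1", "sensitivity", "ppv", "for", "fpr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, pred, labels) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        labels = np.asarray(labels, dtype=bool)
        if pred.shape != labels.shape:
            raise ValueError("prediction/label length mismatch")
        return cls(
            tp=int(np.sum(pred & labels)),
            fp=int(np.sum(pred & ~labels)),
            fn=int(np.sum(~pred & labels)),
            tn=int(np.sum(~pred & ~labels)),
        )


def _metric_arrays(name: str, tp, fp, fn, tn):
    """Vectorised metric from confusion-count arrays; NaN where undefined."""
    tp, fp, fn, tn = (np.asarray(x, dtype=np.float64) for x in (tp, fp, fn, tn))
    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "sensitivity":
            return np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        if name == "ppv":
            return np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        if name == "f1":
            denom = 2 * tp + fp + fn
            return np.where(denom > 0, 2 * tp / denom, np.nan)
        if name == "for":
            return np.where(fn + tn > 0, fn / (fn + tn), np.nan)
        if name == "fpr":
            return np.where(fp + tn > 0, fp / (fp + tn), np.nan)
    raise ValueError(f"unknown metric {name!r}; choose from {METRICS}")


def metric_from_predictions(name: str, pred, labels) -> float:
    c = ConfusionCounts.from_predictions(pred, labels)
    return float(_metric_arrays(name, c.tp, c.fp, c.fn, c.tn))


@dataclass
class MetricSet:
    """The five reported metrics; NaN entries are flagged in ``undefined``."""

    f1: float
    sensitivity: float
    ppv: float
    for_: float
    fpr: float
    n_runs: int = 1
    undefined: tuple[str, ...] = ()
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "for": self.for_,
            "fpr": self.fpr,
        }


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Exact metric ratios from one confusion matrix."""
    values = {name: float(_metric_arrays(name, counts.tp, counts.fp, counts.fn, counts.tn)) for name in METRICS}
    undefined = tuple(name for name, v in values.items() if np.isnan(v))
    return MetricSet(
        f1=values["f1"],
        sensitivity=values["sensitivity"],
        ppv=values["ppv"],
        for_=values["for"],
        fpr=values["fpr"],
        undefined=undefined,
    )


@dataclass
class CurveSet:
    """ROC and PPV-sensitivity (precision-recall) curves.

    ROC is the step function from (0, 0) to (1, 1) through every distinct
    score threshold; the PR curve's full-recall endpoint has PPV equal to the
    class prevalence (threshold below every score, i.e. predict everything
    positive).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    pr_thresholds: np.ndarray
    auroc: float


def roc_and_pr_curves(scores, labels) -> CurveSet:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to draw curves")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.flatnonzero(np.diff(sorted_scores)) if scores.size > 1 else np.array([], int)
    cut = np.concatenate([distinct, [scores.size - 1]])  # last index of each score block
    tps = np.cumsum(sorted_labels)[cut]
    fps = (cut + 1) - tps
    thresholds = sorted_scores[cut]

    fpr = np.concatenate([[0.0], fps / n_neg])
    tpr = np.concatenate([[0.0], tps / n_pos])
    roc_thresholds = np.concatenate([[np.inf], thresholds])
    auroc = float(np.trapezoid(tpr, fpr))

    # The final block (threshold = lowest score) predicts everything positive,
    # so the full-recall endpoint has PPV equal to the class prevalence.
    recall = tps / n_pos
    precision = tps / (tps + fps)
    pr_thresholds = thresholds
    return CurveSet(
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=roc_thresholds,
        recall=recall,
        precision=precision,
        pr_thresholds=pr_thresholds,
        auroc=auroc,
    )


@dataclass
class PermutationResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    test_type: str  # "paired" | "independent"
    alternative: str  # "greater" | "less"
    metric: str
    n_skipped: int = 0


def _as_runs(pred) -> np.ndarray:
    arr = np.asarray(pred, dtype=bool)
    return arr[None, :] if arr.ndim == 1 else arr


def _counts_over_perms(pred_mat: np.ndarray, labels: np.ndarray):
    """Confusion counts per row of a (m, n) boolean prediction matrix."""
    pos = labels[None, :]
    tp = np.sum(pred_mat & pos, axis=1)
    fp = np.sum(pred_mat & ~pos, axis=1)
    fn = np.sum(~pred_mat & pos, axis=1)
    tn = np.sum(~pred_mat & ~pos, axis=1)
    return tp, fp, fn, tn


def _run_metric(name: str, pred_runs: np.ndarray, labels: np.ndarray) -> float:
    tp, fp, fn, tn = _counts_over_perms(pred_runs, labels)
    return float(np.nanmean(_metric_arrays(name, tp, fp, fn, tn)))


def paired_permutation_test(
    pred_a,
    pred_b,
    labels,
    metric: str = "f1",
    alternative: str = "greater",
    n_perm: int = 10_000,
    seed: int = 0,
    chunk: int = 256,
) -> PermutationResult:
    """One-sided paired approximate permutation test on the same calls.

    ``pred_a`` / ``pred_b`` are boolean vectors of length n or (runs, n)
    matrices; a single-run system is broadcast against a multi-run one.  The
    statistic is the run-averaged metric(A) - metric(B); under the null each
    call's (A, B) pair is swapped independently with probability 1/2, the
    same swap mask applied to every run.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    A, B = _as_runs(pred_a), _as_runs(pred_b)
    labels = np.asarray(labels, dtype=bool)
    if A.shape[1] != labels.size or B.shape[1] != labels.size:
        raise ValueError("prediction/label length mismatch")
    if A.shape[0] != B.shape[0]:
        if A.shape[0] == 1:
            A = np.broadcast_to(A, B.shape)
        elif B.shape[0] == 1:
            B = np.broadcast_to(B, A.shape)
        else:
            raise ValueError("run counts differ and neither system is single-run")
    n_runs, n = A.shape

    observed = _run_metric(metric, A, labels) - _run_metric(metric, B, labels)
    if np.isnan(observed):
        raise ValueError(f"metric {metric!r} undefined on the observed predictions")

    rng = np.random.default_rng(seed)
    diff = A ^ B  # (runs, n): calls where swapping changes anything
    eps = 1e-12
    n_extreme = 0
    n_valid = 0
    n_skipped = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        masks = rng.random((m, n)) < 0.5
        stats = np.empty(m)
        for r in range(n_runs):
            swap = masks & diff[r][None, :]
            a_perm = A[r][None, :] ^ swap
            b_perm = B[r][None, :] ^ swap
            tp, fp, fn, tn = _counts_over_perms(a_perm, labels)
            stat_a = _metric_arrays(metric, tp, fp, fn, tn)
            tp, fp, fn, tn = _counts_over_perms(b_perm, labels)
            stat_b = _metric_arrays(metric, tp, fp, fn, tn)
            part = stat_a - stat_b
            stats = part if r == 0 else stats + part
        stats = stats / n_runs
        valid = ~np.isnan(stats)
        n_skipped += int(m - valid.sum())
        n_valid += int(valid.sum())
        if alternative == "greater":
            n_extreme += int(np.sum(stats[valid] >= observed - eps))
        else:
            n_extreme += int(np.sum(stats[valid] <= observed + eps))
        done += m
    p = (1 + n_extreme) / (1 + n_valid)
    return PermutationResult(
        observed_stat=observed,
        p_value=p,
        n_permutations=n_valid,
        test_type="paired",
        alternative=alternative,
        metric=metric,
        n_skipped=n_skipped,
    )


def independent_permutation_test(
    pred_x,
    labels_x,
    pred_y,
    labels_y,
    metric: str = "f1",
    alternative: str = "greater",
    n_perm: int = 10_000,
    seed: int = 0,
    chunk: int = 128,
) -> PermutationResult:
    """One-sided independent approximate permutation test across disjoint subsets.

    The statistic is the run-averaged metric(X) - metric(Y); the null
    reassigns calls (with their prediction/label pairs) between the groups
    uniformly at random, preserving group sizes.  Null replicates where the
    metric is undefined in either group are skipped and counted.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    X, Y = _as_runs(pred_x), _as_runs(pred_y)
    lx = np.asarray(labels_x, dtype=bool)
    ly = np.asarray(labels_y, dtype=bool)
    if X.shape[1] != lx.size or Y.shape[1] != ly.size:
        raise ValueError("prediction/label length mismatch")
    if lx.size == 0 or ly.size == 0:
        raise ValueError("both groups must be non-empty")
    if X.shape[0] != Y.shape[0]:
        if X.shape[0] == 1:
            X = np.broadcast_to(X, (Y.shape[0], X.shape[1]))
        elif Y.shape[0] == 1:
            Y = np.broadcast_to(Y, (X.shape[0], Y.shape[1]))
        else:
            raise ValueError("run counts differ and neither system is single-run")
    n_runs = X.shape[0]
    nx, ny = lx.size, ly.size

    observed = _run_metric(metric, X, lx) - _run_metric(metric, Y, ly)
    if np.isnan(observed):
        raise ValueError(f"metric {metric!r} undefined on the observed groups")

    pool_pred = np.concatenate([X, Y], axis=1)  # (runs, nx+ny)
    pool_lab = np.concatenate([lx, ly])
    rng = np.random.default_rng(seed)
    eps = 1e-12
    n_extreme = 0
    n_valid = 0
    n_skipped = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # Random group assignment preserving sizes: argsort of uniforms.
        perm = np.argsort(rng.random((m, nx + ny)), axis=1)
        idx_x, idx_y = perm[:, :nx], perm[:, nx:]
        lab_x, lab_y = pool_lab[idx_x], pool_lab[idx_y]
        stats = np.zeros(m)
        for r in range(n_runs):
            part = _rowwise_metric(metric, pool_pred[r][idx_x], lab_x) - _rowwise_metric(
                metric, pool_pred[r][idx_y], lab_y
            )
            stats = part if r == 0 else stats + part
        stats = stats / n_runs
        valid = ~np.isnan(stats)
        n_skipped += int(m - valid.sum())
        n_valid += int(valid.sum())
        if alternative == "greater":
            n_extreme += int(np.sum(stats[valid] >= observed - eps))
        else:
            n_extreme += int(np.sum(stats[valid] <= observed + eps))
        done += m
    p = (1 + n_extreme) / (1 + n_valid)
    return PermutationResult(
        observed_stat=observed,
        p_value=p,
        n_permutations=n_valid,
        test_type="independent",
        alternative=alternative,
        metric=metric,
        n_skipped=n_skipped,
    )


def _rowwise_metric(name: str, pred_mat: np.ndarray, lab_mat: np.ndarray) -> np.ndarray:
    """Metric per row where each row has its own label vector."""
    tp = np.sum(pred_mat & lab_mat, axis=1)
    fp = np.sum(pred_mat & ~lab_mat, axis=1)
    fn = np.sum(~pred_mat & lab_mat, axis=1)
    tn = np.sum(~pred_mat & ~lab_mat, axis=1)
    return _metric_arrays(name, tp, fp, fn, tn)


@dataclass
class BootstrapCI:
    low: float
    high: float
    n_boot: int
    n_skipped: int
    level: float


def bootstrap_ci(
    per_run_predictions,
    labels,
    metric: str = "f1",
    n_boot: int = 1_000,
    seed: int = 0,
    level: float = 0.95,
    chunk: int = 256,
) -> BootstrapCI:
    """Percentile bootstrap CI over calls, metric averaged over runs.

    Each replicate resamples calls with replacement, computes the metric per
    run on the resampled calls and averages over runs; the interval is the
    (1-level)/2 and 1-(1-level)/2 percentiles.  Replicates where the metric
    is undefined in any run are skipped and counted.
    """
    runs = _as_runs(per_run_predictions)
    labels = np.asarray(labels, dtype=bool)
    if runs.shape[1] != labels.size:
        raise ValueError("prediction/label length mismatch")
    n_runs, n = runs.shape
    # Per (run, call) outcome category: 2*pred + label -> {TN, FN, FP, TP}.
    cat = 2 * runs.astype(np.int8) + labels.astype(np.int8)[None, :]

    rng = np.random.default_rng(seed)
    reps: list[np.ndarray] = []
    n_skipped = 0
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        stats = np.zeros(m)
        for r in range(n_runs):
            c = cat[r][idx]  # (m, n)
            tp = np.sum(c == 3, axis=1)
            fp = np.sum(c == 2, axis=1)
            fn = np.sum(c == 1, axis=1)
            tn = np.sum(c == 0, axis=1)
            stats += _metric_arrays(metric, tp, fp, fn, tn)
        stats /= n_runs
        valid = ~np.isnan(stats)
        n_skipped += int(m - valid.sum())
        reps.append(stats[valid])
        done += m
    replicates = np.concatenate(reps)
    if replicates.size == 0:
        raise ValueError(f"metric {metric!r} undefined in every bootstrap replicate")
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(replicates, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(low=float(low), high=float(high), n_boot=int(replicates.size), n_skipped=n_skipped, level=level)


def aggregate_runs(run_metrics: Sequence[MetricSet]) -> MetricSet:
    """Mean of each metric over seeded training runs (NaN-aware)."""
    if not run_metrics:
        raise ValueError("at least one run is required")
    values = {name: np.array([m.as_dict()[name] for m in run_metrics]) for name in METRICS}
    means = {name: float(np.nanmean(v)) if not np.all(np.isnan(v)) else float("nan") for name, v in values.items()}
    undefined = tuple(name for name, v in means.items() if np.isnan(v))
    return MetricSet(
        f1=means["f1"],
        sensitivity=means["sensitivity"],
        ppv=means["ppv"],
        for_=means["for"],
        fpr=means["fpr"],
        n_runs=len(run_metrics),
        undefined=undefined,
    )


def aggregate_confusion(run_counts: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Confusion matrix reported as the rounded mean over runs."""
    if not run_counts:
        raise ValueError("at least one run is required")
    return ConfusionCounts(
        tp=int(round(float(np.mean([c.tp for c in run_counts])))),
        fp=int(round(float(np.mean([c.fp for c in run_counts])))),
        fn=int(round(float(np.mean([c.fn for c in run_counts])))),
        tn=int(round(float(np.mean([c.tn for c in run_counts])))),
    )
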