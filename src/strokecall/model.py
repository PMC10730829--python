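"""Model/Results facade over the full recognition pipeline.

`StrokeCallData.prepare` turns a cohort (calls + registry + transcripts) into
the analysis-ready dataset: registry-linked labels, the subset/fold
assignment, a vocabulary built on the training folds only, and sparse
bag-of-words matrices per subset.  `StrokeRecognitionModel.fit` then trains
the five-member ensemble for a number of seeded runs, calibrates per-member
thresholds on the validation split against the call-takers' operating point,
and returns a `StrokeRecognitionResults` carrying test-set predictions,
aggregated metrics with bootstrap CIs, permutation comparisons against the
call-takers, a text `summary()`, and the occlusion analysis of the
median-F1 run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import evaluation, linkage
from .calibration import ThresholdSet, ensemble_score
from .classifier import EnsembleModel, MLPConfig, train_ensemble
from .evaluation import (
    BootstrapCI,
    ConfusionCounts,
    MetricSet,
    PermutationResult,
    aggregate_confusion,
    aggregate_runs,
    bootstrap_ci,
    compute_metrics,
    paired_permutation_test,
    roc_and_pr_curves,
)
from .features import Vocabulary, build_vocabulary, vectorize_corpus
from .occlusion import OcclusionReport, occlusion_report, select_median_model, top_words
from .synthetic import SyntheticCohort

__all__ = ["StrokeCallData", "StrokeRecognitionModel", "StrokeRecognitionResults", "RunArtifacts"]


@dataclass
class StrokeCallData:
    """Analysis-ready dataset: labelled calls, subsets, features."""

    calls: pd.DataFrame  # labelled, with a 'subset' column
    vocab: Vocabulary
    X: sparse.csr_matrix  # row-aligned with calls
    y: np.ndarray  # ground-truth labels
    calltaker: np.ndarray  # call-taker labels
    transcripts: dict[str, list[str]]
    n_folds: int = 5

    @classmethod
    def prepare(
        cls,
        cohort: SyntheticCohort,
        test_year: int = 2021,
        n_folds: int = 5,
        validation_fraction: float = 0.1,
        word_n_range: tuple[int, int] = (1, 1),
        char_n_range: Optional[tuple[int, int]] = None,
        min_doc_freq: int = 5,
        max_features: int = 50_000,
        seed: int = 0,
        use_emergency_line: bool = True,
    ) -> "StrokeCallData":
        """Link, split and featurize a cohort.

        ``use_emergency_line=False`` is the ablation arm that drops the
        supplementary emergency-line training data.
        """
        labelled = linkage.label_calls(cohort.calls, cohort.registry)
        subset = linkage.split_dataset(
            labelled, test_year=test_year, n_folds=n_folds,
            validation_fraction=validation_fraction, seed=seed,
        )
        labelled = labelled.assign(subset=subset)
        if not use_emergency_line:
            labelled.loc[labelled["subset"] == "train_extra", "subset"] = "discarded"
        fold_names = [f"train_fold_{i}" for i in range(1, n_folds + 1)]
        train_mask = labelled["subset"].isin(fold_names)
        vocab = build_vocabulary(
            (cohort.transcripts[cid] for cid in labelled.loc[train_mask, "call_id"]),
            word_n_range=word_n_range,
            char_n_range=char_n_range,
            min_doc_freq=min_doc_freq,
            max_features=max_features,
        )
        X = vectorize_corpus((cohort.transcripts[cid] for cid in labelled["call_id"]), vocab)
        return cls(
            calls=labelled.reset_index(drop=True),
            vocab=vocab,
            X=X,
            y=labelled["ground_truth"].to_numpy(dtype=bool),
            calltaker=labelled["calltaker_positive"].to_numpy(dtype=bool),
            transcripts=cohort.transcripts,
            n_folds=n_folds,
        )

    # -- subset access -----------------------------------------------------
    def indices(self, subset: str) -> np.ndarray:
        return np.flatnonzero(self.calls["subset"].to_numpy() == subset)

    def fold_data(self) -> list[tuple[sparse.csr_matrix, np.ndarray]]:
        return [
            (self.X[idx], self.y[idx])
            for idx in (self.indices(f"train_fold_{i}") for i in range(1, self.n_folds + 1))
        ]

    def extra_data(self) -> Optional[tuple[sparse.csr_matrix, np.ndarray]]:
        idx = self.indices("train_extra")
        return (self.X[idx], self.y[idx]) if idx.size else None

    def subset_arrays(self, subset: str):
        idx = self.indices(subset)
        return self.X[idx], self.y[idx], self.calltaker[idx], idx


@dataclass
class RunArtifacts:
    ensemble: EnsembleModel
    thresholds: ThresholdSet
    validation_f1: float
    test_scores: np.ndarray
    test_predictions: np.ndarray


def _run_seed(seed: int, run: int) -> int:
    return int(np.random.SeedSequence([seed, 104729, run]).generate_state(1)[0] % (2**31))


class StrokeRecognitionModel:
    """Ensemble text classifier benchmarked against call-taker triage.

    Parameters
    ----------
    data : StrokeCallData
        Prepared dataset (see :meth:`StrokeCallData.prepare`).
    mlp_config : MLPConfig, optional
        Member hyperparameters (the run seed overrides ``config.seed``).
    reference_sensitivity, reference_ppv : float
        Call-taker operating point that threshold calibration matches.
    """

    def __init__(
        self,
        data: StrokeCallData,
        mlp_config: Optional[MLPConfig] = None,
        reference_sensitivity: float = 0.527,
        reference_ppv: float = 0.171,
    ):
        self.data = data
        self.mlp_config = mlp_config or MLPConfig()
        self.reference_sensitivity = reference_sensitivity
        self.reference_ppv = reference_ppv

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, mlp_config=None,
                    reference_sensitivity: float = 0.527, reference_ppv: float = 0.171,
                    **prepare_kwargs) -> "StrokeRecognitionModel":
        data = StrokeCallData.prepare(cohort, **prepare_kwargs)
        return cls(data, mlp_config, reference_sensitivity, reference_ppv)

    def fit(self, n_runs: int = 11, seed: int = 0) -> "StrokeRecognitionResults":
        """Train ``n_runs`` independently seeded ensembles and evaluate them."""
        import dataclasses as _dc

        data = self.data
        folds = data.fold_data()
        extra = data.extra_data()
        val_X, val_y, _, _ = data.subset_arrays("validation")
        test_X, test_y, test_ct, test_idx = data.subset_arrays("test")

        runs: list[RunArtifacts] = []
        for r in range(n_runs):
            cfg = _dc.replace(self.mlp_config, seed=_run_seed(seed, r))
            ensemble = train_ensemble(folds, extra, cfg)
            thresholds = ThresholdSet.calibrate(
                ensemble.member_scores(val_X), val_y,
                self.reference_sensitivity, self.reference_ppv,
            )
            val_score = ensemble_score(ensemble.member_logits(val_X), thresholds)
            val_f1 = evaluation.metric_from_predictions("f1", val_score.predictions, val_y)
            test_score = ensemble_score(ensemble.member_logits(test_X), thresholds)
            runs.append(
                RunArtifacts(
                    ensemble=ensemble,
                    thresholds=thresholds,
                    validation_f1=val_f1,
                    test_scores=test_score.score,
                    test_predictions=test_score.predictions,
                )
            )
        return StrokeRecognitionResults(
            model=self, runs=runs, test_labels=test_y, test_calltaker=test_ct, test_indices=test_idx
        )


@dataclass
class StrokeRecognitionResults:
    """Fitted ensemble runs with their test-set evaluation."""

    model: StrokeRecognitionModel
    runs: list[RunArtifacts]
    test_labels: np.ndarray
    test_calltaker: np.ndarray
    test_indices: np.ndarray

    # -- basic accessors -----------------------------------------------------
    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def prediction_matrix(self) -> np.ndarray:
        return np.stack([r.test_predictions for r in self.runs])

    @property
    def validation_f1s(self) -> list[float]:
        return [r.validation_f1 for r in self.runs]

    # -- metrics ---------------------------------------------------------------
    def run_metrics(self) -> list[MetricSet]:
        return [
            compute_metrics(ConfusionCounts.from_predictions(r.test_predictions, self.test_labels))
            for r in self.runs
        ]

    def model_metrics(self, n_boot: int = 1000, seed: int = 0) -> MetricSet:
        """Run-averaged test metrics with percentile-bootstrap 95% CIs."""
        agg = aggregate_runs(self.run_metrics())
        cis = {}
        for name in evaluation.METRICS:
            try:
                ci = bootstrap_ci(
                    self.prediction_matrix, self.test_labels, metric=name,
                    n_boot=n_boot, seed=seed,
                )
                cis[name] = (ci.low, ci.high)
            except ValueError:
                pass
        agg.ci = cis
        return agg

    def calltaker_metrics(self, n_boot: int = 1000, seed: int = 0) -> MetricSet:
        m = compute_metrics(ConfusionCounts.from_predictions(self.test_calltaker, self.test_labels))
        cis = {}
        for name in evaluation.METRICS:
            try:
                ci = bootstrap_ci(self.test_calltaker, self.test_labels, metric=name,
                                  n_boot=n_boot, seed=seed)
                cis[name] = (ci.low, ci.high)
            except ValueError:
                pass
        m.ci = cis
        return m

    def model_confusion(self) -> ConfusionCounts:
        """Rounded-mean confusion matrix over runs."""
        return aggregate_confusion(
            [ConfusionCounts.from_predictions(r.test_predictions, self.test_labels) for r in self.runs]
        )

    def calltaker_confusion(self) -> ConfusionCounts:
        return ConfusionCounts.from_predictions(self.test_calltaker, self.test_labels)

    # -- inference -------------------------------------------------------------
    def compare_with_calltakers(
        self, metric: str, alternative: str = "greater", n_perm: int = 10_000, seed: int = 0
    ) -> PermutationResult:
        """Paired permutation test: run-averaged model metric vs call-takers."""
        return paired_permutation_test(
            self.prediction_matrix, self.test_calltaker, self.test_labels,
            metric=metric, alternative=alternative, n_perm=n_perm, seed=seed,
        )

    # -- curves ---------------------------------------------------------------
    def curves(self, run: Optional[int] = None) -> evaluation.CurveSet:
        """ROC / PPV-sensitivity curves of one run's ensemble score
        (default: the median-validation-F1 run)."""
        r = self.median_run_index() if run is None else run
        return roc_and_pr_curves(self.runs[r].test_scores, self.test_labels)

    def plot_curves(self, path=None):
        """Fig.-1-style ROC and PPV-sensitivity plot; returns the figure."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        curves = self.curves()
        ct = self.calltaker_metrics(n_boot=10)
        fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(10, 4))
        ax_roc.plot(curves.fpr, curves.tpr, drawstyle="steps-post", label="ensemble")
        ax_roc.plot([ct.fpr], [ct.sensitivity], "r*", markersize=10, label="call-takers")
        ax_roc.set_xlabel("false positive rate")
        ax_roc.set_ylabel("sensitivity")
        ax_roc.set_xscale("log")
        ax_roc.legend()
        ax_pr.plot(curves.recall, curves.precision, label="ensemble")
        ax_pr.plot([ct.sensitivity], [ct.ppv], "r*", markersize=10, label="call-takers")
        ax_pr.set_xlabel("sensitivity")
        ax_pr.set_ylabel("PPV")
        ax_pr.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    # -- occlusion -------------------------------------------------------------
    def median_run_index(self) -> int:
        """Run used for occlusion: the median-validation-F1 run.

        The strict median needs an odd run count; for an even count this
        object's explicit tie rule is the lower middle order statistic
        (first run index attaining it).
        """
        f1s = self.validation_f1s
        if len(f1s) % 2 == 1:
            return select_median_model(f1s)
        target = sorted(f1s)[(len(f1s) - 1) // 2]
        return f1s.index(target)

    def occlusion(self, group: str = "stroke_predictions", k: int = 30):
        """Occlusion report and top-k list on the median run's predictions."""
        r = self.median_run_index()
        run = self.runs[r]
        mask = run.test_predictions if group == "stroke_predictions" else ~run.test_predictions
        data = self.model.data
        call_ids = data.calls["call_id"].to_numpy()[self.test_indices[mask]]
        docs = {cid: data.transcripts[cid] for cid in call_ids}
        report = occlusion_report(run.ensemble, data.vocab, docs, group=group)
        direction = "positive" if group == "stroke_predictions" else "negative"
        return report, top_words(report, k=k, direction=direction)

    # -- presentation -----------------------------------------------------------
    def summary(self, n_boot: int = 1000, seed: int = 0) -> str:
        """Text summary table of model vs call-taker test performance."""
        model_m = self.model_metrics(n_boot=n_boot, seed=seed)
        ct_m = self.calltaker_metrics(n_boot=n_boot, seed=seed)
        lines = [
            "Stroke recognition on helpline calls — test-set performance",
            "=" * 66,
            f"runs: {self.n_runs}    test calls: {self.test_labels.size}"
            f"    stroke calls: {int(self.test_labels.sum())}",
            "-" * 66,
            f"{'metric':<14}{'model mean':>12}{'(95% CI)':>20}{'call-takers':>14}",
        ]
        for name, label in (("f1", "F1 [%]"), ("sensitivity", "sens. [%]"),
                            ("ppv", "PPV [%]"), ("for", "FOR [%]"), ("fpr", "FPR [%]")):
            mv = model_m.as_dict()[name] * 100
            cv = ct_m.as_dict()[name] * 100
            lo, hi = model_m.ci.get(name, (float("nan"), float("nan")))
            lines.append(
                f"{label:<14}{mv:>12.2f}{f'({lo*100:.2f}-{hi*100:.2f})':>20}{cv:>14.2f}"
            )
        lines.append("-" * 66)
        cm = self.model_confusion()
        cc = self.calltaker_confusion()
        lines.append(f"model confusion (rounded mean): TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}")
        lines.append(f"call-taker confusion:           TP={cc.tp} FP={cc.fp} FN={cc.fn} TN={cc.tn}")
        return "\n".join(lines)
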