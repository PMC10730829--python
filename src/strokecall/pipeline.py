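"""End-to-end pipeline: generate -> link -> split -> featurize -> train x R
seeds -> calibrate -> evaluate -> occlude, with per-stage seeds derived from
one global seed and a manifest recording configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .classifier import MLPConfig
from .model import StrokeCallData, StrokeRecognitionModel, StrokeRecognitionResults
from .synthetic import ConfigurationError, GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "stage_seed"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed and the stage name."""
    return int(
        np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run needs."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    grid: Optional[list[MLPConfig]] = None
    n_runs: int = 11
    n_perm: int = 10_000
    n_boot: int = 1_000
    reference_sensitivity: float = 0.527
    reference_ppv: float = 0.171
    test_year: int = 2021
    n_folds: int = 5
    validation_fraction: float = 0.1
    word_n_range: tuple[int, int] = (1, 1)
    char_n_range: Optional[tuple[int, int]] = None
    min_doc_freq: int = 5
    max_features: int = 50_000
    use_emergency_line: bool = True
    occlusion_top_k: int = 30
    occlusion_max_docs: int = 2_000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["mlp"] = self.mlp.to_dict()
        d["grid"] = [g.to_dict() for g in self.grid] if self.grid else None
        d["word_n_range"] = list(self.word_n_range)
        d["char_n_range"] = list(self.char_n_range) if self.char_n_range else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["generator"] = GeneratorConfig.from_dict(d.get("generator", {}))
        d["mlp"] = MLPConfig.from_dict(d.get("mlp", {}))
        grid = d.get("grid")
        d["grid"] = [MLPConfig.from_dict(g) for g in grid] if grid else None
        if d.get("word_n_range"):
            d["word_n_range"] = tuple(d["word_n_range"])
        if d.get("char_n_range"):
            d["char_n_range"] = tuple(d["char_n_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _metricset_dict(m) -> dict:
    d = {k: v for k, v in m.as_dict().items()}
    d["ci"] = {k: list(v) for k, v in m.ci.items()}
    d["n_runs"] = m.n_runs
    return d


def run_pipeline(config: PipelineConfig, out_dir=None, make_figures: bool = True) -> dict:
    """Execute the full pipeline; optionally write all artefacts to ``out_dir``.

    Returns the results bundle (the content of results.json plus the fitted
    results object under ``"_results"``).  Any stage failure raises
    :class:`StageError` naming the stage; artefacts written so far remain.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    seeds = {
        stage: stage_seed(config.seed, stage)
        for stage in ("generate", "split", "train", "evaluate", "occlude")
    }

    def _stage(name, fn):
        try:
            return fn()
        except (StageError, ConfigurationError):
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    cohort = _stage(
        "generate",
        lambda: generate_cohort(dataclasses.replace(config.generator, seed=seeds["generate"])),
    )
    if out is not None:
        _stage("generate", lambda: cohort.to_files(out / "data"))

    data = _stage(
        "link",
        lambda: StrokeCallData.prepare(
            cohort,
            test_year=config.test_year,
            n_folds=config.n_folds,
            validation_fraction=config.validation_fraction,
            word_n_range=config.word_n_range,
            char_n_range=config.char_n_range,
            min_doc_freq=config.min_doc_freq,
            max_features=config.max_features,
            seed=seeds["split"],
            use_emergency_line=config.use_emergency_line,
        ),
    )

    model = StrokeRecognitionModel(
        data,
        mlp_config=config.mlp,
        reference_sensitivity=config.reference_sensitivity,
        reference_ppv=config.reference_ppv,
    )
    results = _stage("train", lambda: model.fit(n_runs=config.n_runs, seed=seeds["train"]))

    def _evaluate():
        model_m = results.model_metrics(n_boot=config.n_boot, seed=seeds["evaluate"])
        ct_m = results.calltaker_metrics(n_boot=config.n_boot, seed=seeds["evaluate"])
        p_values = {}
        for metric in ("sensitivity", "ppv", "f1"):
            res = results.compare_with_calltakers(
                metric, alternative="greater", n_perm=config.n_perm, seed=seeds["evaluate"]
            )
            p_values[metric] = {"p": res.p_value, "observed": res.observed_stat}
        cm, cc = results.model_confusion(), results.calltaker_confusion()
        return model_m, ct_m, p_values, cm, cc

    model_m, ct_m, p_values, cm, cc = _stage("evaluate", _evaluate)

    def _occlude():
        rng = np.random.default_rng(seeds["occlude"])
        _, pos_top = results.occlusion("stroke_predictions", k=config.occlusion_top_k)
        # The predicted-non-stroke group is large; rank on a seeded subsample.
        run = results.runs[results.median_run_index()]
        neg_mask = ~run.test_predictions
        neg_ids = data.calls["call_id"].to_numpy()[results.test_indices[neg_mask]]
        if neg_ids.size > config.occlusion_max_docs:
            neg_ids = rng.choice(neg_ids, size=config.occlusion_max_docs, replace=False)
        from .occlusion import occlusion_report, top_words

        neg_report = occlusion_report(
            run.ensemble, data.vocab,
            {cid: data.transcripts[cid] for cid in neg_ids},
            group="non_stroke_predictions",
        )
        neg_top = top_words(neg_report, k=config.occlusion_top_k, direction="negative")
        return pos_top, neg_top

    pos_top, neg_top = _stage("occlude", _occlude)

    bundle = {
        "config_hash": config.config_hash(),
        "n": {
            "calls": int(len(data.calls)),
            "test": int(results.test_labels.size),
            "test_stroke": int(results.test_labels.sum()),
            "validation": int(data.indices("validation").size),
            "runs": config.n_runs,
        },
        "metrics": {"model": _metricset_dict(model_m), "calltakers": _metricset_dict(ct_m)},
        "p_values": p_values,
        "confusion": {
            "model": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "calltakers": {"tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn},
        },
        "validation_f1": results.validation_f1s,
        "median_run": results.median_run_index(),
        "occlusion": {
            "stroke_predictions": [
                {"word": w, "rank_score": r, "occurrences": o, "mean_impact": mi}
                for w, r, o, mi in pos_top
            ],
            "non_stroke_predictions": [
                {"word": w, "rank_score": r, "occurrences": o, "mean_impact": mi}
                for w, r, o, mi in neg_top
            ],
        },
    }
    bundle = _round_floats(bundle)

    if out is not None:
        _stage("write", lambda: _write_artifacts(config, data, results, bundle, seeds, out, make_figures))
    bundle["_results"] = results
    return bundle


def _write_artifacts(config, data, results, bundle, seeds, out: Path, make_figures: bool) -> None:
    (out / "results.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    data.calls.to_csv(out / "labelled_calls.csv", index=False)
    data.vocab.to_json(out / "vocabulary.json")

    curves = results.curves()
    rows = [
        {"curve": "roc", "x": x, "y": y, "threshold": t}
        for x, y, t in zip(curves.fpr, curves.tpr, curves.roc_thresholds)
    ] + [
        {"curve": "pr", "x": x, "y": y, "threshold": t}
        for x, y, t in zip(curves.recall, curves.precision, curves.pr_thresholds)
    ]
    pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)

    occ_rows = []
    for group, entries in bundle["occlusion"].items():
        for e in entries:
            occ_rows.append({"group": group, **e})
    pd.DataFrame(occ_rows).to_csv(out / "occlusion.csv", index=False)

    thresholds = [r.thresholds.to_dict() for r in results.runs]
    (out / "thresholds.json").write_text(json.dumps(_round_floats(thresholds), indent=1))

    fold_sizes = [int(data.indices(f"train_fold_{i}").size) for i in range(1, config.n_folds + 1)]
    extra = data.extra_data()
    manifest = {
        "config_hash": bundle["config_hash"],
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "training_inputs": {
            "fold_sizes": fold_sizes,
            "extra_training_calls": int(extra[0].shape[0]) if extra is not None else 0,
            "use_emergency_line": config.use_emergency_line,
        },
        "subset_sizes": {
            s: int(data.indices(s).size)
            for s in ("validation", "test", "test_no_category", "discarded")
        },
        "artifacts": [
            "results.json", "curves.csv", "occlusion.csv", "thresholds.json",
            "labelled_calls.csv", "vocabulary.json", "data/calls.csv",
            "data/registry.csv", "data/transcripts.jsonl",
        ],
    }
    if make_figures:
        results.plot_curves(out / "roc_pr.png")
        manifest["artifacts"].append("roc_pr.png")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def save_results(results: StrokeRecognitionResults, path) -> None:
    """Pickle a fitted results object (CLI checkpointing)."""
    with open(path, "wb") as fh:
        pickle.dump(results, fh)


def load_results(path) -> StrokeRecognitionResults:
    with open(path, "rb") as fh:
        return pickle.load(fh)
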