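"""The reference synthetic study: default cohort, 11 seeded training runs.

This is the package's headline end-to-end experiment: a 50,000-call cohort at
the default study conditions (helpline stroke prevalence 0.25%, call-taker
sensitivity 52.7% / PPV 17.1% by construction), five-member ensembles trained
for 11 seeds, threshold calibration on the validation split, paired
permutation comparison against the simulated call-takers on the test split,
and occlusion recovery of the planted indicator words.

Problem sizes (word unigram features, one 32-unit hidden layer, 2,000-call
smoke variant) are chosen for the synthetic scale; everything is overridable
through :class:`strokecall.pipeline.PipelineConfig`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classifier import MLPConfig
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import DEFAULT_INDICATOR_WORDS, GeneratorConfig

__all__ = ["reference_config", "smoke_config", "run_reference_study"]


def reference_config(seed: int = 0, n_calls: int = 50_000, n_runs: int = 11) -> PipelineConfig:
    """The default study conditions."""
    return PipelineConfig(
        generator=GeneratorConfig(n_calls=n_calls, seed=seed),
        mlp=MLPConfig(hidden_sizes=(32,), learning_rate=1e-3, max_epochs=20, patience=5),
        n_runs=n_runs,
        n_perm=10_000,
        n_boot=1_000,
        word_n_range=(1, 1),
        char_n_range=None,
        min_doc_freq=5,
        occlusion_max_docs=1_500,
        seed=seed,
    )


def smoke_config(seed: int = 0) -> PipelineConfig:
    """A tiny end-to-end configuration (2,000 calls, 2 runs).

    The prevalence is raised to 5% so that every (ground truth, category)
    stratum still holds at least one call per training fold at this size.
    """
    cfg = reference_config(seed=seed, n_calls=2_000, n_runs=2)
    return dataclasses.replace(
        cfg,
        generator=dataclasses.replace(cfg.generator, stroke_prevalence=0.05, n_calls=2_000, seed=seed),
        mlp=dataclasses.replace(
            cfg.mlp, learning_rate=3e-3, batch_size=128, max_epochs=40, patience=8
        ),
        n_perm=200,
        n_boot=100,
        min_doc_freq=2,
        occlusion_max_docs=200,
    )


def run_reference_study(seed: int = 0, n_calls: int = 50_000, n_runs: int = 11) -> dict:
    """Run the reference study and distil the headline quantities.

    Returns a flat dict (percentages on the 0-100 scale) with the model's and
    the simulated call-takers' test-set operating points, the paired
    permutation p-values for the sensitivity and PPV improvements, and the
    number of the ten planted indicator words recovered in the top-30
    positive occlusion ranking.
    """
    config = reference_config(seed=seed, n_calls=n_calls, n_runs=n_runs)
    bundle = run_pipeline(config, out_dir=None, make_figures=False)

    top_pos = [e["word"] for e in bundle["occlusion"]["stroke_predictions"]]
    planted = set(DEFAULT_INDICATOR_WORDS)
    recovered = sum(1 for w in top_pos[:30] if w in planted)

    m = bundle["metrics"]["model"]
    c = bundle["metrics"]["calltakers"]
    out = {
        "n_calls": n_calls,
        "n_test": bundle["n"]["test"],
        "n_test_stroke": bundle["n"]["test_stroke"],
        "n_runs": n_runs,
        "model_sensitivity_pct": 100 * m["sensitivity"],
        "model_ppv_pct": 100 * m["ppv"],
        "model_f1_pct": 100 * m["f1"],
        "calltaker_sensitivity_pct": 100 * c["sensitivity"],
        "calltaker_ppv_pct": 100 * c["ppv"],
        "calltaker_f1_pct": 100 * c["f1"],
        "p_sensitivity_model_gt_calltaker": bundle["p_values"]["sensitivity"]["p"],
        "p_ppv_model_gt_calltaker": bundle["p_values"]["ppv"]["p"],
        "indicator_words_recovered_top30": recovered,
        "median_run": bundle["median_run"],
        "_bundle": bundle,
    }
    return out
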