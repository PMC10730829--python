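import numpy as np
import pytest
from scipy import sparse

from strokecall.experiment import smoke_config
from strokecall.pipeline import run_pipeline
from strokecall.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3,000-call cohort with elevated prevalence for linkage/split tests."""
    return generate_cohort(GeneratorConfig(n_calls=3000, stroke_prevalence=0.05, seed=11))


@pytest.fixture(scope="session")
def smoke_bundle(tmp_path_factory):
    """End-to-end tiny pipeline run (2,000 calls, 2 runs), artefacts on disk."""
    out = tmp_path_factory.mktemp("smoke")
    bundle = run_pipeline(smoke_config(seed=5), out_dir=out)
    bundle["_out_dir"] = out
    return bundle


@pytest.fixture(scope="session")
def toy_folds():
    """Five small linearly-learnable fold datasets plus an extra-train set.

    Ten of 40 features are informative; positives carry a few of them.
    """
    rng = np.random.default_rng(42)
    n_per, n_feat = 150, 40

    def make(n):
        y = rng.random(n) < 0.3
        X = rng.poisson(0.3, size=(n, n_feat)).astype(float)
        X[:, :10] += y[:, None] * rng.poisson(1.5, size=(n, 10))
        return sparse.csr_matrix(X), y

    folds = [make(n_per) for _ in range(5)]
    extra = make(100)
    val = make(300)
    return folds, extra, val
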