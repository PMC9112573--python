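import numpy as np
import pytest

from metastack import GeneratorConfig, MLPHyper, simulate_cohort

TINY_MLP = MLPHyper(width=8)
SMALL_MLP = MLPHyper(width=16)


@pytest.fixture(scope="session")
def small_cohort():
    """Fully observed continuous outcome, default missingness, n=1500."""
    cfg = GeneratorConfig(n=1500, seed=42, cont_subset_fraction=1.0)
    masked, truth, complete = simulate_cohort(cfg)
    return masked, truth, complete, cfg


@pytest.fixture(scope="session")
def complete_cohort():
    """No predictor missingness at all: imputation is a no-op."""
    cfg = GeneratorConfig(n=1200, seed=7, cont_subset_fraction=1.0, missing_rates={})
    masked, truth, complete = simulate_cohort(cfg)
    return masked, truth, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
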