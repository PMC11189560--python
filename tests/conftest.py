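import numpy as np
import pytest

from adaptscan.synthetic_experiment import (
    ExperimentConfig,
    TraitModel,
    run_experiment,
    standard_architecture,
    strong_selection_architecture,
)


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig(rng_seed=3)


@pytest.fixture(scope="session")
def experiment_result(default_config):
    """One full replicated experiment under strong selection (shared, read-only)."""
    arch = strong_selection_architecture()
    return run_experiment(default_config, arch, TraitModel(gxe_effect=0.5))


@pytest.fixture(scope="session")
def small_architecture():
    return standard_architecture(n_ap=4, n_cn_per_soil=3, n_neutral=20)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
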