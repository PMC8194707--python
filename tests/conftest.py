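import numpy as np
import pytest

from tugsae import ExperimentConfig, GeneratorConfig, SAEHyperparams, TrainConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_generator_config():
    """Small cohort config used where full size is not the point."""
    return GeneratorConfig(n_per_class=4, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_generator_config):
    return generate_cohort(tiny_generator_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (22 + 22 subjects)."""
    return generate_cohort(GeneratorConfig(seed=3))


@pytest.fixture
def fast_train_config():
    """Lean deterministic training budget for unit tests."""
    return TrainConfig(max_iterations=20, supervised_iterations=40, optimizer="CG", seed=5)


@pytest.fixture
def small_hyper():
    return SAEHyperparams(n1=16, n2=6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
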