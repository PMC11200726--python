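import numpy as np
import pytest

from barilearn import GeneratorConfig, generate, split_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale synthetic cohort: 118 patients, 60 variables."""
    cohort, truth = generate(GeneratorConfig(seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 40-patient, 12-variable cohort for pipeline-level tests."""
    config = GeneratorConfig(
        n=40, V=12, informative=(2, 3, 4), effect_sizes=(3.0, 3.0, 3.0), seed=11
    )
    cohort, truth = generate(config)
    return cohort, truth


@pytest.fixture(scope="session")
def default_split(default_cohort):
    cohort, _ = default_cohort
    return split_cohort(cohort, fraction=0.7, seed=5)
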