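import numpy as np
import pytest

from flexchart.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-patient synthetic cohort shared by fast tests."""
    return generate_cohort(GeneratorConfig(n_patients=80, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """A full-scale synthetic cohort (≈500 patients, ≈1600 observations)."""
    return generate_cohort(GeneratorConfig(n_patients=500, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
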