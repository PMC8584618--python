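import numpy as np
import pytest

from olfrisk.synth import GeneratorConfig, generate_cohort

PRINTED_MEANS = (24.9, 34.32)
PRINTED_SDS = (3.42, 3.2)
PRINTED_WEIGHTS = (0.167, 0.83)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Default structure, without injected missingness/outliers."""
    return generate_cohort(GeneratorConfig(seed=42, n_missing=0, n_outliers=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
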