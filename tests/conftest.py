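import numpy as np
import pytest

from ssepml.features import assemble_feature_table
from ssepml.synth import GeneratorConfig, generate_cohort, generate_patient


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Desk-scale generator config used across the suite."""
    return GeneratorConfig(
        n_patients=4, trials_per_nerve=8, sample_rate=2000.0, seed=7
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_patient(small_cfg, 0)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return assemble_feature_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
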