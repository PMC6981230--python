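import numpy as np
import pytest

from icurisk.synthetic import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small calibrated cohort shared by fast tests."""
    cohort, truth = simulate_cohort(GeneratorConfig(n_patients=300, seed=7),
                                    calibration_mc=1000)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
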