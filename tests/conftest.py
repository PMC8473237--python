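import numpy as np
import pytest

from megcoh import SynthParams, generate_cohort


@pytest.fixture(scope="session")
def small_params():
    """A cheap cohort: 3 subjects/class, 20 s at 200 Hz."""
    return SynthParams(n_subjects_per_class=3, duration=20.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def cohort30():
    """Study-condition cohort at the reduced 30 s/subject duration, seed 0."""
    return generate_cohort(SynthParams(duration=30.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
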