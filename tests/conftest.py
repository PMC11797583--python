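import numpy as np
import pytest

from cubdrisc import CohortConfig, generate_cohort
from cubdrisc.scales import ScaleName, build_scale, score_frame


@pytest.fixture(scope="session")
def scales():
    return {name.value: build_scale(name) for name in ScaleName}


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by evaluation tests."""
    return generate_cohort(CohortConfig(n=3000, seed=3))


@pytest.fixture(scope="session")
def small_cohort_scores(small_cohort, scales):
    frame = small_cohort.frame
    return {
        name: score_frame(frame, scale).to_numpy() for name, scale in scales.items()
    }


@pytest.fixture(scope="session")
def small_cohort_labels(small_cohort):
    return (small_cohort.frame["latent_state"] != "normal").to_numpy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
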