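import numpy as np
import pytest

import morphopath as mp


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_study():
    """Shared medium-size synthetic study (both sexes, low rater load)."""
    truth = mp.preset_truth("czech_women", seed=11)
    return mp.simulate_study(truth, 40)


@pytest.fixture(scope="session")
def small_aligned(small_study):
    return mp.gpa(small_study.configs, scheme=small_study.scheme, slide=True)
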