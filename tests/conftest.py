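import numpy as np
import pytest

import myogait as mg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A compact walking study: 3 subjects x 2 trials x 12 strides."""
    return mg.generate_study(
        n_subjects=3, trials_per_subject=2, strides_per_trial=12, seed=7
    )


@pytest.fixture(scope="session")
def small_samples(small_study):
    return mg.build_samples(small_study.trials, small_study.muscles)
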