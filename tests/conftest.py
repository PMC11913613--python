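import numpy as np
import pytest

import fsrml


@pytest.fixture(scope="session")
def small_class_cohort():
    """Class-conditional cohort, small enough for fast model fits."""
    spec = fsrml.default_spec().with_(n=400, seed=1)
    return fsrml.generate(spec)


@pytest.fixture(scope="session")
def small_logistic_cohort():
    """Logistic-link cohort with recorded ground-truth coefficients."""
    spec = fsrml.default_spec().with_(n=600, seed=2)
    return fsrml.generate_logistic(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
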