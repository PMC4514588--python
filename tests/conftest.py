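import numpy as np
import pytest

from soilcoda import reference, synth


@pytest.fixture(scope="session")
def ref_T():
    """Published pairwise log-ratio variance matrix (5x5)."""
    return reference.reference_variation()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_table(rng):
    """A generic strictly positive (50, 5) closed table for identity checks."""
    X = rng.lognormal(mean=0.0, sigma=1.0, size=(50, 5))
    return X / X.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def survey39_ds():
    """Default synthetic survey: 39 profiles, 25% minority cluster."""
    return synth.make_fixture("survey39", seed=11)
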