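import warnings

import numpy as np
import pytest

import espd


@pytest.fixture(scope="session")
def spec():
    return espd.study_spec()


@pytest.fixture(scope="session")
def truth():
    return espd.true_coefficients()


@pytest.fixture(scope="session")
def population(spec):
    """Mid-sized reference population shared across tests (uncensored)."""
    return espd.generate_population(n_sim=200_000, rng=101)


@pytest.fixture(scope="session")
def small_sample(population):
    rng = np.random.default_rng(7)
    idx = rng.choice(population.n, 2000, replace=False)
    return population.subset(idx)


@pytest.fixture()
def quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
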