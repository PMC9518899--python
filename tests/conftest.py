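import numpy as np
import pytest

import growthfeedback as g


@pytest.fixture(scope="session")
def fixtures():
    return g.reference_fixtures()


@pytest.fixture(scope="session")
def constitutive(fixtures):
    return fixtures["constitutive"]


@pytest.fixture(scope="session")
def self_activation(fixtures):
    return fixtures["self_activation"]


@pytest.fixture(scope="session")
def toggle(fixtures):
    return fixtures["toggle_tristable"]


@pytest.fixture(scope="session")
def toggle_quad(fixtures):
    return fixtures["toggle_quadstable"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220916)
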