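import numpy as np
import pytest

from osteoimpact import DamageCard, cortical_card, trabecular_card


@pytest.fixture(scope="session")
def cortical():
    return cortical_card()


@pytest.fixture(scope="session")
def trabecular():
    return trabecular_card()


@pytest.fixture(scope="session")
def damage_card():
    return DamageCard()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
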