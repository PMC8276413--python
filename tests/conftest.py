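import matplotlib
matplotlib.use("Agg")

import numpy as np
import pytest

from cogreserve import synthetic as syn


@pytest.fixture(scope="session")
def tilda_config():
    return syn.default_config("tilda", seed=20210712 % 2**31)


@pytest.fixture(scope="session")
def crrann_config():
    return syn.default_config("crrann", seed=(20210712 + 1) % 2**31)


@pytest.fixture(scope="session")
def tilda_cohort(tilda_config):
    return syn.generate_cohort(tilda_config)


@pytest.fixture(scope="session")
def crrann_cohort(crrann_config):
    return syn.generate_cohort(crrann_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2021)
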