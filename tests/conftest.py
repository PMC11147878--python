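import numpy as np
import pytest
from hypothesis import settings

from replocal.grid import average_presentations
from replocal.synthetic import make_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small planted-region dataset shared across tests (4 subjects, 12^3)."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_word_betas(tiny_bundle):
    rep = dict(zip(tiny_bundle.pres_table["stimulus_id"],
                   tiny_bundle.pres_table["word_id"]))
    return [average_presentations(b, rep) for b in tiny_bundle.betasets]


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
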