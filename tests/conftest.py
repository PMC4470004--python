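import logging

import pytest

from fluxnetmir.mirao import extend_model
from fluxnetmir.synthetic import MIRAO_K, FixtureSpec, gen_mir_tables, gen_toy_model


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings(caplog):
    """Keep expected engine warnings out of test noise; tests assert on them explicitly."""
    logging.getLogger("fluxnetmir.engine").setLevel(logging.ERROR)
    yield


@pytest.fixture
def toy_spec():
    return FixtureSpec(seed=1, n_genes=5, n_mirnas=2)


@pytest.fixture
def toy_model(toy_spec):
    model, _tally = gen_toy_model(toy_spec)
    return model


@pytest.fixture
def extended_model(toy_spec, toy_model):
    mirt, tfmir = gen_mir_tables(toy_spec)
    return extend_model(toy_model, mirt, tfmir, k=MIRAO_K)
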