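import numpy as np
import pytest

from selinhib import CircuitParams, derive_couplings
from selinhib.rnn import RNNParams, train

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def params():
    """Reference circuit: gamma_EE=0.32, gamma_EI=0.25, gamma_IE=0, nu0_I=11.5."""
    return CircuitParams()


@pytest.fixture(scope="session")
def couplings(params):
    return derive_couplings(params)


@pytest.fixture(scope="session")
def trained_networks():
    """Three full-size networks trained to the stopping criterion.

    Shared across the RNN analysis and acceptance tests; training three
    networks takes about a minute.
    """
    nets = [train(RNNParams(), seed=s) for s in (11, 12, 13)]
    assert all(t.reached_criterion for t in nets)
    return nets
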