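import numpy as np
import pytest

from evsnn.neuron import NeuronParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def leaky_params():
    """A leaky signed parameter block at realistic magnitudes."""
    return NeuronParams(th_plus=1_000_000, th_minus=-1_000_000,
                        tl_plus=500, tl_minus=500, emit_negative=True)
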