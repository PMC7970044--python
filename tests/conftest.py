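import numpy as np
import pytest

from clusterrl import NeuronParams, Population
from clusterrl.topology import Circuit


@pytest.fixture
def single_lif():
    """One isolated LIF neuron with an infinite threshold (pure integrator)."""

    def make(seed=0, **params):
        params.setdefault("V_th", 1e9)
        c = Circuit()
        c.add_population(Population("n", 1, "lif", params=NeuronParams(**params)))
        return c.compile(dt=0.1, seed=seed)

    return make


@pytest.fixture
def poisson_pop():
    """A population of independent Poisson sources at a fixed rate."""

    def make(n, rate, seed=0, dt=0.1):
        c = Circuit()
        c.add_population(Population("src", n, "poisson", rate_base=rate))
        return c.compile(dt=dt, seed=seed)

    return make
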