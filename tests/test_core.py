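"""Closed-form checks of the LIF integrator, synapse model and Poisson sources."""

import numpy as np
import pytest

from clusterrl import (
    ConfigurationError,
    NeuronParams,
    Population,
    sample_poisson_spikes,
)
from clusterrl.analysis import cv_isi
from clusterrl.topology import Circuit


def test_leak_only_matches_exponential(single_lif):
    net = single_lif(tau_m=20.0)
    net.V[0] = 10.0
    net.run(20.0)
    expected = 10.0 * np.exp(-1.0)
    assert abs(net.V[0] - expected) / expected < 1e-10


def test_constant_current_steady_state(single_lif):
    net = single_lif(tau_m=20.0, C=250.0, I_bias=100.0)
    net.run(2000.0)
    assert net.V[0] == pytest.approx(100.0 * 20.0 / 250.0, rel=1e-9)


def test_psc_impulse_response(single_lif):
    net = single_lif(tau_s=5.0)
    net.I_syn[0] = 7.0
    net.run(10.0)
    assert net.I_syn[0] == pytest.approx(7.0 * np.exp(-2.0), rel=1e-10)


def test_psc_superposition():
    """Response to two input spikes equals the sum of single-spike responses."""

    def response(i_init):
        c = Circuit()
        c.add_population(
            Population("n", 1, "lif", params=NeuronParams(V_th=1e9, tau_s=5.0))
        )
        net = c.compile(dt=0.1, seed=0)
        net.I_syn[0] = i_init
        traj = []
        for _ in range(50):
            net.run(1.0)
            traj.append(net.I_syn[0])
        return np.array(traj)

    np.testing.assert_allclose(response(3.0) + response(4.0), response(7.0), rtol=1e-12)


def test_threshold_reset_and_refractory():
    c = Circuit()
    c.add_population(
        Population(
            "n", 1, "lif",
            params=NeuronParams(tau_m=20.0, C=250.0, V_th=20.0, t_ref=2.0,
                                I_bias=400.0),
        )
    )
    net = c.compile(dt=0.1, seed=0)
    res = net.run(1000.0)
    t = res.spikes.time_ms
    assert len(t) > 3
    # no inter-spike interval shorter than the refractory period
    assert np.all(np.diff(t) >= 2.0 - 1e-9)
    # after each spike the membrane resets
    assert net.V[0] < 20.0


def test_poisson_empirical_rate(poisson_pop):
    """Bernoulli thinning reproduces the requested rate (binomial oracle)."""
    net = poisson_pop(100, 1000.0, seed=3)
    res = net.run(10_000.0)
    n_steps = 100_000
    p = 1000.0 * 0.1e-3
    se = np.sqrt(n_steps * 100 * p * (1 - p))
    assert abs(len(res.spikes) - n_steps * 100 * p) < 4 * se


def test_poisson_isi_cv_near_one(poisson_pop):
    net = poisson_pop(20, 10.0, seed=5)
    res = net.run(100_000.0)
    cv, excluded = cv_isi(res.spikes, np.arange(20))
    assert excluded == 0
    assert cv == pytest.approx(1.0, abs=0.05)


def test_sample_poisson_spikes_contract():
    rng = np.random.default_rng(0)
    assert not sample_poisson_spikes(np.zeros(5), 0.1, rng).any()
    with pytest.raises(ValueError):
        sample_poisson_spikes([-1.0], 0.1, rng)
    with pytest.warns(UserWarning):
        sample_poisson_spikes([5000.0], 0.1, rng)
    draws = np.array(
        [sample_poisson_spikes([1000.0] * 100, 0.1, rng) for _ in range(1000)]
    )
    assert draws.mean() == pytest.approx(0.1, abs=0.01)


def test_zero_duration_is_a_noop(poisson_pop):
    net = poisson_pop(5, 100.0)
    v0 = net.V.copy()
    res = net.run(0.0)
    assert len(res.spikes) == 0
    np.testing.assert_array_equal(net.V, v0)


def test_same_seed_bitwise_identical(poisson_pop):
    a = poisson_pop(50, 200.0, seed=11).run(5000.0)
    b = poisson_pop(50, 200.0, seed=11).run(5000.0)
    np.testing.assert_array_equal(a.spikes.unit, b.spikes.unit)
    np.testing.assert_array_equal(a.spikes.time_ms, b.spikes.time_ms)


def test_disconnected_neurons_superpose():
    """Two disconnected neurons each follow their single-neuron closed form."""
    c = Circuit()
    c.add_population(
        Population("a", 1, "lif", params=NeuronParams(tau_m=20.0, V_th=1e9))
    )
    c.add_population(
        Population("b", 1, "lif", params=NeuronParams(tau_m=10.0, V_th=1e9))
    )
    net = c.compile(dt=0.1, seed=0)
    net.V[:] = [10.0, 6.0]
    net.run(10.0)
    assert net.V[0] == pytest.approx(10.0 * np.exp(-0.5), rel=1e-9)
    assert net.V[1] == pytest.approx(6.0 * np.exp(-1.0), rel=1e-9)


def test_configuration_errors():
    with pytest.raises(ConfigurationError):
        NeuronParams(tau_m=-1.0)
    with pytest.raises(ConfigurationError):
        NeuronParams(V_th=0.0, V_reset=0.0)
    c = Circuit()
    c.add_population(Population("a", 2, "poisson"))
    # delays must sit on the dt grid
    c.add_projection("p", "a", "a", [0], [1], 1.0, delay_ms=0.55)
    with pytest.raises(ConfigurationError):
        c.compile(dt=0.1)
    # durations must be dt multiples
    c2 = Circuit()
    c2.add_population(Population("a", 1, "poisson"))
    net = c2.compile(dt=0.1)
    with pytest.raises(ConfigurationError):
        net.run(10.05)
    # dt too coarse for the membrane constants
    c3 = Circuit()
    c3.add_population(Population("n", 1, "lif", params=NeuronParams(tau_s=1.0)))
    with pytest.raises(ConfigurationError):
        c3.compile(dt=0.5)
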