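"""Actor-critic machinery: spiking critic, reward-prediction-error circuit,
and the dopamine signal.

The TD error of a discrete transition is ``delta = r' + gamma V(S') - V(S)``.
Its continuous-time analogue, realized here as a dopamine concentration, is

    D(t) = dv/dt + r(t) - v(t) / tau_r

where v is the (smoothed) rate of the critic population, r the reward rate
and tau_r the discounting time constant.  The spiking circuit implements the
derivative with a dual connection from each critic neuron to each neuron of
the RPE population: one excitatory connection with a 1 ms delay and one
inhibitory connection with a 20 ms delay.  To first order in the delays the
summed synaptic current of an RPE neuron is then

    I(t) ~ alpha * [ (w_p - w_m) v(t) + (w_m d2 - w_p d1) dv/dt ]

with alpha the stationary current per unit rate and weight.  Solving for the
two weights makes the RPE population rate equal r0 + g_D * (dv/dt + r - v/tau_r)
exactly in the stationary limit; rewards enter as an additive rate offset.
The dopamine concentration is decoded from the RPE population as its
unit-area exponentially filtered mean rate, and its baseline b_D is a moving
average over the trailing 10 s, so that D - b_D is invariant to constant
offsets in the value encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, Network, Population
from .plasticity import TetzlaffParams
from .topology import Circuit

__all__ = [
    "CriticCircuit",
    "RewardSchedule",
    "td_error_oracle",
    "rpe_concentration",
    "build_critic_circuit",
    "immediate_reward_signal",
    "set_reward_rate",
    "simulate_dopamine_schedule",
]


@dataclass(frozen=True)
class CriticCircuit:
    """Layout and calibration of the critic/RPE circuit.

    n_critic Poisson neurons encode the value as a population rate
    (``critic_base + critic_gain * I_syn``); n_rpe Poisson neurons encode
    the reward prediction error around a working point of r0 spikes/s with
    g_D spikes/s per unit of D.  delay_exc/delay_inh are the dual-connection
    delays (ms); tau_r is the discounting time constant (s).
    """

    n_critic: int = 20
    n_rpe: int = 1000
    delay_exc: float = 1.0
    delay_inh: float = 20.0
    tau_r: float = 1.0
    critic_base: float = 20.0
    critic_gain: float = 1.0
    rpe_base: float = 1000.0
    d_gain: float = 1.0
    tau_s: float = 5.0
    tau_v: float = 100.0

    def __post_init__(self) -> None:
        if self.delay_inh <= self.delay_exc:
            raise ConfigurationError("delay_inh must exceed delay_exc")
        if self.tau_r <= 0:
            raise ConfigurationError("tau_r must be positive")

    def dual_weights(self, dt: float) -> tuple[float, float]:
        """(excitatory, inhibitory-magnitude) critic->RPE weights.

        Calibrated so the RPE drive equals g_D * (dv/dt - v/tau_r) for the
        critic population-mean rate v in spikes/s, smoothed with tau_v (the
        RPE synaptic time constant; long enough that single critic spikes
        do not rectify the RPE rate at zero).  Uses the discrete-time
        stationary current per spike, tau_eff = dt / (1 - exp(-dt/tau_v)),
        rather than tau_v, to cancel the integration-grid bias.
        """
        tau_eff = dt / (1.0 - np.exp(-dt / self.tau_v))
        alpha = self.n_critic * tau_eff * 1e-3  # stationary I per Hz per unit weight
        A = 1000.0 * self.d_gain / alpha  # coefficient for dv/dt (per ms)
        B = -self.d_gain / (self.tau_r * alpha)  # coefficient for v
        w_m = (A + B * self.delay_exc) / (self.delay_inh - self.delay_exc)
        w_p = w_m + B
        if w_p <= 0 or w_m <= 0:
            raise ConfigurationError("infeasible dual-connection calibration")
        return float(w_p), float(w_m)


@dataclass(frozen=True)
class RewardSchedule:
    """A piece of the dopamine-neuron rate schedule."""

    rate: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ConfigurationError("duration must be positive")


def td_error_oracle(r_next: float, V_t: float, V_next: float, gamma: float) -> float:
    """Discrete temporal-difference error ``r' + gamma V(S') - V(S)``."""
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    return r_next + gamma * V_next - V_t


def rpe_concentration(v, r, tau_r: float, dt_ms: float = 1.0) -> np.ndarray:
    """Continuous reference form ``D = dv/dt + r - v/tau_r``.

    v (spikes/s) and r are sampled every dt_ms; tau_r is in seconds; the
    derivative is in spikes/s per second (central differences).
    """
    v = np.asarray(v, float)
    r = np.broadcast_to(np.asarray(r, float), v.shape)
    if np.any(v < 0):
        raise ValueError("critic rate must be non-negative")
    if tau_r <= 0:
        raise ValueError("tau_r must be positive")
    dvdt = np.gradient(v, dt_ms * 1e-3) if v.size > 1 else np.zeros_like(v)
    return dvdt + r - v / tau_r


def build_critic_circuit(
    circuit: Circuit,
    spec: CriticCircuit,
    exc_pop: str,
    rng: np.random.Generator,
    rule_params: TetzlaffParams | None = None,
    dt: float = 0.1,
    plastic: bool = True,
    w_init_low: float = 0.0,
    w_init_high: float = 0.1,
    critic_name: str = "critic",
    rpe_name: str = "rpe",
) -> tuple[Population, Population]:
    """Add the critic and RPE populations and their wiring to a circuit.

    The representation->critic projection carries the value estimate and is
    plastic under the three-factor rule; each critic neuron connects to every
    RPE neuron twice (excitatory at delay_exc, inhibitory at delay_inh) with
    the calibrated weights.  Compile the circuit with
    ``dopamine_pop=rpe_units, d_gain=1/g_D, d_offset=-r0/g_D`` to decode D.
    """
    critic = circuit.add_population(
        Population(
            critic_name,
            spec.n_critic,
            "poisson",
            rate_base=spec.critic_base,
            rate_gain=spec.critic_gain,
            tau_s=spec.tau_s,
        )
    )
    rpe = circuit.add_population(
        Population(
            rpe_name,
            spec.n_rpe,
            "poisson",
            rate_base=spec.rpe_base,
            rate_gain=1.0,
            tau_s=spec.tau_v,
        )
    )
    if exc_pop is not None:
        n_e = circuit.populations[exc_pop].n
        pre, post = np.meshgrid(
            np.arange(n_e), np.arange(spec.n_critic), indexing="ij"
        )
        w = rng.uniform(w_init_low, w_init_high, size=pre.size)
        circuit.add_projection(
            "critic_proj",
            exc_pop,
            critic_name,
            pre.ravel(),
            post.ravel(),
            w,
            plastic="three_factor" if plastic else None,
            rule_params=rule_params if plastic else None,
        )
    w_p, w_m = spec.dual_weights(dt)
    pre, post = np.meshgrid(
        np.arange(spec.n_critic), np.arange(spec.n_rpe), indexing="ij"
    )
    circuit.add_projection(
        "rpe_exc", critic_name, rpe_name, pre.ravel(), post.ravel(), w_p,
        delay_ms=spec.delay_exc,
    )
    circuit.add_projection(
        "rpe_inh", critic_name, rpe_name, pre.ravel(), post.ravel(), -w_m,
        delay_ms=spec.delay_inh,
    )
    return critic, rpe


def dopamine_decode_args(spec: CriticCircuit) -> dict:
    """Network compile kwargs decoding D from the RPE population's mean F."""
    return {
        "d_gain": 1.0 / spec.d_gain,
        "d_offset": -spec.rpe_base / spec.d_gain,
    }


def set_reward_rate(net: Network, spec: CriticCircuit, r: float, rpe_name: str = "rpe") -> None:
    """Inject the environmental reward as an additive RPE rate offset.

    r is in D units (value per second); the offset is clipped so the base
    rate never goes negative.
    """
    rate = max(spec.rpe_base + spec.d_gain * r, 0.0)
    net.set_rates(rpe_name, rate)


def simulate_dopamine_schedule(
    spec: CriticCircuit,
    schedule: list[tuple[float, float, float]],
    dt: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Drive the critic/RPE circuit with a piecewise-constant schedule.

    ``schedule`` is a list of (duration_ms, critic_rate, reward) segments,
    with reward in D units (value per second).  The critic population is
    driven directly (no representation layer), the reward enters as an RPE
    rate offset, and the decoded dopamine concentration is returned as an
    array with columns (time_ms, D, b_D) sampled every millisecond.  This
    is the standard probe for checking the spiking circuit against the
    closed-form concentration.
    """
    circuit = Circuit()
    _, rpe = build_critic_circuit(
        circuit, spec, exc_pop=None, rng=np.random.default_rng(seed), dt=dt
    )
    net = circuit.compile(
        dt=dt,
        seed=seed,
        dopamine_pop=np.arange(rpe.start, rpe.stop),
        **dopamine_decode_args(spec),
    )
    net.set_record_spikes("rpe", False)
    logs = []
    for duration_ms, v, r in schedule:
        net.set_rates("critic", v)
        set_reward_rate(net, spec, r)
        res = net.run(duration_ms, record_dopamine=True, record_spikes=False)
        logs.append(res.dopamine)
    return np.concatenate(logs)


def immediate_reward_signal(outcome: str, base_rate: float) -> RewardSchedule:
    """Dopamine-neuron rate schedule for classification feedback.

    The dopamine neuron doubles its base firing rate for 100 ms when the
    predicted label is correct and falls silent for 100 ms when it is
    incorrect; outside feedback periods it fires at base_rate.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if outcome == "correct":
        return RewardSchedule(2.0 * base_rate, 100.0)
    if outcome == "incorrect":
        return RewardSchedule(0.0, 100.0)
    raise ValueError(f"unknown outcome {outcome!r}")
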