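"""Clock-driven simulation of LIF neurons with exponential post-synaptic currents.

Membrane dynamics follow ``dV/dt = -V/tau_m + I/C`` with the total current
composed of exponentially relaxing synaptic currents (each presynaptic spike
increments the current by the synaptic weight, which then decays with tau_s),
a constant bias, and threshold/reset/refractory mechanics.  Integration uses
the exact exponential-Euler update, which reproduces the closed-form leak
trajectory to machine precision and is unconditionally stable.

Rate-modulated Poisson units share the same synaptic-current machinery but
spike stochastically with instantaneous rate ``rate_base + rate_gain * I_syn``
instead of integrating a membrane potential.  All units carry an exponential
rate trace F (unit-area kernel, so F estimates the firing rate in spikes/s),
which is the substrate of the rate-based plasticity rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "NeuronParams",
    "Population",
    "SpikeRecord",
    "TraceRecord",
    "Network",
    "sample_poisson_spikes",
    "advance_network",
    "run_simulation",
]

DEFAULT_DT = 0.1  # ms


class ConfigurationError(ValueError):
    """Raised for structurally invalid network or recorder configuration."""


class SimulationError(RuntimeError):
    """Raised when the numerical state becomes invalid (e.g. NaN currents)."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane and synapse constants of one LIF population.

    tau_m : membrane time constant (ms)
    C : membrane capacitance (pF); with currents in pA, V = I * tau_m / C is in mV
    V_th : spike threshold (mV); V_reset : post-spike reset (mV)
    t_ref : absolute refractory period (ms) during which V is clamped
    I_bias : constant bias current (pA), identical within a population
    tau_s : relaxation time of the exponential post-synaptic current (ms)
    """

    tau_m: float = 20.0
    C: float = 250.0
    V_th: float = 20.0
    V_reset: float = 0.0
    t_ref: float = 2.0
    I_bias: float = 0.0
    tau_s: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_s <= 0:
            raise ConfigurationError("tau_m and tau_s must be positive")
        if self.t_ref < 0:
            raise ConfigurationError("t_ref must be non-negative")
        if self.V_th <= self.V_reset:
            raise ConfigurationError("V_th must exceed V_reset")


@dataclass
class Population:
    """A named homogeneous group of units.

    kind 'lif' uses ``params``; kind 'poisson' units fire at
    ``rate_base + rate_gain * I_syn`` spikes/s (clipped at zero), with
    I_syn relaxing with time constant tau_s as for LIF synapses.
    """

    name: str
    n: int
    kind: str = "lif"
    params: NeuronParams = field(default_factory=NeuronParams)
    rate_base: float = 0.0
    rate_gain: float = 0.0
    tau_s: float = 5.0
    start: int = -1  # global index of first unit, assigned at compile time

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"population {self.name!r} must have >= 1 unit")
        if self.kind not in ("lif", "poisson"):
            raise ConfigurationError(f"unknown population kind {self.kind!r}")

    @property
    def stop(self) -> int:
        return self.start + self.n

    def globalize(self, local_ids) -> np.ndarray:
        return np.asarray(local_ids, dtype=np.int64) + self.start


@dataclass
class SpikeRecord:
    """Time-stamped spike events, ordered by time.

    ``unit`` holds global unit indices; ``time_ms`` the spike times on the
    simulation grid.  The record is the substrate of all spike-train
    statistics (rates, CV of ISIs, decisions, reconstructions).
    """

    unit: np.ndarray
    time_ms: np.ndarray

    def __post_init__(self) -> None:
        self.unit = np.asarray(self.unit, dtype=np.int64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if self.unit.shape != self.time_ms.shape:
            raise ValueError("unit and time_ms must have equal length")
        if self.time_ms.size and np.any(np.diff(self.time_ms) < 0):
            raise ValueError("spike times must be non-decreasing")

    def __len__(self) -> int:
        return self.unit.size

    def for_population(self, pop: Population) -> "SpikeRecord":
        """Restrict to one population, re-indexing units to local ids."""
        m = (self.unit >= pop.start) & (self.unit < pop.stop)
        return SpikeRecord(self.unit[m] - pop.start, self.time_ms[m])

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        m = (self.time_ms >= t0) & (self.time_ms < t1)
        return SpikeRecord(self.unit[m], self.time_ms[m])

    def spike_times(self, unit: int) -> np.ndarray:
        return self.time_ms[self.unit == unit]

    def counts(self, n_units: int) -> np.ndarray:
        return np.bincount(self.unit, minlength=n_units)

    def mean_rate(self, n_units: int, duration_ms: float) -> float:
        """Population-mean firing rate in spikes/s."""
        if duration_ms <= 0:
            raise ValueError("duration must be positive")
        return float(len(self) / n_units / (duration_ms * 1e-3))

    @staticmethod
    def concatenate(records: list["SpikeRecord"]) -> "SpikeRecord":
        if not records:
            return SpikeRecord(np.empty(0, np.int64), np.empty(0))
        return SpikeRecord(
            np.concatenate([r.unit for r in records]),
            np.concatenate([r.time_ms for r in records]),
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"neuron_id": self.unit, "time_ms": self.time_ms}).to_csv(
            path, index=False
        )

    @staticmethod
    def from_csv(path) -> "SpikeRecord":
        import pandas as pd

        df = pd.read_csv(path)
        return SpikeRecord(df["neuron_id"].to_numpy(), df["time_ms"].to_numpy())


@dataclass
class TraceRecord:
    """Filtered-rate snapshots: ``values[i, j]`` is F of ``units[j]`` at ``times[i]``."""

    times: np.ndarray
    units: np.ndarray
    values: np.ndarray


@dataclass
class RunResult:
    spikes: SpikeRecord
    t0: float
    t1: float
    traces: TraceRecord | None = None
    dopamine: np.ndarray | None = None  # columns: time_ms, D, b_D


@dataclass
class _PlasticGroup:
    name: str
    edge_idx: np.ndarray
    rule: int
    mu: float
    kappa: float
    F_T: float
    w_min: float
    w_max: float


def sample_poisson_spikes(rates, dt: float, rng: np.random.Generator) -> np.ndarray:
    """One Bernoulli-thinning step of inhomogeneous Poisson sources.

    rates are in spikes/s, dt in ms; each unit fires with probability
    rate * dt (dt converted to seconds), independently across units and steps.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("Poisson rates must be non-negative")
    p = rates * dt * 1e-3
    if np.any(p > 0.1):
        warnings.warn(
            "per-step spike probability exceeds 0.1; Bernoulli thinning is a "
            "poor Poisson approximation at this rate*dt",
            stacklevel=2,
        )
    return rng.random(rates.shape) < p


class Network:
    """A compiled circuit: populations, connectivity, plasticity, recorders.

    Construction is done through :class:`clusterrl.topology.Circuit`; the
    network then advances in chunks via :meth:`run`.  The simulation is a
    pure function of (configuration, seed): identical runs give bit-identical
    spike records.
    """

    def __init__(
        self,
        populations: list[Population],
        edges: dict,
        plastic_groups: list[_PlasticGroup],
        dt: float = DEFAULT_DT,
        tau_F: float = 100.0,
        plast_interval_ms: float = 1.0,
        dopamine_pop: np.ndarray | None = None,
        d_gain: float = 1.0,
        d_offset: float = 0.0,
        d_baseline_window_ms: float = 10_000.0,
        d_init: float = 0.0,
        seed: int = 0,
    ) -> None:
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        self.dt = float(dt)
        self.tau_F = float(tau_F)
        self.populations = {p.name: p for p in populations}
        self.n_units = sum(p.n for p in populations)

        # per-unit model arrays
        n = self.n_units
        self.kind = np.zeros(n, np.uint8)
        tau_m = np.full(n, 20.0)
        C = np.full(n, 250.0)
        self.v_th = np.full(n, np.inf)
        self.v_reset = np.zeros(n)
        t_ref = np.zeros(n)
        self.i_bias = np.zeros(n)
        tau_s = np.full(n, 5.0)
        self.rate_base = np.zeros(n)
        self.rate_gain = np.zeros(n)
        for p in populations:
            sl = slice(p.start, p.stop)
            if p.kind == "lif":
                q = p.params
                if self.dt > min(q.tau_m, q.tau_s) / 5 + 1e-12:
                    raise ConfigurationError(
                        f"dt={self.dt} too coarse for population {p.name!r} "
                        f"(need dt <= min(tau_m, tau_s)/5)"
                    )
                tau_m[sl] = q.tau_m
                C[sl] = q.C
                self.v_th[sl] = q.V_th
                self.v_reset[sl] = q.V_reset
                t_ref[sl] = q.t_ref
                self.i_bias[sl] = q.I_bias
                tau_s[sl] = q.tau_s
            else:
                self.kind[sl] = _kernel.KIND_POISSON
                self.rate_base[sl] = p.rate_base
                self.rate_gain[sl] = p.rate_gain
                tau_s[sl] = p.tau_s
        self.e_m = np.exp(-self.dt / tau_m)
        self.dv_gain = (tau_m / C) * (1.0 - self.e_m)
        self.e_s = np.exp(-self.dt / tau_s)
        self.ref_steps = np.round(t_ref / self.dt).astype(np.int64)
        self.tau_s = tau_s

        # connectivity: CSR by presynaptic unit
        pre = np.asarray(edges["pre"], np.int64)
        post = np.asarray(edges["post"], np.int64)
        w = np.asarray(edges["weight"], np.float64)
        delay_ms = np.asarray(edges["delay_ms"], np.float64)
        d_steps = np.round(delay_ms / self.dt).astype(np.int64)
        if np.any(np.abs(d_steps * self.dt - delay_ms) > 1e-9):
            raise ConfigurationError("all delays must be multiples of dt")
        if np.any(d_steps < 1):
            raise ConfigurationError("delays must be at least one time step")
        order = np.argsort(pre, kind="stable")
        self._edge_order = order  # original edge id -> position via argsort inverse
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        self._edge_pos = inv  # position of original edge i in CSR arrays
        self.edge_pre = pre[order]
        self.edge_post = post[order]
        self.edge_weight = w[order].copy()
        self.edge_delay = d_steps[order]
        self.indptr = np.zeros(n + 1, np.int64)
        np.add.at(self.indptr, self.edge_pre + 1, 1)
        self.indptr = np.cumsum(self.indptr)
        max_delay = int(self.edge_delay.max()) if self.edge_delay.size else 1
        self.ring = np.zeros((max_delay + 1, n))

        # plasticity groups -> flat per-edge arrays (kernel layout)
        self.plastic_groups = {g.name: g for g in plastic_groups}
        self._rebuild_plastic_arrays(enabled=None)
        self.plast_interval_steps = self._steps_of(plast_interval_ms, "plasticity interval")

        # dopamine machinery
        self.d_pop = (
            np.asarray(dopamine_pop, np.int64)
            if dopamine_pop is not None
            else np.empty(0, np.int64)
        )
        self.d_gain = float(d_gain)
        self.d_offset = float(d_offset)
        self.d_sample_steps = self._steps_of(1.0, "dopamine sampling interval")
        n_ring = int(round(d_baseline_window_ms / 1.0))
        self.d_ring = np.zeros(n_ring)
        # d_state: [ring pos, filled count, running sum, last D, last b_D]
        self.d_state = np.array([0.0, 0.0, 0.0, d_init, d_init])

        # dynamic state
        self.V = np.zeros(n)
        self.I_syn = np.zeros(n)
        self.ref_until = np.zeros(n, np.int64)
        self.F = np.zeros(n)
        self.e_F = float(np.exp(-self.dt / self.tau_F))
        self.f_incr = 1000.0 / self.tau_F  # unit-area kernel: F is in spikes/s
        self.step = 0
        self.rec_mask = np.ones(n, np.uint8)
        self._step_spk = np.empty(n, np.int64)
        mixed = (int(seed) * 0x2545F4914F6CDD1D + 0x9E3779B97F4A7C15) % (1 << 64)
        self.rng_state = np.array([mixed], np.uint64)

    # ------------------------------------------------------------------ helpers
    def _steps_of(self, interval_ms: float, what: str) -> int:
        steps = int(round(interval_ms / self.dt))
        if abs(steps * self.dt - interval_ms) > 1e-9 or steps < 1:
            raise ConfigurationError(f"{what} must be a positive multiple of dt")
        return steps

    @property
    def t_ms(self) -> float:
        return self.step * self.dt

    def pop(self, name: str) -> Population:
        return self.populations[name]

    def set_rates(self, pop_name: str, rates) -> None:
        """Set the externally driven rate (spikes/s) of a Poisson population."""
        p = self.pop(pop_name)
        if p.kind != "poisson":
            raise ConfigurationError(f"population {pop_name!r} is not a Poisson source")
        rates = np.broadcast_to(np.asarray(rates, float), (p.n,))
        if np.any(rates < 0):
            raise ValueError("Poisson rates must be non-negative")
        self.rate_base[p.start : p.stop] = rates

    def set_record_spikes(self, pop_name: str, record: bool) -> None:
        p = self.pop(pop_name)
        self.rec_mask[p.start : p.stop] = 1 if record else 0

    def _rebuild_plastic_arrays(self, enabled: set[str] | None) -> None:
        """Flatten enabled plastic groups into the kernel's edge/param arrays."""
        groups = [
            g
            for g in self.plastic_groups.values()
            if enabled is None or g.name in enabled
        ]
        idx = [self._edge_pos[g.edge_idx] for g in groups]
        self.pe_idx = (
            np.concatenate(idx).astype(np.int64) if idx else np.empty(0, np.int64)
        )
        self.pe_pre = self.edge_pre[self.pe_idx]
        self.pe_post = self.edge_post[self.pe_idx]
        self.pe_group = np.concatenate(
            [np.full(g.edge_idx.size, i, np.int64) for i, g in enumerate(groups)]
        ) if groups else np.empty(0, np.int64)
        self.pg_rule = np.array([g.rule for g in groups], np.int64)
        self.pg_mu = np.array([g.mu for g in groups], float)
        self.pg_kappa = np.array([g.kappa for g in groups], float)
        self.pg_ft = np.array([g.F_T for g in groups], float)
        self.pg_wmin = np.array([g.w_min for g in groups], float)
        self.pg_wmax = np.array([g.w_max for g in groups], float)
        self._enabled_groups = (
            set(self.plastic_groups) if enabled is None else set(enabled)
        )

    def enable_plasticity(self, group_names) -> None:
        """Restrict plasticity to the named groups (empty set disables all)."""
        names = set(group_names)
        unknown = names - set(self.plastic_groups)
        if unknown:
            raise ConfigurationError(f"unknown plastic groups: {sorted(unknown)}")
        self._rebuild_plastic_arrays(enabled=names)

    def get_weights(self, group_or_slice) -> np.ndarray:
        """Current weights of a plastic group (by name) or edge-id array."""
        if isinstance(group_or_slice, str):
            ids = self.plastic_groups[group_or_slice].edge_idx
        else:
            ids = np.asarray(group_or_slice, np.int64)
        return self.edge_weight[self._edge_pos[ids]].copy()

    def set_weights(self, group_or_ids, values) -> None:
        """Overwrite weights of a plastic group (by name) or edge-id array."""
        if isinstance(group_or_ids, str):
            ids = self.plastic_groups[group_or_ids].edge_idx
        else:
            ids = np.asarray(group_or_ids, np.int64)
        self.edge_weight[self._edge_pos[ids]] = values

    def edge_endpoints(self, group_name: str) -> tuple[np.ndarray, np.ndarray]:
        pos = self._edge_pos[self.plastic_groups[group_name].edge_idx]
        return self.edge_pre[pos].copy(), self.edge_post[pos].copy()

    # ------------------------------------------------------------------ running
    def run(
        self,
        duration_ms: float,
        plasticity: bool = True,
        record_spikes: bool = True,
        trace_units: np.ndarray | None = None,
        trace_interval_ms: float = 1.0,
        record_dopamine: bool = False,
        spike_rate_guess: float = 20.0,
    ) -> RunResult:
        """Advance the network by ``duration_ms`` and collect recordings.

        duration and recorder intervals must be multiples of dt.  With
        ``plasticity=False`` all weights are frozen for the duration.
        """
        n_steps = self._steps_of(duration_ms, "duration") if duration_ms > 0 else 0
        t0 = self.t_ms
        if n_steps == 0:
            return RunResult(
                SpikeRecord(np.empty(0, np.int64), np.empty(0)), t0, t0
            )
        rec_interval = 0
        rec_units = np.empty(0, np.int64)
        rec_buf = np.empty((0, 0))
        rec_row0 = 0
        if trace_units is not None:
            rec_interval = self._steps_of(trace_interval_ms, "recorder interval")
            rec_units = np.asarray(trace_units, np.int64)
            n_rows = (self.step + n_steps) // rec_interval - self.step // rec_interval
            rec_buf = np.empty((n_rows, rec_units.size))
            rec_row0 = self.step // rec_interval
        drec_buf = np.empty((0, 2))
        drec_row0 = 0
        if record_dopamine:
            ds = self.d_sample_steps
            drec_buf = np.empty(((self.step + n_steps) // ds - self.step // ds, 2))
            drec_row0 = self.step // ds

        cap = max(int(self.n_units * spike_rate_guess * duration_ms * 1e-3 * 1.5), 4096)
        sp_unit = np.empty(cap, np.int64)
        sp_step = np.empty(cap, np.int64)
        chunks_u: list[np.ndarray] = []
        chunks_t: list[np.ndarray] = []
        rec_mask = self.rec_mask if record_spikes else np.zeros(self.n_units, np.uint8)
        plast_interval = self.plast_interval_steps if (plasticity and self.pe_idx.size) else 0

        remaining = n_steps
        while remaining > 0:
            done, n_sp = _kernel.run_chunk(
                remaining,
                self.step,
                self.dt,
                self.kind,
                self.e_m,
                self.dv_gain,
                self.e_s,
                self.v_th,
                self.v_reset,
                self.ref_steps,
                self.i_bias,
                self.rate_base,
                self.rate_gain,
                self.V,
                self.I_syn,
                self.ref_until,
                self.F,
                self.e_F,
                self.f_incr,
                self.ring,
                self.indptr,
                self.edge_post,
                self.edge_weight,
                self.edge_delay,
                plast_interval,
                self.pe_idx,
                self.pe_pre,
                self.pe_post,
                self.pe_group,
                self.pg_rule,
                self.pg_mu,
                self.pg_kappa,
                self.pg_ft,
                self.pg_wmin,
                self.pg_wmax,
                self.d_pop,
                self.d_gain,
                self.d_offset,
                self.d_sample_steps if self.d_pop.size else 0,
                self.d_ring,
                self.d_state,
                rec_mask,
                sp_unit,
                sp_step,
                rec_interval,
                rec_units,
                rec_buf,
                rec_row0,
                drec_buf,
                drec_row0,
                self._step_spk,
                self.rng_state,
            )
            if n_sp:
                chunks_u.append(sp_unit[:n_sp].copy())
                chunks_t.append(sp_step[:n_sp] * self.dt)
            self.step += done
            remaining -= done
            if done == 0 and n_sp == 0:  # pragma: no cover - defensive
                raise SimulationError(f"no progress at t={self.t_ms} ms")
            if remaining > 0 and n_sp > 0.9 * cap:
                cap *= 2
                sp_unit = np.empty(cap, np.int64)
                sp_step = np.empty(cap, np.int64)
        if not np.all(np.isfinite(self.V)) or not np.all(np.isfinite(self.I_syn)):
            raise SimulationError(f"non-finite state at t={self.t_ms} ms")

        spikes = (
            SpikeRecord.concatenate(
                [SpikeRecord(u, t) for u, t in zip(chunks_u, chunks_t)]
            )
            if chunks_u
            else SpikeRecord(np.empty(0, np.int64), np.empty(0))
        )
        traces = None
        if trace_units is not None:
            times = (np.arange(rec_buf.shape[0]) + rec_row0 + 1) * rec_interval * self.dt
            traces = TraceRecord(times, rec_units, rec_buf)
        dope = None
        if record_dopamine:
            ds = self.d_sample_steps
            dt_col = (np.arange(drec_buf.shape[0]) + drec_row0 + 1) * ds * self.dt
            dope = np.column_stack([dt_col, drec_buf])
        return RunResult(spikes, t0, self.t_ms, traces, dope)


def advance_network(network: Network, n_steps: int = 1) -> tuple[Network, SpikeRecord]:
    """Advance the network by ``n_steps`` grid steps of dt.

    Returns the network (mutated in place) and the spikes emitted.  One
    step performs the exact-exponential membrane and synaptic-current
    update, threshold/reset/refractory handling, Poisson sampling and
    delayed spike delivery.
    """
    res = network.run(n_steps * network.dt)
    return network, res.spikes


def run_simulation(
    network: Network, duration_ms: float, **kwargs
) -> RunResult:
    """Run ``network`` for ``duration_ms``; see :meth:`Network.run`."""
    return network.run(duration_ms, **kwargs)
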