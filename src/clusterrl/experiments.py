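"""End-to-end task protocols.

Each experiment builds the circuit for the configured variant, runs the
task's stimulation/feedback protocol, and returns a results bundle with
per-trial outcomes, spike statistics and weight snapshots.  Runs are pure
functions of (config, seed): the single seed is expanded into independent
substreams for wiring, stimulus order, and tie-breaking, while the
simulator's own Poisson sampling derives from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import cv_isi, decide, filtered_traces, fit_eval_linear_readout
from .config import ExperimentConfig
from .core import ConfigurationError, Network, NeuronParams, Population, SpikeRecord
from .neuromodulation import (
    CriticCircuit,
    build_critic_circuit,
    dopamine_decode_args,
    immediate_reward_signal,
    set_reward_rate,
)
from .plasticity import TetzlaffParams
from .tasks import (
    GATES,
    LOGIC_PATTERN_ORDER,
    LOGIC_TRUTH_TABLE,
    MountainCar,
    RFEncoder,
    encode_image,
    generate_synthetic_digits,
    load_idx_images,
    load_idx_labels,
    rf_encode,
)
from .topology import (
    Circuit,
    ClusterMembership,
    ClusterSpec,
    build_representation_layer,
    wire_input_projections,
    wire_output_layer,
)

__all__ = ["ResultsBundle", "run_experiment"]


@dataclass
class ResultsBundle:
    """Everything one task run produced."""

    config: ExperimentConfig
    task: str
    outcomes: np.ndarray | None = None  # per-trial correct/incorrect or steps
    accuracies: dict | None = None  # xor: {gate: (pre, post)}
    spike_stats: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _cluster_spec(cfg: ExperimentConfig) -> ClusterSpec:
    net = cfg.network
    n_c = cfg.n_clusters_effective
    return ClusterSpec(
        n_exc=net.n_exc,
        n_inh=net.n_inh,
        n_clusters=n_c,
        conn_prob=net.conn_prob,
        j_plus=net.j_plus if n_c > 1 else 1.0,
        j_plus_inh=net.j_plus_inh if n_c > 1 else 1.0,
        j_ee=net.j_ee,
        j_ei=net.j_ei,
        j_ie=net.j_ie,
        j_ii=net.j_ii,
        exc_params=NeuronParams(
            tau_m=net.tau_m_exc, C=net.C, V_th=net.V_th, V_reset=net.V_reset,
            t_ref=net.t_ref, I_bias=net.I_bias_exc, tau_s=net.tau_s,
        ),
        inh_params=NeuronParams(
            tau_m=net.tau_m_inh, C=net.C, V_th=net.V_th, V_reset=net.V_reset,
            t_ref=net.t_ref, I_bias=net.I_bias_inh, tau_s=net.tau_s,
        ),
    )


# --------------------------------------------------------------------------
# logic gates
# --------------------------------------------------------------------------


def _xor_experiment(cfg: ExperimentConfig) -> ResultsBundle:
    """Small-network logic-gate protocol.

    Two rate-coded input neurons project with plastic uniform-initialized
    weights onto a handful of LIF neurons forming a weak WTA (static lateral
    inhibition plus independent background noise).  Filtered activity is
    recorded for the first and last `record_s` seconds; the unsupervised
    rule runs in between; an OLS readout is fit per gate on each recording.
    """
    x = cfg.xor
    rng = np.random.default_rng(cfg.seed)
    c = Circuit()
    c.add_population(Population("input", 2, "poisson"))
    c.add_population(Population("rep", x.n_rep, "lif", params=NeuronParams()))
    c.add_population(Population("noise", x.n_rep, "poisson", rate_base=x.noise_rate))
    rule = TetzlaffParams(
        mu=x.mu, kappa=x.kappa, F_T=x.F_T, w_min=0.0, w_max=x.w_max
    )
    wire_input_projections(
        c, "input", ["rep"], rng, x.init_low, x.init_high, rule,
        plastic=cfg.input_plasticity.enabled,
    )
    pre_l, post_l = np.nonzero(~np.eye(x.n_rep, dtype=bool))
    c.add_projection("wta", "rep", "rep", pre_l, post_l, -abs(x.j_wta))
    ids = np.arange(x.n_rep)
    c.add_projection("noise", "noise", "rep", ids, ids, x.w_noise)
    net = c.compile(dt=cfg.network.dt, seed=cfg.seed, plast_interval_ms=1.0)
    rep = net.pop("rep")

    def run_block(t_s: float, plastic: bool, record: bool):
        spks, targets = [], []
        t_start = net.t_ms
        for _ in range(int(round(t_s / 2.0))):
            for a, b in LOGIC_PATTERN_ORDER:
                net.set_rates(
                    "input",
                    [x.on_rate if a else x.off_rate, x.on_rate if b else x.off_rate],
                )
                res = net.run(500.0, plasticity=plastic, record_spikes=record)
                if record:
                    spks.append(res.spikes.for_population(rep))
                    tt = LOGIC_TRUTH_TABLE[(a, b)]
                    targets.append(np.tile([tt[g] for g in GATES], (500, 1)))
        if not record:
            return None, None, t_start
        return SpikeRecord.concatenate(spks), np.concatenate(targets), t_start

    s0, tg0, t0 = run_block(x.record_s, False, True)
    run_block(x.total_s - 2 * x.record_s, True, False)
    s1, tg1, t1 = run_block(x.record_s, True, True)
    accs = {}
    for rec, tg, t_start, key in ((s0, tg0, t0, 0), (s1, tg1, t1, 1)):
        tr = filtered_traces(
            rec, x.n_rep, t_start, t_start + x.record_s * 1000.0, x.tau_readout
        )
        for gi, g in enumerate(GATES):
            accs.setdefault(g, [None, None])[key] = fit_eval_linear_readout(
                tr, tg[:, gi]
            )
    accs = {g: tuple(v) for g, v in accs.items()}
    return ResultsBundle(
        config=cfg,
        task="xor",
        accuracies=accs,
        weights={"input_proj": net.get_weights("input_proj").reshape(2, x.n_rep)}
        if cfg.input_plasticity.enabled
        else {},
    )


# --------------------------------------------------------------------------
# digit classification
# --------------------------------------------------------------------------


def _build_digits_network(
    cfg: ExperimentConfig, rng: np.random.Generator, n_inputs: int = 784
) -> tuple[Network, ClusterMembership, Circuit]:
    spec = _cluster_spec(cfg)
    ip = cfg.input_plasticity
    op = cfg.output_plasticity
    c = Circuit()
    c.add_population(Population("input", n_inputs, "poisson"))
    membership = build_representation_layer(c, spec, rng)
    targets = ["rep_exc"] if ip.targets == "exc" else ["rep_exc", "rep_inh"]
    rule_in = TetzlaffParams(
        mu=ip.mu, kappa=ip.kappa, F_T=ip.F_T, w_min=ip.w_min, w_max=ip.w_max
    )
    wire_input_projections(
        c, "input", targets, rng, ip.init_low, ip.init_high, rule_in,
        plastic=ip.enabled, conn_prob=ip.conn_prob,
    )
    rule_out = TetzlaffParams(
        mu=op.mu, kappa=op.kappa, F_T=op.F_T, w_min=op.w_min, w_max=op.w_max
    )
    wire_output_layer(
        c, 3, "rep_exc", rng, rule_params=rule_out,
        w_init_low=op.init_low, w_init_high=op.init_high,
        j_lateral=op.j_lateral, bg_rate=op.bg_rate, w_bg=op.w_bg,
    )
    c.add_population(Population("da", 1, "poisson", rate_base=cfg.digits.da_base_rate))
    net = c.compile(
        dt=cfg.network.dt,
        seed=cfg.seed,
        plast_interval_ms=ip.update_interval,
        d_gain=1.0 / cfg.digits.da_base_rate,
        d_init=1.0,
    )
    da = net.pop("da")
    net.d_pop = np.arange(da.start, da.stop)
    return net, membership, c


def _digits_experiment(cfg: ExperimentConfig) -> ResultsBundle:
    """Digit classification with immediate reward.

    Each trial presents one image for `present_ms`; the decision is the most
    active output neuron (exponentially filtered); during a subsequent blank
    feedback window the dopamine neuron doubles its base rate (correct) or
    falls silent (incorrect), driving the three-factor rule on the output
    projections.  The unsupervised rule shapes the input projections
    throughout training.
    """
    d = cfg.digits
    wiring_rng = np.random.default_rng(cfg.seed)
    net, membership, circ = _build_digits_network(cfg, wiring_rng)
    stim_rng = np.random.default_rng(cfg.seed + 10_000)
    if d.synthetic or d.mnist_images is None:
        images, labels = generate_synthetic_digits(d.n_train + d.n_test, stim_rng)
    else:
        images = load_idx_images(d.mnist_images)
        labels = load_idx_labels(d.mnist_labels)
        keep = labels < 3
        images, labels = images[keep], labels[keep]
        order = stim_rng.permutation(len(images))[: d.n_train + d.n_test]
        images, labels = images[order], labels[order]
    out = net.pop("out")
    rep_e = net.pop("rep_exc")
    outcomes = []
    all_rep_spikes = []
    for k in range(len(labels)):
        training = k < d.n_train
        net.set_rates("input", encode_image(images[k], d.F_max))
        t0 = net.t_ms
        res = net.run(d.present_ms, plasticity=training)
        if k < 10 or k >= len(labels) - 10:
            all_rep_spikes.append(res.spikes.for_population(rep_e))
        decision = decide(
            res.spikes.for_population(out), 3, (t0, net.t_ms),
            cfg.output_plasticity.tau_dec, stim_rng,
        )
        ok = decision == labels[k]
        outcomes.append(ok)
        net.set_rates("input", np.zeros(784))
        sched = immediate_reward_signal("correct" if ok else "incorrect", d.da_base_rate)
        net.set_rates("da", sched.rate)
        net.run(sched.duration_ms, plasticity=training)
        net.set_rates("da", d.da_base_rate)
    outcomes = np.asarray(outcomes)
    stats = {}
    if all_rep_spikes:
        first = SpikeRecord.concatenate(all_rep_spikes[:10])
        try:
            stats["cv_isi_first"], _ = cv_isi(first, np.arange(rep_e.n))
        except ValueError:
            pass
        stats["rate_first"] = first.mean_rate(rep_e.n, 10 * d.present_ms)
        if len(all_rep_spikes) > 10:
            last = SpikeRecord.concatenate(all_rep_spikes[10:])
            try:
                stats["cv_isi_last"], _ = cv_isi(last, np.arange(rep_e.n))
            except ValueError:
                pass
            stats["rate_last"] = last.mean_rate(rep_e.n, 10 * d.present_ms)
    weights = {
        "output_proj": net.get_weights("output_proj").reshape(rep_e.n, 3),
    }
    proj = circ.projections["input_proj"]
    weights["input_proj_edges"] = np.column_stack(
        [proj.pre, proj.post, net.get_weights(proj.edge_ids)]
    )
    return ResultsBundle(
        config=cfg,
        task="digits",
        outcomes=outcomes,
        spike_stats=stats,
        weights=weights,
        extras={"labels": labels, "membership": membership},
    )


# --------------------------------------------------------------------------
# mountain car
# --------------------------------------------------------------------------


def _mountaincar_experiment(cfg: ExperimentConfig) -> ResultsBundle:
    """Closed-loop control with the actor-critic/RPE circuit.

    State is population-coded by Gaussian receptive fields; every
    environment step lasts `env_step_ms` of simulated time; the action is
    the most active output neuron over the step; rewards are injected as
    rate offsets on the RPE population, whose decoded concentration D(t)
    gates the three-factor rule on both the output (actor) and critic
    projections.
    """
    mc_cfg = cfg.mountaincar
    cc = cfg.critic
    rng = np.random.default_rng(cfg.seed)
    spec = _cluster_spec(cfg)
    ip = cfg.input_plasticity
    op = cfg.output_plasticity
    enc = RFEncoder(mc_cfg.n_rf, mc_cfg.rf_sigma, mc_cfg.rf_peak_rate)
    n_inputs = 2 * mc_cfg.n_rf

    c = Circuit()
    c.add_population(Population("input", n_inputs, "poisson"))
    membership = build_representation_layer(c, spec, rng)
    rule_in = TetzlaffParams(
        mu=ip.mu, kappa=ip.kappa, F_T=ip.F_T, w_min=ip.w_min, w_max=ip.w_max
    )
    wire_input_projections(
        c, "input", ["rep_exc"], rng, ip.init_low, ip.init_high, rule_in,
        plastic=ip.enabled, conn_prob=1.0,
    )
    rule_out = TetzlaffParams(
        mu=op.mu, kappa=op.kappa, F_T=op.F_T, w_min=op.w_min, w_max=op.w_max
    )
    wire_output_layer(
        c, 3, "rep_exc", rng, rule_params=rule_out,
        w_init_low=op.init_low, w_init_high=op.init_high,
        j_lateral=op.j_lateral, bg_rate=op.bg_rate, w_bg=op.w_bg,
    )
    critic_spec = CriticCircuit(
        n_critic=cc.n_critic, n_rpe=cc.n_rpe, delay_exc=cc.delay_exc,
        delay_inh=cc.delay_inh, tau_r=cc.tau_r, critic_base=cc.critic_base,
        rpe_base=cc.rpe_base, d_gain=cc.d_gain, tau_v=cc.tau_v,
    )
    rule_critic = TetzlaffParams(
        mu=cc.mu, kappa=cc.kappa, F_T=cc.F_T, w_min=0.0, w_max=cc.w_max
    )
    _, rpe = build_critic_circuit(
        c, critic_spec, "rep_exc", rng, rule_params=rule_critic, dt=cfg.network.dt
    )
    net = c.compile(
        dt=cfg.network.dt,
        seed=cfg.seed,
        plast_interval_ms=ip.update_interval,
        dopamine_pop=np.arange(rpe.start, rpe.stop),
        **dopamine_decode_args(critic_spec),
    )
    net.set_record_spikes("rpe", False)

    env = MountainCar()
    episode_steps = []
    d_log = []
    trajectory = []
    for _ in range(mc_cfg.n_episodes):
        env.reset(rng)
        steps = 0
        done = False
        while not done and steps < mc_cfg.max_steps:
            xn, vn = env.normalized()
            net.set_rates("input", rf_encode(xn, vn, enc))
            t0 = net.t_ms
            res = net.run(mc_cfg.env_step_ms, record_dopamine=True)
            action = decide(
                res.spikes.for_population(net.pop("out")), 3,
                (t0, net.t_ms), op.tau_dec, rng,
            )
            state, reward, done = env.step(action)
            # reward held as an RPE rate offset for the next step
            set_reward_rate(net, critic_spec, reward * cc.reward_gain)
            trajectory.append((net.t_ms, state.x, state.v, action, reward))
            if res.dopamine is not None:
                d_log.append(res.dopamine[-1])
            steps += 1
        set_reward_rate(net, critic_spec, 0.0)
        episode_steps.append(steps)
    return ResultsBundle(
        config=cfg,
        task="mountaincar",
        outcomes=np.asarray(episode_steps),
        extras={
            "trajectory": np.asarray(trajectory),
            "dopamine": np.asarray(d_log),
            "membership": membership,
        },
    )


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Run the task protocol named in the config and return its results."""
    if config.task == "xor":
        return _xor_experiment(config)
    if config.task == "digits":
        return _digits_experiment(config)
    if config.task == "mountaincar":
        return _mountaincar_experiment(config)
    raise ConfigurationError(f"unknown task {config.task!r}")
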