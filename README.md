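# clusterrl

Spiking neural networks that *learn their own state representation*.
`clusterrl` implements a three-layer architecture for reinforcement
learning with biologically motivated plasticity: a rate-coded Poisson
**input layer**, a clustered balanced random network of leaky
integrate-and-fire (LIF) neurons as **representation layer**, and a
winner-takes-all **output layer**.  Input projections adapt with an
unsupervised Hebbian rule with quadratic synaptic scaling; output
projections adapt with a dopamine-modulated three-factor rule, with the
dopamine concentration produced either by an immediate correct/incorrect
signal (classification) or by a spiking actor–critic circuit that encodes
a reward prediction error (closed-loop control).

It is aimed at computational neuroscientists studying how clustered
connectivity and local plasticity can self-organize task-relevant state
spaces without hand-designed place cells or receptive fields.

## Model

Membrane dynamics (exact-exponential integration on a 0.1 ms grid):

    dV/dt = -V/τ_m + I(t)/C,      dI_i/dt = -I_i/τ_s + w_i Σ_f δ(t - t_i^f)

Unsupervised rule on input projections (rates F are exponentially filtered
spike trains, τ = 100 ms; F^T is the homeostatic set point):

    Δw_ji = μ ( F_i F_j + κ (F^T - F_j) w_ji² )

Three-factor rule on output projections, gated by the dopamine
concentration D relative to its 10-s moving-average baseline b_D:

    Δw_ji = μ ( (D - b_D) F_i F_j + κ (F^T - F_j) w_ji² )

The reward prediction error is the continuous analogue of the TD error,
D(t) = v̇ + r - v/τ_r, realized by a dual excitatory (1 ms) / inhibitory
(20 ms) connection from a 20-neuron critic population onto a 1000-neuron
RPE population.

Clustered connectivity keeps the connection probability uniform but scales
within-cluster weights up by J⁺ and between-cluster weights down by
J⁻ = (n_clusters − J⁺)/(n_clusters − 1), conserving each neuron's expected
total synaptic input.

## Worked example: the XOR task

Two rate-coded inputs (1000 Hz = "1", 10 Hz = "0") drive three LIF neurons
in a weak winner-takes-all circuit; the four input combinations cycle
every 2 s for 500 s while the unsupervised rule shapes the six input
weights.  A least-squares readout of the filtered activity is fit before
and after learning:

```bash
clusterrl run xor --seed 1 --outdir results/xor
```

prints (seed 1):

```
OR: pre=0.951 post=0.968
AND: pre=0.952 post=0.973
XOR: pre=0.470 post=0.958
IMPL: pre=0.899 post=0.953
```

Before learning the readout solves the linearly separable gates but is at
chance on XOR; after unsupervised learning the three neurons have
specialized (one per active input pattern, including a dedicated neuron
for the both-on pattern) and all four gates are read out above 95%.

The digit-classification and Mountain Car protocols run the full
clustered network with reinforcement learning:

```bash
clusterrl run digits --seed 1 --outdir results/digits
clusterrl run mountaincar --preset smoke --outdir results/mc
```

`clusterrl analyze <dir>` recomputes summary statistics from a saved run.
All protocols are also available programmatically via
`clusterrl.experiments.run_experiment(config)` with YAML-configurable
parameters (`clusterrl.config.validate_config`).

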