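# Methods

## Neuron and synapse model

All deterministic units are current-based leaky integrate-and-fire
neurons: `dV/dt = -V/τ_m + I/C` with threshold `V_th`, reset `V_reset`,
and an absolute refractory period during which the membrane is clamped.
Each presynaptic spike increments the postsynaptic current by the synaptic
weight (pA), and the current relaxes exponentially with τ_s.  Integration
uses the exact exponential-Euler update

    V ← V·e^{−dt/τ_m} + (I_syn + I_bias)·(τ_m/C)·(1 − e^{−dt/τ_m}),

which reproduces the closed-form leak trajectory to machine precision and
is unconditionally stable; dt = 0.1 ms, and all delays, durations and
recorder intervals are snapped to this grid (delays must be ≥ 1 step).
Defaults: τ_m = 20 ms (excitatory) / 10 ms (inhibitory), C = 250 pF,
V_th = 20 mV above a 0 mV reset, t_ref = 2 ms, τ_s = 5 ms.  Excitatory and
inhibitory neurons differ only in τ_m and the constant bias current.

Rate-modulated Poisson units share the synaptic-current machinery and fire
with instantaneous rate `max(0, rate_base + rate_gain · I_syn)`, sampled
per step by Bernoulli thinning (p = rate·dt; adequate because rate·dt ≤ 0.1
everywhere in the shipped protocols).  Every unit carries an exponential
rate trace F with a unit-area kernel (τ_F = 100 ms), so F estimates the
firing rate in spikes/s; these traces are the pre/post factors of the
plasticity rules and double as eligibility traces across short blank
periods.

The per-step loop is JIT-compiled (numba) and the in-kernel random stream
is a splitmix64 counter generator, so any run is a bit-reproducible pure
function of (configuration, seed).

## Topology

The representation layer is a clustered balanced random network:
Bernoulli(p = 0.2) connectivity uniform over all pairs, no
self-connections, excitatory weights positive and inhibitory negative.
Within-cluster weights are scaled by `j_plus` and between-cluster weights
by `j_minus = (n_clusters − j_plus)/(n_clusters − 1)`, which conserves the
expected summed input per neuron (exact per-neuron conservation would
require fixed in-degrees and is incompatible with Bernoulli wiring; the
conservation tests therefore compare population means over a few wiring
realizations, separately for excitatory and inhibitory inputs).

Excitatory-to-excitatory clustering and the clustering of the blocks
involving inhibition are controlled separately (`j_plus` vs
`j_plus_inh`).  This matters: scaling all four blocks by the same factor
weakens the *between*-cluster inhibitory coupling (its scale factor drops
below one), which removes the competition between clusters and lets
several clusters stay active at once.  The defaults use strong E→E
clustering (j_plus = 8 at the smoke scale) with mild inhibitory clustering
(j_plus_inh = 1.5), giving winner-take-most dynamics across clusters.

Input projections are plastic and excitatory.  They are all-to-all by
default; the digit task uses sparse input sampling (connection probability
0.1 with correspondingly larger weights).  The reason is quantitative:
with 784 inputs connected all-to-all and narrow uniform weights, the
standard deviation of the stimulus-evoked drive across neurons is ~2% of
its mean — there is essentially no stimulus tuning anywhere in the
network, and no mixed selectivity for learning to amplify.  Sparse
sampling of ~78 pixels per neuron restores ~30% drive heterogeneity and
measurable class information in the initial responses.

The output layer is a soft winner-takes-all circuit: plastic excitatory
projections from the excitatory representation neurons (keeping the
plastic weights non-negative is then Dale-consistent), static all-to-all
lateral inhibition without self-inhibition, and an independent background
Poisson source per output neuron.  The background drive is deliberately
*subthreshold* (≈200 pA against a 250 pA rheobase): output neurons then
fire only when representation input is present, so during the feedback
window the eligibility trace F_j singles out the output that actually won
the decision.  A suprathreshold background makes all outputs fire during
feedback and smears the reinforcement credit across actions.

## Plasticity

Both rules are rate-based and applied at a coarse interval (default 1 ms
for the logic task, 5 ms for the network tasks) using the current traces;
`μ` is the increment per update.  Weights are clipped to
[w_min, w_max] after every update (w_min = 0 keeps synapses excitatory; a
large w_max guards against transient overshoot by spiking noise).  With
clamped rates and F_j > F^T the unmodulated rule converges to
`w* = sqrt(F_i F_j / (κ (F_j − F^T)))` from any start in (0, 2w*) for
sufficiently small μ, and `fixed_point()` exposes this closed form.

The three-factor rule multiplies only the Hebbian term by (D − b_D).  The
baseline b_D is a trailing 10-s boxcar mean of D maintained in a ring
buffer sampled every millisecond; before the window has filled, the mean
runs over the available samples, so early (D − b_D) values are
conservative.  Setting D = b_D + 1 reduces the modulated rule to the plain
rule exactly (bit-for-bit when the unit modulation is exactly
representable in floating point).

## Dopamine circuit

The critic is a population of 20 rate-modulated Poisson neurons driven by
plastic projections from the excitatory representation neurons (value
learning, also under the three-factor rule).  Each critic neuron connects
to each of the 1000 Poisson RPE neurons twice: excitatory at 1 ms delay,
inhibitory at 20 ms.  Expanding the delayed rates to first order, the RPE
drive is `α[(w₊ − w₋)v + (w₋d₂ − w₊d₁)v̇]`; the two weights are solved so
this equals `g_D(v̇ − v/τ_r)` exactly in the stationary limit, using the
discrete-time current per spike `τ_eff = dt/(1 − e^{−dt/τ_v})` to cancel
the integration-grid bias.  Environmental reward enters as an additive
rate offset on the RPE population, and D is decoded as the population-mean
unit-area-filtered rate, linearly mapped so that the working point r₀
reads as D = 0.

The value estimate is smoothed with τ_v = 100 ms on the RPE synapses.
This is a deliberate choice: with a fast synapse (τ_s = 5 ms) the per-spike
kicks required by the derivative coupling are ~20× larger, the RPE rate
rectifies at zero, and the decoded concentration acquires a large positive
bias.  The smoothing spreads the transient response to a value step over
a few hundred milliseconds while preserving its integral (= g_D·Δv), which
is what the validation probes measure.  Since baseline subtraction makes
(D − b_D) invariant to constant offsets, values may be encoded relative to
an arbitrary working rate; τ_r defaults to 1 s.

For classification the critic is bypassed: a single dopamine neuron fires
at a 100 Hz base rate, doubles its rate for 100 ms after a correct
decision and falls silent for 100 ms after an incorrect one, so that
correct ⇒ D − b_D > 0 and incorrect ⇒ D − b_D < 0.

## Tasks and protocols

**Logic gates.** Two input neurons code the operand bits as 1000 vs 10
spikes/s; the four combinations cycle in 500-ms slots (period 2 s).  The
representation is three LIF neurons with −1000 pA lateral inhibition and a
small independent background noise source per neuron (1000 Hz × 8 pA).
The noise is required at this size: with only two shared input spike
trains, deterministic twin neurons can lock into identical weight
trajectories that plasticity never separates.  Weights start uniform in
[33.33, 66.66]; μ = 10⁻⁶, κ = 0.3, F^T = 5 spikes/s (chosen so the
pattern-specific weight fixed points sit inside the weight bounds and each
neuron's duty cycle supports roughly one pattern).  Protocol: 50 s
recording without plasticity, learning until 500 s, recording again over
the last 50 s; an ordinary-least-squares readout of the 1000-Hz-sampled
filtered activity (readout filter τ = 30 ms, matching the state-decoding
filter; the 100-ms plasticity trace is too sluggish at the 500-ms pattern
boundaries) is thresholded at 0.5 to score each gate.

**Digit classification.** 28×28 images are rate-coded one neuron per
pixel, rate = F_max·g/255 with F_max = 60 spikes/s, presented for 500 ms
with a 100-ms blank feedback window.  The decision is the most active
output neuron (exponential filter, τ_dec = 50 ms) at stimulus end.  The
built-in generator renders three digit classes with two handwriting
sub-styles each (round/oval-tilted zero, straight/tilted one,
looped/unlooped two) from parametric strokes, adds rotation/scale/shift
writer variability plus pixel noise, and normalizes every image to a
common summed intensity so the classes differ in shape rather than
brightness (overall brightness otherwise confounds which cluster responds).
A held-out linear classifier on raw pixels scores ~80–90%: the classes
overlap but are learnable.  MNIST IDX files can be substituted when
available; all shipped tests use the generator.

**Mountain Car.** A self-contained implementation of the standard
under-powered car: force 0.001, gravity 0.0025·cos(3x), goal at x ≥ 0.5,
inelastic left wall, −1 reward per step with +1 added at the goal, and no
time limit (a configurable safety cap bounds episodes in short runs).  The
velocity bound is ±0.07, the value consistent with these dynamics
constants.  Position and velocity are normalized to [−1, 1] and encoded by
200 Gaussian receptive fields per dimension (σ = 0.05, peak 35 spikes/s);
each environment step lasts 20 ms of simulated time.

## Scales, what the tests show, and known limitations

The shipped protocols run at desk scale: the logic task at its original
size (3 neurons, 500 s), the network tasks on a ~500-neuron representation
layer (400 E / 96 I, 8 clusters) with 200 stimulus presentations.  The
acceptance suite verifies, at this scale: the learning-rule fixed point
and the exact baseline reduction of the three-factor rule; conservation of
synaptic strength under clustering; the spiking RPE circuit against both
the closed-form concentration and the discrete TD error; the full
logic-gate protocol (unsupervised learning lifts the non-linear gate from
chance-level to ≥95% readout accuracy on nearly every seed); and the
analysis oracles.

One documented property does *not* reproduce at this scale: on the
200-presentation digit task, the clustered-plastic > unclustered-plastic >
static-at-chance ordering of final accuracy.  The individual mechanisms
all work in isolation — given a stable class-organized representation the
three-factor output rule reaches ~70% in 200 trials, and the unsupervised
rule produces clean pattern specialization in the logic task — but the
joint bootstrap, in which clusters must become class-selective through
unsupervised imprinting while the output layer learns from them, needs
either more neurons per cluster (quenched wiring disorder at 50 E neurons
per cluster outweighs the class-dependent drive differences that the
bootstrap amplifies) or several-fold more presentations than the
smoke-scale budget.  The corresponding acceptance test is left in place
and failing rather than weakened.  Passing tests therefore demonstrate the
correctness of the dynamics, rules, circuit calibration and protocols, not
the full-scale self-organization result.

Other limitations: synapses are current-based and static within the
recurrent network (by design); pair-based spike-timing plasticity is out
of scope; the critic/RPE circuit is a minimal functional construction, not
a biological model; and the synthetic digit generator emulates style
variance but not the full covariance structure of handwritten digits.
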