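"""Decision readout, linear-readout accuracy, and spike-train statistics."""

import numpy as np
import pytest

from clusterrl.core import ConfigurationError, SpikeRecord
from clusterrl.analysis import (
    cluster_specificity,
    cv_isi,
    decide,
    filtered_traces,
    fit_eval_linear_readout,
    performance_curve,
    receptive_field,
    reconstruct_state,
)
from clusterrl.plasticity import TetzlaffParams, apply_update, tetzlaff_update
from clusterrl.tasks import RFEncoder, rf_encode


def _record(pairs):
    pairs = sorted(pairs, key=lambda p: p[1])
    return SpikeRecord(
        np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
    )


def test_decide_single_active_neuron():
    rec = _record([(2, 10.0), (2, 20.0), (2, 30.0)])
    assert decide(rec, 3, (0.0, 50.0)) == 2


def test_decide_all_silent_is_seeded_uniform():
    rec = SpikeRecord(np.empty(0, np.int64), np.empty(0))
    choices = {decide(rec, 3, (0, 50), rng=np.random.default_rng(s)) for s in range(30)}
    assert choices == {0, 1, 2}
    a = decide(rec, 3, (0, 50), rng=np.random.default_rng(5))
    b = decide(rec, 3, (0, 50), rng=np.random.default_rng(5))
    assert a == b


def test_decide_equivariant_under_relabeling():
    rng = np.random.default_rng(3)
    units = rng.integers(0, 5, 200)
    times = np.sort(rng.uniform(0, 100, 200))
    rec = SpikeRecord(units, times)
    perm = rng.permutation(5)
    rec_p = SpikeRecord(perm[units], times)
    d = decide(rec, 5, (0, 100), rng=np.random.default_rng(0))
    d_p = decide(rec_p, 5, (0, 100), rng=np.random.default_rng(0))
    assert d_p == perm[d]


def test_decide_invariant_to_rate_scaling():
    rng = np.random.default_rng(4)
    units = rng.integers(0, 4, 100)
    times = np.sort(rng.uniform(0, 100, 100))
    rec = SpikeRecord(units, times)
    doubled = SpikeRecord(np.repeat(units, 2), np.repeat(times, 2))
    assert decide(rec, 4, (0, 100)) == decide(doubled, 4, (0, 100))


def test_decide_requires_outputs():
    with pytest.raises(ConfigurationError):
        decide(SpikeRecord(np.empty(0, np.int64), np.empty(0)), 0, (0, 1))


def test_linear_readout_perfect_traces():
    targets = np.tile([0, 1], 50).astype(float)
    traces = targets[:, None]
    assert fit_eval_linear_readout(traces, targets) == 1.0


def test_linear_readout_uninformative_traces_near_chance():
    rng = np.random.default_rng(0)
    traces = rng.normal(size=(4000, 3))
    targets = np.tile([0, 1], 2000).astype(float)
    acc = fit_eval_linear_readout(traces, targets)
    assert abs(acc - 0.5) < 0.05


def test_linear_readout_separable_xor_pattern():
    """Two units high / one low on XOR=1, reversed otherwise: 100% accuracy."""
    rng = np.random.default_rng(1)
    n = 400
    xor = np.tile([0, 1], n // 2).astype(float)
    traces = np.empty((n, 3))
    traces[xor == 1] = [5.0, 40.0, 40.0]
    traces[xor == 0] = [40.0, 5.0, 5.0]
    traces += rng.normal(0, 1.0, traces.shape)
    assert fit_eval_linear_readout(traces, xor) == 1.0


def test_cv_isi_statistics():
    # perfectly regular train
    reg = SpikeRecord(np.zeros(100, np.int64), np.arange(100) * 10.0)
    cv, _ = cv_isi(reg, [0])
    assert cv == pytest.approx(0.0, abs=1e-12)
    # Poisson train: CV near 1 (exponential ISIs)
    rng = np.random.default_rng(2)
    isis = rng.exponential(10.0, 20_000)
    poiss = SpikeRecord(np.zeros(isis.size, np.int64), np.cumsum(isis))
    cv, _ = cv_isi(poiss, [0])
    assert cv == pytest.approx(1.0, abs=0.05)
    # burst/silent mixture: CV > 1
    isis = np.where(rng.random(20_000) < 0.5, rng.exponential(1.0, 20_000),
                    rng.exponential(50.0, 20_000))
    burst = SpikeRecord(np.zeros(isis.size, np.int64), np.cumsum(isis))
    cv, _ = cv_isi(burst, [0])
    assert cv > 1.0


def test_cv_isi_exclusion_and_failure():
    rec = _record([(0, 1.0), (0, 2.0), (0, 4.0), (1, 5.0)])
    cv, excluded = cv_isi(rec, [0, 1])
    assert excluded == 1
    with pytest.raises(ValueError):
        cv_isi(rec, [1])


@pytest.mark.parametrize(
    "Wbar,expected",
    [
        (np.array([[1.0, 1.0, 1.0]]), 1 / 3),
        (np.array([[0.0, 1.0, 0.0]]), 1.0),
        (np.array([[0.6, 0.3, 0.1]]), 0.6),
    ],
)
def test_cluster_specificity_values(Wbar, expected):
    W = np.repeat(Wbar, 5, axis=0)  # 5 identical neurons in one cluster
    S = cluster_specificity(W, np.zeros(5, int))
    assert S[0] == pytest.approx(expected)


def test_cluster_specificity_bounds_and_nan():
    rng = np.random.default_rng(0)
    W = rng.random((60, 4))
    cl = np.repeat(np.arange(3), 20)
    S = cluster_specificity(W, cl)
    assert np.all((S >= 0.25 - 1e-12) & (S <= 1.0 + 1e-12))
    W[cl == 2] = 0.0
    S = cluster_specificity(W, cl)
    assert np.isnan(S[2])
    with pytest.raises(ValueError):
        cluster_specificity(-W, cl)


def test_receptive_field_flat_and_independent():
    W = np.full((784, 10), 2.5)
    maps = receptive_field(W, np.repeat([0, 1], 5))
    assert maps.shape == (2, 28, 28)
    assert np.allclose(maps, 2.5)
    # maps of disjoint clusters are computed independently
    W2 = W.copy()
    W2[:, 5:] = 7.0
    maps2 = receptive_field(W2, np.repeat([0, 1], 5))
    assert np.allclose(maps2[0], 2.5) and np.allclose(maps2[1], 7.0)


def test_receptive_field_reflects_trained_image():
    """Clamped-rate training on one image imprints it on the field map."""
    rng = np.random.default_rng(7)
    image = np.zeros((28, 28))
    image[8:20, 10:16] = 200.0
    rates = image.ravel() * 60.0 / 255.0
    params = TetzlaffParams(mu=1e-5, kappa=0.5, F_T=10.0, w_max=100.0)
    w = rng.uniform(1.0, 2.0, size=(784, 6))
    for _ in range(3000):
        dw = tetzlaff_update(w, rates[:, None], 30.0, params)
        w = apply_update(w, dw, params)
    maps = receptive_field(w, np.zeros(6, int))
    r = np.corrcoef(maps[0].ravel(), image.ravel())[0, 1]
    assert r > 0.5


def test_reconstruct_state_single_neuron():
    enc = RFEncoder()
    rec = _record([(30, t) for t in np.arange(5.0, 200.0, 5.0)])
    df = reconstruct_state(rec, enc, 0.0, 200.0)
    assert df["x_hat"].iloc[-1] == pytest.approx(enc.centers[30])


def test_reconstruct_state_round_trip():
    """High-rate encode/decode recovers held positions to within the
    receptive-field grid spacing (evaluated after the filter settles)."""
    enc = RFEncoder()
    rng = np.random.default_rng(11)
    dt = 0.1
    hold_ms = 300.0
    positions = rng.uniform(-0.8, 0.8, 10)
    units, times = [], []
    for k, x in enumerate(positions):
        t0 = k * hold_ms
        rates = rf_encode(x, 0.0, enc) * 60.0  # dense spikes
        for i in range(int(hold_ms / dt)):
            fired = np.flatnonzero(rng.random(rates.size) < rates * dt * 1e-3)
            units.extend(fired)
            times.extend([t0 + i * dt] * fired.size)
    rec = SpikeRecord(np.array(units), np.array(times))
    df = reconstruct_state(rec, enc, 0.0, len(positions) * hold_ms)
    errs = []
    for k, x in enumerate(positions):
        settled = df["x_hat"].to_numpy()[int(k * hold_ms) + 150 : int((k + 1) * hold_ms)]
        errs.append(np.abs(settled - x).mean())
    assert np.mean(errs) < 2.0 / enc.n_per_dim


def test_reconstruct_state_mirror_symmetry():
    enc = RFEncoder(n_per_dim=50)
    rng = np.random.default_rng(3)

    def spikes_for(xs):
        units, times = [], []
        for i, x in enumerate(xs):
            rates = np.concatenate([enc.encode_1d(x), enc.encode_1d(0.0)]) * 30.0
            fired = np.flatnonzero(rng.random(100) < rates * 1e-3)
            units.extend(fired)
            times.extend([i * 1.0] * fired.size)
        return SpikeRecord(np.array(units), np.array(times))

    xs = np.linspace(-0.9, 0.9, 500)
    rng = np.random.default_rng(3)
    a = reconstruct_state(spikes_for(xs), enc, 100.0, 500.0)
    rng = np.random.default_rng(3)
    b = reconstruct_state(spikes_for(-xs), enc, 100.0, 500.0)
    # centers are mirror-symmetric up to half a grid step
    assert np.nanmean(np.abs(a["x_hat"].to_numpy() + b["x_hat"].to_numpy())) < 0.1


def test_performance_curves_match_naive_oracle():
    rng = np.random.default_rng(5)
    outcomes = rng.random(200) < 0.7
    curve = performance_curve(outcomes, "sliding_mean_30")
    naive = np.array([outcomes[i : i + 30].mean() for i in range(171)])
    np.testing.assert_allclose(curve, naive, rtol=0, atol=1e-15)
    steps = rng.integers(50, 500, 80)
    med = performance_curve(steps, "running_median_10")
    naive_med = np.array([np.median(steps[i : i + 10]) for i in range(71)])
    np.testing.assert_allclose(med, naive_med)


def test_performance_curve_edge_cases():
    assert np.allclose(performance_curve(np.ones(40), "sliding_mean_30"), 1.0)
    alt = performance_curve(np.tile([1, 0], 30), "sliding_mean_30")
    assert np.allclose(alt, 0.5, atol=0.02)
    with pytest.raises(ValueError):
        performance_curve(np.ones(5), "sliding_mean_30")
    with pytest.raises(ValueError):
        performance_curve(np.ones(50), "bogus")


def test_filtered_traces_match_explicit_convolution():
    rec = _record([(0, 3.0), (0, 7.0), (1, 4.0)])
    tr = filtered_traces(rec, 2, 0.0, 10.0, tau=5.0)
    t_eval = 10.0
    expected0 = (1000 / 5.0) * (
        np.exp(-(t_eval - 3.0 - 1.0 + 1.0) / 5.0)  # binned at 1-ms boundaries
    )
    # spikes are accumulated at the end of their 1-ms bin
    e0 = (1000 / 5.0) * (np.exp(-(10 - 4) / 5.0) + np.exp(-(10 - 8) / 5.0))
    e1 = (1000 / 5.0) * np.exp(-(10 - 5) / 5.0)
    assert tr[-1, 0] == pytest.approx(e0)
    assert tr[-1, 1] == pytest.approx(e1)
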