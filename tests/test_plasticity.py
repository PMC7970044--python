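"""The Hebbian/synaptic-scaling rule, its three-factor extension, rate
traces and the dopamine baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterrl.plasticity import (
    DopamineTrace,
    RateTrace,
    TetzlaffParams,
    apply_update,
    tetzlaff_update,
    three_factor_update,
    update_dopamine_baseline,
    update_rate_trace,
)


def test_rate_trace_decay_closed_form():
    tr = RateTrace(np.array([10.0]), tau_F=100.0)
    for _ in range(1000):
        tr = update_rate_trace(tr, [0], 0.1)
    assert tr.F[0] == pytest.approx(10.0 * np.exp(-1.0), rel=1e-9)


def test_rate_trace_kernel_normalization():
    """A single spike raises F by 1000/tau_F: unit-area kernel in spikes/s."""
    tr = RateTrace(np.zeros(1), tau_F=100.0)
    tr = update_rate_trace(tr, [1], 0.1)
    assert tr.F[0] == pytest.approx(10.0)


def test_rate_trace_estimates_rate():
    """A regular 50 spikes/s train averages to F = 50 (convolution oracle)."""
    tr = RateTrace(np.zeros(1), tau_F=100.0)
    dt = 0.1
    vals = []
    for step in range(200_000):
        spike = int((step % 200) == 0)  # every 20 ms
        tr = update_rate_trace(tr, [spike], dt)
        vals.append(tr.F[0])
    assert np.mean(vals[10_000:]) == pytest.approx(50.0, abs=1.0)


@pytest.mark.parametrize(
    "w,F_i,F_j,params,expected",
    [
        (1.0, 0.0, 10.0, TetzlaffParams(mu=0.01, kappa=0.1, F_T=10.0), 0.0),
        (2.0, 0.0, 0.0, TetzlaffParams(mu=0.01, kappa=0.1, F_T=5.0), 0.02),
    ],
)
def test_tetzlaff_update_examples(w, F_i, F_j, params, expected):
    assert tetzlaff_update(w, F_i, F_j, params) == pytest.approx(expected)


def test_tetzlaff_fixed_point_iteration():
    """Clamped rates converge to w* = sqrt(F_i F_j / (kappa (F_j - F_T)))."""
    params = TetzlaffParams(mu=1e-4, kappa=0.05, F_T=10.0, w_max=1e4)
    w_star = params.fixed_point(20.0, 30.0)
    assert w_star == pytest.approx(np.sqrt(600.0))
    for w0 in (1.0, 10.0, 40.0):
        w = w0
        for _ in range(200_000):
            w = apply_update(w, tetzlaff_update(w, 20.0, 30.0, params), params)
        assert w == pytest.approx(w_star, rel=1e-3)


@pytest.mark.parametrize(
    "w,F_i,F_j,D,b_D,params,expected",
    [
        # D at baseline: pure homeostasis
        (2.0, 30.0, 20.0, 1.0, 1.0, TetzlaffParams(mu=0.01, kappa=0.1, F_T=5.0),
         0.01 * 0.1 * (5.0 - 20.0) * 4.0),
        # negative prediction error depresses
        (1.0, 10.0, 10.0, 0.0, 1.0, TetzlaffParams(mu=0.01, kappa=0.0), -1.0),
    ],
)
def test_three_factor_update_examples(w, F_i, F_j, D, b_D, params, expected):
    assert three_factor_update(w, F_i, F_j, D, b_D, params) == pytest.approx(expected)


def test_three_factor_potentiates_under_reward():
    p = TetzlaffParams(mu=0.01, kappa=0.1, F_T=10.0)
    dw = three_factor_update(1.0, 20.0, 10.0, 2.0, 1.0, p)
    assert dw > 0


def test_three_factor_at_baseline_plus_one_equals_hebbian_bitwise():
    """With D = b_D + 1 the modulated rule reduces exactly to the plain rule."""
    p = TetzlaffParams(mu=3e-4, kappa=0.07, F_T=8.0, w_max=500.0)
    rng = np.random.default_rng(0)
    w_a = w_b = 5.0
    baselines = np.array([0.0, 0.5, 1.0, 2.0])  # (b+1)-b is exactly 1.0
    for _ in range(10_000):
        F_i, F_j = rng.uniform(0, 50, 2)
        b_D = float(rng.choice(baselines))
        w_a = apply_update(w_a, tetzlaff_update(w_a, F_i, F_j, p), p)
        w_b = apply_update(w_b, three_factor_update(w_b, F_i, F_j, b_D + 1.0, b_D, p), p)
        assert float(w_a) == float(w_b)  # bitwise identical trajectories


def test_homeostatic_term_sign():
    p = TetzlaffParams(mu=1.0, kappa=0.5, F_T=10.0)
    for F_j in (0.0, 5.0, 15.0, 50.0):
        dw = tetzlaff_update(3.0, 0.0, F_j, p)
        assert np.sign(dw) == np.sign(p.F_T - F_j)


@settings(max_examples=50, deadline=None)
@given(
    w0=st.floats(0.0, 100.0),
    rates=st.lists(st.tuples(st.floats(0, 200), st.floats(0, 200)), min_size=1,
                   max_size=50),
)
def test_weights_stay_bounded(w0, rates):
    p = TetzlaffParams(mu=0.1, kappa=0.3, F_T=10.0, w_min=0.0, w_max=50.0)
    w = min(w0, p.w_max)
    for F_i, F_j in rates:
        w = apply_update(w, tetzlaff_update(w, F_i, F_j, p), p)
        assert p.w_min <= w <= p.w_max


def test_dopamine_baseline_constant():
    tr = DopamineTrace(window_ms=10_000.0, sample_interval=1.0)
    for _ in range(12_000):
        update_dopamine_baseline(tr, 3.0, 1.0)
    assert tr.b_D == pytest.approx(3.0)
    assert tr.D - tr.b_D == pytest.approx(0.0)


def test_dopamine_baseline_pulse():
    """A 100-ms unit pulse inside the 10-s window contributes 0.01."""
    tr = DopamineTrace()
    for i in range(10_000):
        update_dopamine_baseline(tr, 1.0 if i < 100 else 0.0, 1.0)
    assert tr.b_D == pytest.approx(0.01)


def test_dopamine_baseline_matches_naive_windowed_mean():
    rng = np.random.default_rng(42)
    series = rng.normal(size=25_000)
    tr = DopamineTrace(window_ms=10_000.0)
    for i, d in enumerate(series):
        update_dopamine_baseline(tr, d, 1.0)
        lo = max(0, i + 1 - 10_000)
        assert tr.b_D == pytest.approx(series[lo : i + 1].mean(), abs=1e-12)
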