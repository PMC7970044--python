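"""Readout and spike-train analyses.

Decisions are taken as the argmax of exponentially filtered output activity;
task accuracy for the logic tasks uses an ordinary-least-squares linear
readout with a 0.5 threshold; population statistics cover the CV of
inter-spike intervals, firing rates, cluster specificity of the output
projections, per-cluster receptive fields, state reconstruction from
receptive-field input spikes, and windowed performance curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ConfigurationError, SpikeRecord
from .tasks import RFEncoder

__all__ = [
    "filtered_activity",
    "filtered_traces",
    "decide",
    "fit_eval_linear_readout",
    "cv_isi",
    "cluster_specificity",
    "receptive_field",
    "reconstruct_state",
    "performance_curve",
    "export_receptive_fields",
]


def filtered_activity(
    spikes: SpikeRecord, n_units: int, t_eval: float, tau: float
) -> np.ndarray:
    """Exponentially filtered spike count per unit, evaluated at t_eval.

    activity_u = sum over spikes of unit u before t_eval of exp(-(t_eval-t)/tau).
    """
    m = spikes.time_ms <= t_eval
    w = np.exp(-(t_eval - spikes.time_ms[m]) / tau)
    act = np.zeros(n_units)
    np.add.at(act, spikes.unit[m], w)
    return act


def filtered_traces(
    spikes: SpikeRecord,
    n_units: int,
    t0: float,
    t1: float,
    tau: float,
    bin_ms: float = 1.0,
) -> np.ndarray:
    """Low-pass filtered activity of every unit on a regular grid.

    Spikes are convolved with a unit-area exponential kernel (tau in ms) and
    sampled every bin_ms; returns an (n_bins, n_units) array in spikes/s.
    This is the representation handed to the linear readout (1000 Hz
    sampling at the default bin width).
    """
    n_bins = int(round((t1 - t0) / bin_ms))
    decay = np.exp(-bin_ms / tau)
    incr = 1000.0 / tau
    win = spikes.window(t0, t1)
    order = np.argsort(win.time_ms, kind="stable")
    times = win.time_ms[order]
    units = win.unit[order]
    act = np.zeros(n_units)
    out = np.empty((n_bins, n_units))
    ptr = 0
    for b in range(n_bins):
        t_end = t0 + (b + 1) * bin_ms
        act *= decay
        while ptr < times.size and times[ptr] < t_end:
            act[units[ptr]] += incr
            ptr += 1
        out[b] = act
    return out


def decide(
    spikes: SpikeRecord,
    n_outputs: int,
    window: tuple[float, float],
    tau_dec: float = 50.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Winner among output neurons at the end of a decision window.

    Output spikes within the window are filtered with an exponential kernel
    of time constant tau_dec (ms) and the most active neuron wins; exact
    ties (including an all-silent window) are broken uniformly at random
    with the experiment's seeded generator.
    """
    if n_outputs < 1:
        raise ConfigurationError("empty output population")
    t0, t1 = window
    act = filtered_activity(spikes.window(t0, t1 + 1e-9), n_outputs, t1, tau_dec)
    winners = np.flatnonzero(act == act.max())
    if winners.size == 1:
        return int(winners[0])
    if rng is None:
        rng = np.random.default_rng(0)
    return int(rng.choice(winners))


def fit_eval_linear_readout(
    traces: np.ndarray, targets: np.ndarray, threshold: float = 0.5
) -> float:
    """Accuracy of an ordinary-least-squares readout of a binary target.

    traces: (n_samples, n_neurons) filtered activity sampled at 1000 Hz;
    targets: the 0/1 target bit per sample.  The regressor is fit by least
    squares (pseudo-inverse under rank deficiency) and a prediction counts
    as correct when it falls on the target's side of the threshold.
    """
    from sklearn.linear_model import LinearRegression

    traces = np.asarray(traces, float)
    targets = np.asarray(targets, float)
    if traces.ndim != 2 or traces.shape[0] != targets.shape[0]:
        raise ValueError("traces must be (n_samples, n_neurons) aligned with targets")
    classes = np.unique(targets)
    if classes.size < 2:
        raise ValueError("need at least one sample per class")
    model = LinearRegression().fit(traces, targets)
    pred = model.predict(traces) >= threshold
    return float(np.mean(pred == (targets >= threshold)))


def cv_isi(
    spikes: SpikeRecord, units: np.ndarray, min_spikes: int = 3
) -> tuple[float, int]:
    """Mean coefficient of variation of inter-spike intervals.

    Per-neuron CV = sd(ISI)/mean(ISI); neurons with fewer than
    ``min_spikes`` spikes are excluded (and counted).  Returns
    (population mean CV, number of excluded neurons).  Raises if no neuron
    qualifies.
    """
    cvs = []
    excluded = 0
    for u in np.asarray(units):
        t = spikes.spike_times(int(u))
        if t.size < min_spikes:
            excluded += 1
            continue
        isi = np.diff(t)
        m = isi.mean()
        cvs.append(isi.std(ddof=1) / m if m > 0 else 0.0)
    if not cvs:
        raise ValueError("no neuron has enough spikes for an ISI CV")
    return float(np.mean(cvs)), excluded


def cluster_specificity(
    W_out: np.ndarray, cluster_of_pre: np.ndarray
) -> np.ndarray:
    """Sharpness of each cluster's output projection.

    W_out: (n_pre, n_out) mean non-negative output weights per presynaptic
    neuron; S_c = max_o(mean weight to o from cluster c) / sum_o(mean weight
    to o from cluster c), in [1/n_out, 1].  Clusters whose outgoing weights
    are all zero yield NaN.
    """
    W_out = np.asarray(W_out, float)
    if np.any(W_out < 0):
        raise ValueError("output weights must be non-negative")
    clusters = np.unique(cluster_of_pre)
    S = np.full(clusters.size, np.nan)
    for i, c in enumerate(clusters):
        Wbar = W_out[cluster_of_pre == c].mean(axis=0)
        tot = Wbar.sum()
        if tot > 0:
            S[i] = Wbar.max() / tot
    return S


def receptive_field(
    W_in: np.ndarray, cluster_of_post: np.ndarray, shape: tuple[int, int] = (28, 28)
) -> np.ndarray:
    """Per-cluster mean input-weight map.

    W_in: (n_inputs, n_post) input weights with the input layer image-shaped;
    returns (n_clusters, *shape) maps, the stimulus feature each cluster has
    specialized for.
    """
    W_in = np.asarray(W_in, float)
    if W_in.shape[0] != shape[0] * shape[1]:
        raise ValueError("input layer size does not match the image shape")
    clusters = np.unique(cluster_of_post)
    maps = np.empty((clusters.size, *shape))
    for i, c in enumerate(clusters):
        maps[i] = W_in[:, cluster_of_post == c].mean(axis=1).reshape(shape)
    return maps


def reconstruct_state(
    spikes: SpikeRecord,
    encoder: RFEncoder,
    t0: float,
    t1: float,
    tau: float = 30.0,
    bin_ms: float = 1.0,
) -> pd.DataFrame:
    """Decode position/velocity from receptive-field input spikes.

    Input spikes (units 0..N-1 position array, N..2N-1 velocity array) are
    filtered with an exponential kernel (tau ms) on a 1-ms grid; the center
    of the most active neuron per array is the estimate.  Bins where an
    array is entirely silent carry the previous estimate forward.
    """
    n = encoder.n_per_dim
    centers = encoder.centers
    n_bins = int(round((t1 - t0) / bin_ms))
    decay = np.exp(-bin_ms / tau)
    act = np.zeros(2 * n)
    out = np.full((n_bins, 2), np.nan)
    win = spikes.window(t0, t1)
    order = np.argsort(win.time_ms, kind="stable")
    times = win.time_ms[order]
    units = win.unit[order]
    ptr = 0
    x_hat = v_hat = np.nan
    for b in range(n_bins):
        t_end = t0 + (b + 1) * bin_ms
        act *= decay
        while ptr < times.size and times[ptr] < t_end:
            act[units[ptr]] += 1.0
            ptr += 1
        if act[:n].max() > 0:
            x_hat = centers[int(np.argmax(act[:n]))]
        if act[n:].max() > 0:
            v_hat = centers[int(np.argmax(act[n:]))]
        out[b, 0] = x_hat
        out[b, 1] = v_hat
    return pd.DataFrame(
        {"time_ms": t0 + (np.arange(n_bins) + 1) * bin_ms, "x_hat": out[:, 0], "v_hat": out[:, 1]}
    )


def export_receptive_fields(maps: np.ndarray, basename) -> None:
    """Write per-cluster receptive-field maps as CSV matrices and a PNG grid.

    The PNG requires matplotlib (optional); the CSVs are always written.
    """
    maps = np.asarray(maps)
    for i, m in enumerate(maps):
        pd.DataFrame(m).to_csv(f"{basename}_cluster{i}.csv", index=False,
                               header=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    n = maps.shape[0]
    cols = min(n, 4)
    rows = -(-n // cols)
    fig, axes = plt.subplots(rows, cols, figsize=(2.2 * cols, 2.2 * rows))
    for i, ax in enumerate(np.atleast_1d(axes).ravel()):
        if i < n:
            ax.imshow(maps[i], cmap="viridis")
            ax.set_title(f"cluster {i}", fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(f"{basename}.png", dpi=120)
    plt.close(fig)


def performance_curve(outcomes, mode: str = "sliding_mean_30") -> np.ndarray:
    """Windowed performance statistic over trials.

    'sliding_mean_30': sliding average of correct/incorrect over 30 trials
    (classification); 'running_median_10': running median of steps-to-goal
    over 10 trials (control).  Returns one value per full window.
    """
    outcomes = np.asarray(outcomes, float)
    if mode == "sliding_mean_30":
        window, stat = 30, "mean"
    elif mode == "running_median_10":
        window, stat = 10, "median"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if outcomes.size < window:
        raise ValueError(f"need at least {window} trials")
    roll = pd.Series(outcomes).rolling(window)
    series = roll.mean() if stat == "mean" else roll.median()
    return series.to_numpy()[window - 1 :]
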