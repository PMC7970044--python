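"""Rate-based plasticity: Hebbian learning with quadratic synaptic scaling,
and its dopamine-modulated three-factor extension.

Both rules operate on exponentially filtered firing rates rather than spike
pairs.  The unmodulated rule is

    dw = mu * ( F_i * F_j  +  kappa * (F_T - F_j) * w**2 )

where F_i, F_j are pre-/post-synaptic filtered rates (spikes/s), F_T is the
homeostatic set point (the target post-synaptic rate) and kappa sets the
strength of the quadratic-weight scaling term relative to the Hebbian term.
With clamped rates F_j > F_T the rule has a stable fixed point at
``w* = sqrt(F_i F_j / (kappa (F_j - F_T)))``.

The three-factor form multiplies the Hebbian term by the deviation of the
dopamine concentration D from its baseline b_D (a trailing 10-s average):

    dw = mu * ( (D - b_D) * F_i * F_j  +  kappa * (F_T - F_j) * w**2 )

so coincident pre/post activity potentiates under above-baseline dopamine
and depresses under below-baseline dopamine, while the homeostatic term is
unmodulated.  Setting D = b_D + 1 recovers the unmodulated rule exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateTrace",
    "TetzlaffParams",
    "DopamineTrace",
    "update_rate_trace",
    "tetzlaff_update",
    "three_factor_update",
    "update_dopamine_baseline",
]


@dataclass
class RateTrace:
    """Exponentially filtered firing-rate estimate per neuron.

    The kernel has unit area (each spike adds 1000/tau_F with tau_F in ms
    and decays with tau_F), so F is an unbiased rate estimate in spikes/s.
    """

    F: np.ndarray
    tau_F: float = 100.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.tau_F <= 0:
            raise ValueError("tau_F must be positive")


def update_rate_trace(trace: RateTrace, spikes, dt: float) -> RateTrace:
    """Advance the trace by one step of dt ms given per-neuron spike indicators."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    F = trace.F * np.exp(-dt / trace.tau_F) + (1000.0 / trace.tau_F) * np.asarray(
        spikes, dtype=float
    )
    return RateTrace(F, trace.tau_F)


@dataclass(frozen=True)
class TetzlaffParams:
    """Parameters of the Hebbian/synaptic-scaling rule.

    mu : learning rate per update (dimensionless)
    kappa : ratio of synaptic scaling to Hebbian modification
    F_T : homeostatic target rate (spikes/s)
    w_min, w_max : hard weight bounds applied after each update (pA)
    update_interval : time between rule applications (ms)
    """

    mu: float = 1e-5
    kappa: float = 0.5
    F_T: float = 10.0
    w_min: float = 0.0
    w_max: float = 1e4
    update_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.kappa < 0 or self.F_T <= 0:
            raise ValueError("require mu > 0, kappa >= 0, F_T > 0")
        if self.w_min < 0 or self.w_max <= self.w_min:
            raise ValueError("require 0 <= w_min < w_max")

    def fixed_point(self, F_i: float, F_j: float) -> float:
        """Stable weight fixed point for clamped rates with F_j > F_T."""
        if F_j <= self.F_T:
            raise ValueError("fixed point requires F_j > F_T")
        return float(np.sqrt(F_i * F_j / (self.kappa * (F_j - self.F_T))))


def tetzlaff_update(w, F_i, F_j, params: TetzlaffParams):
    """Weight increment of the unmodulated Hebbian/scaling rule.

    Returns dw; the caller is responsible for clipping w + dw to
    [w_min, w_max] (as done by :func:`apply_update`).
    """
    w = np.asarray(w, dtype=float)
    return params.mu * (
        np.asarray(F_i, float) * np.asarray(F_j, float)
        + params.kappa * (params.F_T - F_j) * w**2
    )


def three_factor_update(w, F_i, F_j, D, b_D, params: TetzlaffParams):
    """Weight increment of the dopamine-gated three-factor rule."""
    w = np.asarray(w, dtype=float)
    return params.mu * (
        (D - b_D) * np.asarray(F_i, float) * np.asarray(F_j, float)
        + params.kappa * (params.F_T - F_j) * w**2
    )


def apply_update(w, dw, params: TetzlaffParams) -> np.ndarray:
    """Clip w + dw to the rule's weight bounds."""
    return np.clip(np.asarray(w, float) + dw, params.w_min, params.w_max)


@dataclass
class DopamineTrace:
    """Dopamine concentration D with its trailing-window baseline b_D.

    b_D is the boxcar mean of D over the trailing ``window_ms`` (default
    10 s), maintained with a ring buffer of samples taken every
    ``sample_interval`` ms.  Before the window has filled, the mean runs
    over the available samples.
    """

    window_ms: float = 10_000.0
    sample_interval: float = 1.0
    D: float = 0.0
    _ring: np.ndarray = field(default=None, repr=False)
    _pos: int = 0
    _count: int = 0
    _sum: float = 0.0

    def __post_init__(self) -> None:
        n = int(round(self.window_ms / self.sample_interval))
        if n < 1:
            raise ValueError("window must cover at least one sample")
        if self._ring is None:
            self._ring = np.zeros(n)

    @property
    def b_D(self) -> float:
        return self._sum / self._count if self._count else self.D

    def push(self, D_t: float) -> None:
        if self._count < self._ring.size:
            self._sum += D_t
            self._count += 1
        else:
            self._sum += D_t - self._ring[self._pos]
        self._ring[self._pos] = D_t
        self._pos = (self._pos + 1) % self._ring.size
        self.D = float(D_t)


def update_dopamine_baseline(trace: DopamineTrace, D_t: float, dt: float) -> DopamineTrace:
    """Advance the baseline by one sample of duration dt ms (dt must equal
    the trace's sample interval)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if abs(dt - trace.sample_interval) > 1e-12:
        raise ValueError("dt must match the trace's sample interval")
    trace.push(D_t)
    return trace
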