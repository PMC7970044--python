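"""Stimulus encoders and task environments.

Three tasks exercise the architecture: (i) logic gates on two rate-coded
binary inputs, (ii) 3-class digit classification on 28x28 grayscale images
(a built-in synthetic generator emulates intra-class style variants, so no
dataset download is needed; MNIST IDX files can be loaded when available),
and (iii) a self-contained Mountain Car environment with Gaussian
receptive-field population coding of position and velocity.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOGIC_TRUTH_TABLE",
    "LogicPattern",
    "logic_pattern_rates",
    "encode_image",
    "generate_synthetic_digits",
    "load_idx_images",
    "load_idx_labels",
    "CarState",
    "MountainCar",
    "RFEncoder",
    "rf_encode",
]

# truth table rows keyed by (A, B)
LOGIC_TRUTH_TABLE = {
    (0, 0): {"OR": 0, "AND": 0, "XOR": 0, "IMPL": 1},
    (0, 1): {"OR": 1, "AND": 0, "XOR": 1, "IMPL": 1},
    (1, 0): {"OR": 1, "AND": 0, "XOR": 1, "IMPL": 0},
    (1, 1): {"OR": 1, "AND": 1, "XOR": 0, "IMPL": 1},
}
LOGIC_PATTERN_ORDER = [(0, 0), (0, 1), (1, 0), (1, 1)]
GATES = ("OR", "AND", "XOR", "IMPL")


@dataclass(frozen=True)
class LogicPattern:
    """Rate coding of the two binary stimulation neurons.

    'on' inputs fire at 1000 spikes/s, 'off' inputs at 10 spikes/s; each
    (A, B) combination is presented for 500 ms and the four combinations
    cycle for the whole simulation (period 2000 ms).
    """

    on_rate: float = 1000.0
    off_rate: float = 10.0
    period_ms: float = 500.0


def logic_pattern_rates(
    t_ms: float, pattern: LogicPattern = LogicPattern()
) -> tuple[tuple[float, float], dict[str, int], tuple[int, int]]:
    """Input rates and per-gate targets at time t.

    Returns ((rate_A, rate_B), {gate: target bit}, (A, B)).
    """
    if t_ms < 0:
        raise ValueError("t must be non-negative")
    idx = int(t_ms // pattern.period_ms) % 4
    a, b = LOGIC_PATTERN_ORDER[idx]
    rates = (
        pattern.on_rate if a else pattern.off_rate,
        pattern.on_rate if b else pattern.off_rate,
    )
    return rates, dict(LOGIC_TRUTH_TABLE[(a, b)]), (a, b)


def encode_image(pixels, F_max: float = 60.0) -> np.ndarray:
    """Rate coding of a grayscale image: rate_i = F_max * g_i / 255.

    One input neuron per pixel; intensities must lie in [0, 255].
    """
    g = np.asarray(pixels, dtype=float).ravel()
    if np.any(g < 0) or np.any(g > 255):
        raise ValueError("pixel intensities must lie in [0, 255]")
    return F_max * g / 255.0


# --------------------------------------------------------------------------
# synthetic 3-class digit generator
# --------------------------------------------------------------------------


def _render_strokes(points: np.ndarray, size: int = 28, width: float = 1.3) -> np.ndarray:
    """Rasterize a polyline (n, 2) in unit coordinates to a [0, 1] image."""
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    # dense resampling of the polyline
    seg = np.diff(points, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    n_samp = np.maximum((lens * size * 3).astype(int), 2)
    for i in range(seg.shape[0]):
        ts = np.linspace(0, 1, n_samp[i])
        pts = points[i] + ts[:, None] * seg[i]
        for px, py in pts:
            d2 = (xx - px * (size - 1)) ** 2 + (yy - py * (size - 1)) ** 2
            img = np.maximum(img, np.exp(-d2 / (2 * width**2)))
    return img


def _digit_zero(rng: np.random.Generator, style: int) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, 40)
    rx = 0.26 if style == 0 else 0.18  # round vs oval
    ry = 0.30
    tilt = 0.0 if style == 0 else rng.uniform(0.25, 0.5)
    cx, cy = 0.5 + rng.normal(0, 0.02), 0.5 + rng.normal(0, 0.02)
    x = rx * np.cos(th)
    y = ry * np.sin(th)
    xr = x * np.cos(tilt) - y * np.sin(tilt) + cx
    yr = x * np.sin(tilt) + y * np.cos(tilt) + cy
    return _render_strokes(np.column_stack([xr, yr]))


def _digit_one(rng: np.random.Generator, style: int) -> np.ndarray:
    slant = 0.0 if style == 0 else rng.uniform(0.12, 0.22)  # straight vs tilted
    x0 = 0.5 + rng.normal(0, 0.02)
    pts = np.array(
        [[x0 - slant, 0.18], [x0 + slant, 0.82]]
    )
    if rng.random() < 0.7:  # serif flag
        pts = np.vstack([[x0 - slant - 0.12, 0.30], pts])
    return _render_strokes(pts)


def _digit_two(rng: np.random.Generator, style: int) -> np.ndarray:
    jx = rng.normal(0, 0.02)
    top = [
        [0.28 + jx, 0.70],
        [0.32 + jx, 0.80],
        [0.50 + jx, 0.84],
        [0.68 + jx, 0.78],
        [0.70 + jx, 0.62],
    ]
    diag = [[0.42 + jx, 0.42], [0.28 + jx, 0.26]]
    if style == 1:  # looped "2": small loop at the diagonal's base
        diag += [[0.40 + jx, 0.20], [0.34 + jx, 0.32], [0.30 + jx, 0.24]]
    base = [[0.30 + jx, 0.22], [0.72 + jx, 0.22]]
    return _render_strokes(np.array(top + diag + base))


_DIGIT_RENDERERS = (_digit_zero, _digit_one, _digit_two)


def generate_synthetic_digits(
    n: int, rng: np.random.Generator, noise: float = 0.3, total_intensity: float = 70.0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 28x28 grayscale digits for classes {0, 1, 2}.

    Each class has two sub-styles (round vs oval/tilted zero, straight vs
    tilted one, looped vs unlooped two) rendered from parametric strokes
    with positional jitter plus pixel noise, emulating the intra-class
    style variance of handwritten digits.  Images are contrast-normalized
    to a common summed intensity (``total_intensity`` in units of fully-lit
    pixels) so that classes differ in shape rather than overall brightness.
    Deterministic given the generator state.  Returns (images in [0, 255]
    of shape (n, 28, 28), labels of shape (n,)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from scipy import ndimage

    images = np.empty((n, 28, 28))
    labels = rng.integers(0, 3, size=n)
    for i in range(n):
        style = int(rng.random() < 0.5)
        img = _DIGIT_RENDERERS[labels[i]](rng, style)
        # writer variability: small random rotation, scale and translation
        angle = rng.uniform(-25.0, 25.0)
        zoom = rng.uniform(0.7, 1.3)
        img = ndimage.rotate(img, angle, reshape=False, order=1)
        img = ndimage.zoom(img, zoom, order=1)
        if img.shape[0] >= 28:
            o = (img.shape[0] - 28) // 2
            img = img[o : o + 28, o : o + 28]
        else:
            pad = 28 - img.shape[0]
            img = np.pad(img, ((pad // 2, pad - pad // 2),) * 2)
        img = ndimage.shift(img, rng.uniform(-3, 3, size=2), order=1)
        img = np.clip(img + rng.normal(0, noise, img.shape), 0, 1)
        if total_intensity is not None and img.sum() > 0:
            img = np.clip(img * (total_intensity / img.sum()), 0, 1)
        # vertical flip so row 0 is the image top
        images[i] = img[::-1] * 255.0
    return images, labels.astype(np.int64)


def load_idx_images(path) -> np.ndarray:
    """Read an IDX3 image file (the MNIST container format)."""
    with open(path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">IIII", fh.read(16))
        if magic != 2051:
            raise ValueError(f"not an IDX3 image file (magic {magic})")
        data = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    return data.reshape(n, rows, cols).astype(float)


def load_idx_labels(path) -> np.ndarray:
    """Read an IDX1 label file."""
    with open(path, "rb") as fh:
        magic, n = struct.unpack(">II", fh.read(8))
        if magic != 2049:
            raise ValueError(f"not an IDX1 label file (magic {magic})")
        return np.frombuffer(fh.read(n), dtype=np.uint8).astype(np.int64)


# --------------------------------------------------------------------------
# Mountain Car
# --------------------------------------------------------------------------


@dataclass
class CarState:
    """Raw position/velocity of the car (un-normalized units)."""

    x: float
    v: float


@dataclass
class MountainCar:
    """Deterministic Mountain Car dynamics with discrete actions.

    Physics follow the de-facto standard environment: actions 'left' (0),
    'nothing' (1), 'right' (2) change the velocity by +-force, gravity adds
    -gravity*cos(3x), position integrates velocity, the left wall is
    inelastic and the goal sits at x >= goal_x.  The time limit is removed;
    an episode ends only at the goal.  Reward is -1 per step with +1 added
    on reaching the goal.
    """

    force: float = 0.001
    gravity: float = 0.0025
    x_min: float = -1.2
    x_max: float = 0.6
    v_max: float = 0.07
    goal_x: float = 0.5
    start_low: float = -0.6
    start_high: float = -0.4
    state: CarState = field(default_factory=lambda: CarState(-0.5, 0.0))

    ACTIONS = ("left", "nothing", "right")

    def reset(self, rng: np.random.Generator) -> CarState:
        self.state = CarState(float(rng.uniform(self.start_low, self.start_high)), 0.0)
        return self.state

    def step(self, action: int) -> tuple[CarState, float, bool]:
        if action not in (0, 1, 2):
            raise ValueError("action must be 0 (left), 1 (nothing) or 2 (right)")
        s = self.state
        v = s.v + (action - 1) * self.force - self.gravity * np.cos(3 * s.x)
        v = float(np.clip(v, -self.v_max, self.v_max))
        x = float(np.clip(s.x + v, self.x_min, self.x_max))
        if x <= self.x_min:
            v = 0.0  # inelastic left wall
        self.state = CarState(x, v)
        done = x >= self.goal_x
        reward = -1.0 + (1.0 if done else 0.0)
        return self.state, reward, done

    def normalized(self) -> tuple[float, float]:
        """Map (x, v) to [-1, 1] for the receptive-field encoder."""
        x01 = (self.state.x - self.x_min) / (self.x_max - self.x_min)
        v01 = (self.state.v + self.v_max) / (2 * self.v_max)
        return 2 * x01 - 1, 2 * v01 - 1

    def height(self, x: float) -> float:
        """Hill profile implied by the gravity term (potential ~ sin(3x)/3)."""
        return np.sin(3 * x) / 3.0


@dataclass(frozen=True)
class RFEncoder:
    """Gaussian receptive fields tiling each normalized input dimension.

    N neurons per dimension with centers mu_i = -1 + 2i/N, width sigma and
    peak rate 35 spikes/s: rate_i = peak * exp(-(z - mu_i)^2 / (2 sigma^2)).
    """

    n_per_dim: int = 200
    sigma: float = 0.05
    peak_rate: float = 35.0

    @property
    def centers(self) -> np.ndarray:
        return -1.0 + 2.0 * np.arange(self.n_per_dim) / self.n_per_dim

    def encode_1d(self, z: float) -> np.ndarray:
        if not -1.0 <= z <= 1.0:
            warnings.warn("input outside [-1, 1]; clipping", stacklevel=2)
            z = float(np.clip(z, -1, 1))
        return self.peak_rate * np.exp(
            -((z - self.centers) ** 2) / (2 * self.sigma**2)
        )


def rf_encode(
    x_norm: float, v_norm: float, encoder: RFEncoder = RFEncoder()
) -> np.ndarray:
    """Rates of the 2*N input neurons for normalized position and velocity."""
    return np.concatenate([encoder.encode_1d(x_norm), encoder.encode_1d(v_norm)])
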