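"""Synthetic lensless calcium-imaging datasets with known ground truth.

The simulator emulates recordings from a bare (lensless) CMOS sensor
implanted in tissue: a small number of neurons act as point sources of
light at known (x, y) positions and depths above the 120 x 40 pixel
imaging area.  Because there are no focusing optics, each source spreads
over many pixels; the footprint widens and the peak dims as the source
moves away from the sensor.

The temporal design mirrors a stimulation experiment: a pre-stimulation
segment in which every neuron fires spontaneously (10% chance per
frame), followed by a post-stimulation segment in which each neuron is
randomly assigned one of three activity patterns:

* ``pattern1`` -- high activity for the first sixth of the window,
  medium for the next two sixths, low for the rest.
* ``pattern2`` -- the high-activity block is shifted to the second
  sixth; medium before and after, low for the final third.
* ``unresponsive`` -- spontaneous statistics continue unchanged.

Activity levels are event processes: high is 10 Hz with a 25% chance
that an event is a burst of 2-5 spikes, medium is 10 Hz with a 1-in-15
burst chance, low is 5 Hz with a 1-in-20 burst chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import oaconvolve

from .stack import FrameStack

logger = logging.getLogger(__name__)

PATTERN1 = "pattern1"
PATTERN2 = "pattern2"
UNRESPONSIVE = "unresponsive"
PATTERNS = (PATTERN1, PATTERN2, UNRESPONSIVE)


@dataclass(frozen=True)
class ActivityLevel:
    """Event statistics of one firing regime.

    ``rate_hz`` is the expected number of firing events per second; an
    event becomes a burst with probability ``burst_prob``, contributing
    a uniformly drawn integer number of spikes from
    ``burst_size_range`` (inclusive), otherwise a single spike.
    """

    rate_hz: float
    burst_prob: float
    burst_size_range: tuple[int, int] = (2, 5)

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be >= 0")
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must be in [0, 1]")
        lo, hi = self.burst_size_range
        if not (1 <= lo <= hi):
            raise ValueError("burst_size_range must satisfy 1 <= lo <= hi")

    @property
    def spikes_per_event(self) -> float:
        """Expected spikes contributed by one event."""
        lo, hi = self.burst_size_range
        return (1 - self.burst_prob) + self.burst_prob * (lo + hi) / 2.0


def default_activity_levels() -> dict[str, ActivityLevel]:
    return {
        "high": ActivityLevel(10.0, 0.25, (2, 5)),
        "medium": ActivityLevel(10.0, 1.0 / 15.0, (2, 5)),
        "low": ActivityLevel(5.0, 0.05, (2, 5)),
    }


# Activity schedules per pattern, as (level, end_fraction) blocks over the
# post-stimulation window.  Fractions refer to the default 60-minute
# window (10 min = 1/6) and scale with n_post_frames so that reduced
# simulations keep all phases.
PATTERN_SCHEDULES: dict[str, tuple[tuple[str, float], ...]] = {
    PATTERN1: (("high", 1 / 6), ("medium", 3 / 6), ("low", 1.0)),
    PATTERN2: (("medium", 1 / 6), ("high", 2 / 6), ("medium", 4 / 6), ("low", 1.0)),
}


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic dataset.

    Defaults reproduce the reference design: a 120 x 40 px field of
    view at 10 fps, 9,000 pre- plus 36,000 post-stimulation frames,
    30 neurons with centers drawn uniformly from x in [5, 35],
    y in [5, 115] (a 5 px border is excluded because the device edge is
    noisy) and depths z in [4, 8] px, i.e. 30-60 um at 7.5 um/px.
    """

    height_px: int = 120
    width_px: int = 40
    fps: float = 10.0
    n_pre_frames: int = 9000
    n_post_frames: int = 36000
    n_neurons: int = 30
    x_range: tuple[int, int] = (5, 35)
    y_range: tuple[int, int] = (5, 115)
    z_range_px: tuple[int, int] = (4, 8)
    pixel_pitch_um: float = 7.5
    spontaneous_fire_prob: float = 0.10
    pattern_params: dict[str, ActivityLevel] = field(
        default_factory=default_activity_levels
    )
    decay_tau_s: float = 1.0
    amp_per_spike: float = 60.0
    baseline_offset: float = 100.0
    noise_sd: float = 1.0
    spatial_noise_sd: float = 1.0
    spatial_noise_scale_px: float = 2.0
    spatial_noise_tau_s: float = 30.0
    shared_noise_sd: float = 2.0
    shared_noise_tau_s: float = 10.0
    gradient_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre_frames <= 0 or self.n_post_frames <= 0:
            raise ValueError("frame counts must be > 0")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        if not 0.0 <= self.spontaneous_fire_prob <= 1.0:
            raise ValueError("spontaneous_fire_prob must be in [0, 1]")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        x0, x1 = self.x_range
        y0, y1 = self.y_range
        z0, z1 = self.z_range_px
        if not (0 <= x0 <= x1 < self.width_px):
            raise ValueError(f"x_range {self.x_range} outside frame width")
        if not (0 <= y0 <= y1 < self.height_px):
            raise ValueError(f"y_range {self.y_range} outside frame height")
        if not (0 < z0 <= z1):
            raise ValueError(f"z_range_px {self.z_range_px} must be positive")
        for name in ("high", "medium", "low"):
            if name not in self.pattern_params:
                raise ValueError(f"pattern_params missing level {name!r}")

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_post_frames

    @property
    def z_range_um(self) -> tuple[float, float]:
        return (
            self.z_range_px[0] * self.pixel_pitch_um,
            self.z_range_px[1] * self.pixel_pitch_um,
        )


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth position and activity pattern of one neuron.

    Coordinates are 0-based integer pixels, origin at the top-left of
    the frame; ``x_px`` indexes columns (short axis), ``y_px`` rows
    (long axis).  ``z_px`` is the distance from the sensor plane in
    pixel units.
    """

    x_px: int
    y_px: int
    z_px: int
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class SimulatedDataset:
    """Frames plus the full ground truth they were rendered from."""

    frames: FrameStack
    neurons: list[NeuronSpec]
    spikes: np.ndarray  # n_neurons x n_frames nonnegative int spike counts
    config: SimulationConfig
    seed: int


def sample_neurons(
    config: SimulationConfig, rng: np.random.Generator
) -> list[NeuronSpec]:
    """Draw neuron positions, depths and post-stimulation patterns.

    Positions are uniform over the configured inclusive ranges; the
    activity pattern is uniform over the three patterns.
    """
    x0, x1 = config.x_range
    y0, y1 = config.y_range
    z0, z1 = config.z_range_px
    neurons = []
    for _ in range(config.n_neurons):
        x = int(rng.integers(x0, x1 + 1))
        y = int(rng.integers(y0, y1 + 1))
        z = int(rng.integers(z0, z1 + 1))
        pattern = PATTERNS[rng.integers(0, len(PATTERNS))]
        neurons.append(NeuronSpec(x, y, z, pattern))
    return neurons


def _schedule_blocks(pattern: str, n_post: int) -> list[tuple[str, int, int]]:
    """Frame extents [start, stop) of each activity block of a pattern."""
    blocks = []
    start = 0
    for level, end_frac in PATTERN_SCHEDULES[pattern]:
        stop = int(round(end_frac * n_post))
        blocks.append((level, start, stop))
        start = stop
    if start != n_post:
        raise ValueError("activity schedule does not cover the post window")
    return blocks


def _event_spikes(
    n_frames: int, level: ActivityLevel, fps: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike counts per frame for one activity level.

    Events per frame are Poisson(rate_hz / fps); each event is expanded
    to a burst with probability burst_prob.
    """
    events = rng.poisson(level.rate_hz / fps, size=n_frames)
    bursts = rng.binomial(events, level.burst_prob)
    singles = events - bursts
    spikes = singles.astype(np.int64)
    total_bursts = int(bursts.sum())
    if total_bursts:
        lo, hi = level.burst_size_range
        draws = rng.integers(lo, hi + 1, size=total_bursts)
        frame_idx = np.repeat(np.arange(n_frames), bursts)
        spikes += np.bincount(
            frame_idx, weights=draws, minlength=n_frames
        ).astype(np.int64)
    return spikes


def generate_spike_trains(
    neurons: list[NeuronSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-neuron, per-frame spike counts (n_neurons x n_frames).

    Pre-stimulation frames are independent Bernoulli single spikes at
    ``spontaneous_fire_prob`` for every neuron.  Post-stimulation frames
    follow each neuron's pattern schedule; unresponsive neurons keep the
    spontaneous statistics.
    """
    n_pre, n_post = config.n_pre_frames, config.n_post_frames
    spikes = np.zeros((len(neurons), n_pre + n_post), dtype=np.int64)
    for i, neuron in enumerate(neurons):
        spikes[i, :n_pre] = (
            rng.random(n_pre) < config.spontaneous_fire_prob
        ).astype(np.int64)
        if neuron.pattern == UNRESPONSIVE:
            spikes[i, n_pre:] = (
                rng.random(n_post) < config.spontaneous_fire_prob
            ).astype(np.int64)
        else:
            for level_name, start, stop in _schedule_blocks(neuron.pattern, n_post):
                level = config.pattern_params[level_name]
                spikes[i, n_pre + start: n_pre + stop] = _event_spikes(
                    stop - start, level, config.fps, rng
                )
    return spikes


def calcium_kernel(decay_tau_s: float, fps: float) -> np.ndarray:
    """Causal transient kernel: instantaneous rise, exponential decay.

    Truncated at 5 decay constants.
    """
    n = int(np.ceil(5.0 * decay_tau_s * fps)) + 1
    return np.exp(-np.arange(n) / (decay_tau_s * fps)).astype(np.float32)


def point_source_footprint(
    x_px: int, y_px: int, z_px: float, height_px: int, width_px: int
) -> tuple[slice, slice, np.ndarray]:
    """Sensor-plane irradiance pattern of a unit point source.

    A source at lateral offset d (pixels) and depth z above a planar
    detector illuminates a pixel in proportion to z / (d^2 + z^2)^(3/2)
    (inverse-square falloff with obliquity), truncated at radius 4 z.
    Returns row slice, column slice and the weight patch.
    """
    radius = int(np.ceil(4.0 * z_px))
    r0 = max(0, y_px - radius)
    r1 = min(height_px, y_px + radius + 1)
    c0 = max(0, x_px - radius)
    c1 = min(width_px, x_px + radius + 1)
    rows = np.arange(r0, r1)[:, None] - y_px
    cols = np.arange(c0, c1)[None, :] - x_px
    d2 = rows.astype(np.float64) ** 2 + cols.astype(np.float64) ** 2
    w = z_px / (d2 + z_px**2) ** 1.5
    w[d2 > (4.0 * z_px) ** 2] = 0.0
    return slice(r0, r1), slice(c0, c1), w.astype(np.float32)


def _shared_background(
    n_frames: int, sd: float, tau_s: float, fps: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) stray-light fluctuation common to all pixels."""
    a = float(np.exp(-1.0 / (tau_s * fps))) if tau_s > 0 else 0.0
    innovations = rng.standard_normal(n_frames).astype(np.float32)
    from scipy.signal import lfilter

    x = lfilter([np.sqrt(1.0 - a**2)], [1.0, -a], innovations).astype(np.float32)
    return sd * x


def _spatial_noise(
    shape: tuple[int, int, int],
    sd: float,
    scale_px: float,
    tau_s: float,
    fps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slowly drifting spatially correlated noise (stray-light speckle).

    White noise smoothed with a Gaussian of standard deviation
    ``scale_px`` in the image plane and filtered to an AR(1) process
    with time constant ``tau_s`` along frames, rescaled so the field's
    marginal standard deviation is ``sd``.  Because the speckle drifts
    slowly it does not average out over frames, mimicking the
    persistent non-stationary stray-light structure of a real device.
    """
    from scipy.ndimage import gaussian_filter

    field = rng.standard_normal(shape, dtype=np.float32)
    field = gaussian_filter(field, (0, scale_px, scale_px), mode="reflect")
    if tau_s > 0:
        # in-place AR(1) recursion along frames (much faster than a
        # general IIR filter call on the time axis)
        a = np.float32(np.exp(-1.0 / (tau_s * fps)))
        b = np.float32(np.sqrt(1.0 - float(a) ** 2))
        flat = field.reshape(shape[0], -1)
        flat *= b
        for t in range(1, shape[0]):
            flat[t] += a * flat[t - 1]
    # variance shrink factor of the smoothing = sum of squared kernel weights
    delta = np.zeros((4 * int(np.ceil(scale_px)) * 2 + 1,) * 2, dtype=np.float64)
    delta[delta.shape[0] // 2, delta.shape[1] // 2] = 1.0
    kernel = gaussian_filter(delta, scale_px)
    field *= np.float32(sd / np.sqrt((kernel**2).sum()))
    return field


def render_frames(
    spikes: np.ndarray,
    neurons: list[NeuronSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> FrameStack:
    """Render a video from spike trains and neuron geometry.

    Each neuron's brightness trace is its spike train convolved with the
    calcium kernel, scaled by ``amp_per_spike`` and spread onto the
    sensor by its point-source footprint.  Frames additionally carry a
    constant offset, a static linear illumination gradient along the
    long axis (emulating uneven LED excitation), a slowly varying
    frame-wide stray-light term shared by every pixel (non-stationary
    background, an AR(1) process with time constant
    ``shared_noise_tau_s``), per-frame spatially correlated speckle
    (stray light scattered through tissue), and independent white
    Gaussian noise per pixel.  Intensities are clipped at zero.

    The shared term is spatially uniform, so it cancels out of the
    local-threshold binarization but contaminates every extracted
    trace -- exactly the component spectral subtraction against the
    non-ROI background is meant to remove.
    """
    n_frames = config.n_frames
    if spikes.shape != (len(neurons), n_frames):
        raise ValueError(
            f"spikes shape {spikes.shape} does not match "
            f"{len(neurons)} neurons x {n_frames} frames"
        )
    h, w = config.height_px, config.width_px
    base = np.full((h, w), config.baseline_offset, dtype=np.float32)
    if config.gradient_amplitude:
        ramp = np.linspace(0.0, 1.0, h, dtype=np.float32)[:, None]
        base = base + config.gradient_amplitude * ramp

    if len(neurons):
        kernel = calcium_kernel(config.decay_tau_s, config.fps)
        traces = oaconvolve(
            spikes.astype(np.float32), kernel[None, :], axes=1
        )[:, :n_frames]
        # one footprint row per neuron; the whole source term is then a
        # single (T x n) @ (n x H*W) matrix product
        footprints = np.zeros((len(neurons), h * w), dtype=np.float32)
        for i, neuron in enumerate(neurons):
            rs, cs, patch = point_source_footprint(
                neuron.x_px, neuron.y_px, neuron.z_px, h, w
            )
            full = np.zeros((h, w), dtype=np.float32)
            full[rs, cs] = patch
            footprints[i] = config.amp_per_spike * full.ravel()
        frames = (traces.T @ footprints).reshape(n_frames, h, w)
        frames += base
    else:
        frames = np.empty((n_frames, h, w), dtype=np.float32)
        frames[:] = base

    if config.shared_noise_sd:
        frames += _shared_background(
            n_frames, config.shared_noise_sd, config.shared_noise_tau_s,
            config.fps, rng,
        )[:, None, None]
    if config.spatial_noise_sd:
        frames += _spatial_noise(
            frames.shape, config.spatial_noise_sd,
            config.spatial_noise_scale_px, config.spatial_noise_tau_s,
            config.fps, rng,
        )
    if config.noise_sd:
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        frames += config.noise_sd * noise
    np.clip(frames, 0.0, None, out=frames)
    return FrameStack(frames, fps=config.fps, n_baseline_frames=config.n_pre_frames)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one reproducible dataset from a single seed."""
    rng = np.random.default_rng(config.seed)
    neurons = sample_neurons(config, rng)
    spikes = generate_spike_trains(neurons, config, rng)
    frames = render_frames(spikes, neurons, config, rng)
    return SimulatedDataset(
        frames=frames,
        neurons=neurons,
        spikes=spikes,
        config=replace(config),
        seed=config.seed,
    )
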