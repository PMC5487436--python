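"""Synthetic labeled data generators.

Two families of fixtures make every stage of the pipeline testable without
external downloads:

* **Oriented-bar intensity images** — anti-aliased bars at a configurable
  set of orientations (chosen from the Gabor bank's angles so each class
  excites a distinct feature map), with positional/angular jitter and
  additive Gaussian noise.  These play the role of a static handwritten-
  symbol set and are converted to spikes by the encoders.
* **DVS-like event streams** — a bar sweeping across the field of view,
  emitting ON/OFF polarity events where the local intensity changes between
  consecutive rendered frames, with per-event timestamp jitter and uniform
  background noise events.  These emulate the statistics of event-camera
  recordings (edge-locked events, polarity split, sensor noise) though not
  sensor-level effects such as refractory pixels or hot-pixel clusters.

Everything is driven by ``numpy.random.default_rng(seed)``: the same config
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aer import NO_FM, EventStream, SampleSet, concat_op_stream

__all__ = ["BarImageConfig", "BarImageSet", "gen_bar_images",
           "DVSFixtureConfig", "gen_dvs_sample", "gen_dvs_samples",
           "gen_dvs_stream"]

DEFAULT_ANGLES: tuple[float, ...] = (0.0, 40.0, 80.0, 120.0)


# ---------------------------------------------------------------------------
# Oriented-bar intensity images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarImageConfig:
    """Oriented-bar image set.

    ``angles`` are class orientations in degrees (the angle of the normal
    to the bar, matching the Gabor convention); jitters perturb each
    drawn sample; ``noise_sigma`` is the additive Gaussian noise level in
    intensity units (0..255 scale).
    """

    angles: tuple[float, ...] = DEFAULT_ANGLES
    image_size: int = 28
    samples_per_class: int = 125
    train_fraction: float = 0.8
    bar_width: float = 1.4
    bar_length_frac: float = 0.75
    center_jitter: float = 2.0
    angle_jitter: float = 4.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if len(set(self.angles)) != len(self.angles):
            raise ValueError("class angles must be distinct")


@dataclass
class BarImageSet:
    """Labeled images with a recorded train/test split."""

    images: np.ndarray  # (n, size, size) uint8
    labels: np.ndarray  # (n,) int64
    train_idx: np.ndarray
    test_idx: np.ndarray
    config: BarImageConfig

    @property
    def n_classes(self) -> int:
        return len(self.config.angles)


def _render_bar(size: int, angle_deg: float, cx: float, cy: float,
                width: float, length: float) -> np.ndarray:
    """Anti-aliased bar via a smooth transverse Gaussian profile.

    ``angle_deg`` is the direction of the bar *normal*; the bar axis runs
    along the perpendicular, so a Gabor kernel of the same angle gives the
    maximal aligned response.
    """
    th = np.deg2rad(angle_deg)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    d_perp = dx * np.cos(th) + dy * np.sin(th)
    d_along = -dx * np.sin(th) + dy * np.cos(th)
    profile = np.exp(-(d_perp**2) / (2.0 * width**2))
    ends = 1.0 / (1.0 + np.exp(4.0 * (np.abs(d_along) - length / 2.0)))
    return 255.0 * profile * ends


def gen_bar_images(config: BarImageConfig = BarImageConfig()) -> BarImageSet:
    """Generate a balanced, jittered, noisy oriented-bar image set."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    length = config.bar_length_frac * size
    images, labels = [], []
    for label, angle in enumerate(config.angles):
        for _ in range(config.samples_per_class):
            cx = (size - 1) / 2.0 + rng.uniform(-config.center_jitter,
                                                config.center_jitter)
            cy = (size - 1) / 2.0 + rng.uniform(-config.center_jitter,
                                                config.center_jitter)
            a = angle + rng.uniform(-config.angle_jitter, config.angle_jitter)
            img = _render_bar(size, a, cx, cy, config.bar_width, length)
            if config.noise_sigma > 0:
                img = img + rng.normal(0.0, config.noise_sigma, img.shape)
            images.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(label)
    images = np.stack(images)
    labels = np.asarray(labels, dtype=np.int64)
    order = rng.permutation(len(labels))
    n_train = int(round(config.train_fraction * len(labels)))
    return BarImageSet(images, labels, np.sort(order[:n_train]),
                       np.sort(order[n_train:]), config)


# ---------------------------------------------------------------------------
# DVS-like moving-bar event streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DVSFixtureConfig:
    """Moving-bar event-camera emulation.

    A bar of each class orientation sweeps along its normal at
    ``speed_px_per_s``; frames rendered every ``frame_dt_us`` are
    differenced and pixels whose intensity changed by more than
    ``threshold`` emit one event of the corresponding polarity, with a
    uniform timestamp jitter inside the frame interval.  Background noise
    events arrive at ``background_rate_hz`` over the whole array with
    random polarity.
    """

    angles: tuple[float, ...] = DEFAULT_ANGLES
    image_size: int = 28
    samples_per_class: int = 125
    train_fraction: float = 0.8
    duration_us: int = 20_000
    frame_dt_us: int = 1000
    speed_px_per_s: float = 400.0
    threshold: float = 25.0
    background_rate_hz: float = 1000.0
    bar_width: float = 1.4
    bar_length_frac: float = 0.75
    center_jitter: float = 2.0
    angle_jitter: float = 4.0
    gap_us: int = 3_000_000
    seed: int = 0

    def __post_init__(self):
        if len(set(self.angles)) != len(self.angles):
            raise ValueError("class angles must be distinct")
        if self.duration_us <= 0 or self.frame_dt_us <= 0:
            raise ValueError("durations must be positive")


def gen_dvs_sample(label: int, config: DVSFixtureConfig,
                   rng: np.random.Generator) -> EventStream:
    """One moving-bar presentation as an ON/OFF event stream."""
    size = config.image_size
    angle = config.angles[label] + rng.uniform(-config.angle_jitter,
                                               config.angle_jitter)
    th = np.deg2rad(angle)
    length = config.bar_length_frac * size
    c0x = (size - 1) / 2.0 + rng.uniform(-config.center_jitter,
                                         config.center_jitter)
    c0y = (size - 1) / 2.0 + rng.uniform(-config.center_jitter,
                                         config.center_jitter)
    sweep = config.speed_px_per_s * config.duration_us * 1e-6  # px travelled
    n_frames = config.duration_us // config.frame_dt_us
    rows: list[tuple[int, int, int, int, int]] = []
    prev = None
    for i in range(n_frames + 1):
        frac = i / n_frames if n_frames else 0.0
        offset = (frac - 0.5) * sweep  # displacement along the bar normal
        cx = c0x + offset * np.cos(th)
        cy = c0y + offset * np.sin(th)
        frame = _render_bar(size, angle, cx, cy, config.bar_width, length)
        if prev is not None:
            diff = frame - prev
            # one event per threshold crossed, as an event camera emits
            # several events for a large intensity swing; the fractional
            # remainder is rounded stochastically (pixel threshold jitter),
            # making the expected count proportional to the change
            frac = np.abs(diff) / config.threshold
            n_ev = np.floor(frac + rng.uniform(size=frac.shape)
                            ).astype(np.int64)
            ys, xs = np.nonzero(n_ev)
            if len(ys):
                reps = n_ev[ys, xs]
                ys_r = np.repeat(ys, reps)
                xs_r = np.repeat(xs, reps)
                signs = np.repeat(np.where(diff[ys, xs] > 0, 1, -1), reps)
                t0 = (i - 1) * config.frame_dt_us
                ts = t0 + rng.integers(0, config.frame_dt_us,
                                       size=len(ys_r))
                rows.extend(zip(ts.tolist(), xs_r.tolist(), ys_r.tolist(),
                                signs.tolist(), [NO_FM] * len(ys_r)))
        prev = frame
    # uniform background noise with random polarity
    n_noise = rng.poisson(config.background_rate_hz * config.duration_us * 1e-6)
    for _ in range(n_noise):
        rows.append((int(rng.integers(0, config.duration_us)),
                     int(rng.integers(0, size)), int(rng.integers(0, size)),
                     int(rng.choice((-1, 1))), NO_FM))
    data = np.array(rows, dtype=np.int64).reshape(-1, 5)
    data = data[np.argsort(data[:, 0], kind="stable")]
    return EventStream(data, size, size, config.duration_us)


def gen_dvs_samples(config: DVSFixtureConfig = DVSFixtureConfig()
                    ) -> tuple[SampleSet, np.ndarray, np.ndarray]:
    """Balanced labeled sample streams plus a train/test index split."""
    rng = np.random.default_rng(config.seed)
    items: list[tuple[EventStream, int]] = []
    for label in range(len(config.angles)):
        for _ in range(config.samples_per_class):
            items.append((gen_dvs_sample(label, config, rng), label))
    order = rng.permutation(len(items))
    n_train = int(round(config.train_fraction * len(items)))
    sample_set = SampleSet(items, len(config.angles), [False] * len(items))
    return sample_set, np.sort(order[:n_train]), np.sort(order[n_train:])


def gen_dvs_stream(config: DVSFixtureConfig = DVSFixtureConfig()
                   ) -> EventStream:
    """All samples concatenated into one annotated One-Pass stream."""
    samples, train_idx, test_idx = gen_dvs_samples(config)
    return concat_op_stream(samples.items, gap_us=config.gap_us)
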