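"""Intensity-image to spike-train encoders.

Two synthetic encodings of a grayscale image (values 0..255) are provided:

* **Poisson encoding** — every pixel fires at a rate proportional to its
  intensity, all rates jointly scaled so the *total* number of spikes of the
  input population is fixed for a given stimulus duration, and no pixel's
  expected count exceeds a per-pixel cap.  Defaults: 1,000 total spikes,
  at most 15 expected spikes per pixel, 255 us stimulus duration.
* **Intensity-to-latency encoding** — one spike per nonzero pixel, with a
  delay decreasing linearly in intensity: maximum intensity fires at t = 0
  and the delay approaches the stimulus duration as intensity approaches 0.
  Zero-intensity (background) pixels stay silent, so the event count per
  sample equals the nonzero-pixel count.

Both encoders emit time-sorted streams confined to ``[0, duration)`` and
are reproducible given (image, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .aer import NO_FM, EventStream

__all__ = ["EncodingConfig", "poisson_encode", "latency_encode", "load_image"]


@dataclass(frozen=True)
class EncodingConfig:
    """Encoder settings; defaults match the standard synthetic protocol."""

    duration_us: int = 255
    max_spikes_per_pixel: float = 15.0
    total_spikes: int = 1000
    seed: Optional[int] = None

    def __post_init__(self):
        if self.duration_us <= 0:
            raise ValueError("duration_us must be positive")
        if self.total_spikes < 0:
            raise ValueError("total_spikes must be >= 0")


def _check_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D intensity matrix")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return img


def _capped_expected_counts(img: np.ndarray, total: int, cap: float) -> np.ndarray:
    """Per-pixel expected spike counts: proportional to intensity, summing to
    ``total``, no pixel above ``cap``.

    Iterative water-filling: pixels hitting the cap are frozen there and the
    remaining budget is redistributed proportionally over the rest.  If the
    cap cannot absorb the budget at all, every nonzero pixel sits at the cap.
    """
    flat = img.ravel()
    expected = np.zeros_like(flat)
    free = flat > 0
    budget = float(total)
    for _ in range(flat.size):
        mass = flat[free].sum()
        if budget <= 0 or mass <= 0:
            break
        alloc = flat * (budget / mass)
        alloc[~free] = 0.0
        over = free & (alloc >= cap)
        if not over.any():
            expected[free] = alloc[free]
            break
        expected[over] = cap
        budget -= cap * over.sum()
        free = free & ~over
        if not free.any():
            # budget exceeds what the cap allows; rates saturate at the cap
            break
    return expected


def poisson_encode(image, config: EncodingConfig = EncodingConfig(),
                   rng: Optional[np.random.Generator] = None) -> EventStream:
    """Encode an image as a fixed-total-budget Poisson-like spike train.

    The budget is allocated across pixels by a single multinomial draw over
    the normalized capped rates (which pins the total event count exactly);
    timestamps are uniform integer draws in ``[0, duration)``.
    """
    img = _check_image(image)
    h, w = img.shape
    if config.total_spikes == 0:
        return EventStream.empty(w, h, config.duration_us)
    if img.max() == 0:
        raise ValueError("all-zero image with a positive spike budget: "
                         "no rate mass to allocate")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    expected = _capped_expected_counts(img, config.total_spikes,
                                       config.max_spikes_per_pixel)
    probs = expected / expected.sum()
    counts = rng.multinomial(config.total_spikes, probs)
    pix = np.repeat(np.arange(img.size), counts)
    ys, xs = np.divmod(pix, w)
    ts = rng.integers(0, config.duration_us, size=config.total_spikes)
    sign = np.ones_like(ts)
    fm = np.full_like(ts, NO_FM)
    data = np.stack([ts, xs, ys, sign, fm], axis=1).astype(np.int64)
    data = data[np.argsort(data[:, 0], kind="stable")]
    return EventStream(data, w, h, config.duration_us)


def latency_encode(image, config: EncodingConfig = EncodingConfig()
                   ) -> EventStream:
    """Encode an image as one spike per nonzero pixel, earlier for brighter.

    Delay map: ``t = round((1 - I/255) * duration_us)`` clipped into
    ``[0, duration)``; deterministic.
    """
    img = _check_image(image)
    h, w = img.shape
    ys, xs = np.nonzero(img)
    if len(ys) == 0:
        return EventStream.empty(w, h, config.duration_us)
    inten = img[ys, xs]
    ts = np.rint((1.0 - inten / 255.0) * config.duration_us).astype(np.int64)
    ts = np.minimum(ts, config.duration_us - 1)
    sign = np.ones_like(ts)
    fm = np.full_like(ts, NO_FM)
    data = np.stack([ts, xs, ys, sign, fm], axis=1).astype(np.int64)
    data = data[np.argsort(data[:, 0], kind="stable")]
    return EventStream(data, w, h, config.duration_us)


def load_image(path) -> np.ndarray:
    """Read a grayscale image (PGM/PNG/... via Pillow, or a CSV matrix)."""
    path = str(path)
    if path.endswith(".csv"):
        return np.loadtxt(path, delimiter=",", dtype=np.float64)
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)
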