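"""Event-driven network layers: shared-kernel convolution, subsampling
pooling, flatten addressing, and the fully-connected spiking classifier.

Every layer exposes ``process(t, payload) -> list of payloads`` (the module
interface consumed by the scheduler and the feed-forward pipeline) and
``reset()`` (the sample-by-sample state reset).  Payloads are
``(x, y, sign, fm)`` integer tuples; after the flatten stage ``x`` carries
the linear index and ``fm`` is -1.

Convolution is *valid* (no padding): an input layer of side ``n`` and a
kernel of side ``k`` give feature maps of side ``n - k + 1``.  The kernel
is applied as a correlation: the output neuron at (ox, oy) covers input
columns ``ox .. ox+k-1`` and rows ``oy .. oy+k-1``, and an input spike at
(x, y) reaches it through tap ``kernel[y - oy, x - ox]``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .aer import NO_FM
from .neuron import NeuronArray, NeuronParams

__all__ = ["ConvLayer", "SubsampleLayer", "FlattenLayer", "FCLayer",
           "flatten_index", "unflatten_index"]


class ConvLayer:
    """One spiking convolution layer: ``n_maps`` feature maps sharing integer
    kernels and one neuron parameter block.

    Parameters
    ----------
    kernels : ndarray (n_maps, k, k), integer
        Shared synaptic weights, one kernel per feature map.
    params : NeuronParams
        Common neuron parameters of all feature-map neurons.
    input_size : int
        Side of the (square) input address space.
    """

    def __init__(self, kernels: np.ndarray, params: NeuronParams,
                 input_size: int):
        kernels = np.asarray(kernels)
        self.kernels = kernels
        self.params = params
        self.n_maps, self.k, k2 = kernels.shape
        if self.k != k2:
            raise ValueError("kernels must be square")
        self.input_size = input_size
        self.out_size = input_size - self.k + 1
        if self.out_size < 1:
            raise ValueError("kernel larger than input")
        self.neurons = NeuronArray((self.n_maps, self.out_size, self.out_size),
                                   params)

    def reset(self) -> None:
        self.neurons.reset()

    def membrane_map(self) -> np.ndarray:
        """Current membrane values, shape (n_maps, out, out)."""
        return self.neurons.vm.copy()

    def process(self, t: int, payload: tuple) -> list[tuple]:
        x, y, sign = int(payload[0]), int(payload[1]), int(payload[2])
        if not (0 <= x < self.input_size and 0 <= y < self.input_size):
            raise ValueError(f"event at ({x}, {y}) outside "
                             f"{self.input_size}x{self.input_size} input")
        k, last = self.k, self.out_size - 1
        ax, bx = max(0, x - k + 1), min(last, x)
        ay, by = max(0, y - k + 1), min(last, y)
        # tap for output (ox, oy) is kernel[y - oy, x - ox]; over the block
        # this is a doubly reversed sub-window of the kernel
        sub = self.kernels[:, y - by:y - ay + 1, x - bx:x - ax + 1][:, ::-1, ::-1]
        idx = (slice(None), slice(ay, by + 1), slice(ax, bx + 1))
        fired_pos, fired_neg = self.neurons.inject(idx, sub, sign, t)
        emitting = fired_pos | fired_neg if self.params.emit_negative \
            else fired_pos
        out: list[tuple] = []
        for f, ry, rx in np.argwhere(emitting):
            s = 1 if fired_pos[f, ry, rx] else -1
            out.append((int(ax + rx), int(ay + ry), s, int(f)))
        return out


class SubsampleLayer:
    """Spatial pooling by address decimation.

    ``remap`` mode forwards every event at the decimated address
    (x // factor, y // factor) — a pure relabeling that conserves event
    count.  ``accumulate`` mode keeps one signed counter per pooled address
    and emits a single event for every ``m`` net inputs.
    """

    def __init__(self, factor: int = 2, mode: str = "remap",
                 m: int = 4, n_maps: int = 1, in_size: int = 2):
        if mode not in ("remap", "accumulate"):
            raise ValueError("mode must be 'remap' or 'accumulate'")
        if in_size % factor:
            raise ValueError(f"input side {in_size} not divisible by pooling "
                             f"factor {factor}")
        self.factor = factor
        self.mode = mode
        self.m = m
        self.n_maps = n_maps
        self.out_size = in_size // factor
        self._counters = np.zeros((n_maps, self.out_size, self.out_size),
                                  dtype=np.int64)

    def reset(self) -> None:
        self._counters.fill(0)

    def process(self, t: int, payload: tuple) -> list[tuple]:
        x, y, sign, fm = (int(v) for v in payload[:4])
        xs, ys = x // self.factor, y // self.factor
        if self.mode == "remap":
            return [(xs, ys, sign, fm)]
        c = self._counters[fm, ys, xs] + sign
        out: list[tuple] = []
        while c >= self.m:
            out.append((xs, ys, 1, fm))
            c -= self.m
        while c <= -self.m:
            out.append((xs, ys, -1, fm))
            c += self.m
        self._counters[fm, ys, xs] = c
        return out


def flatten_index(fm: int, x: int, y: int, side: int) -> int:
    """Feature-map-major, row-major linear address."""
    return fm * side * side + y * side + x


def unflatten_index(j: int, side: int) -> tuple[int, int, int]:
    fm, rem = divmod(j, side * side)
    y, x = divmod(rem, side)
    return fm, x, y


class FlattenLayer:
    """Bijective relabeling of (fm, x, y) addresses to one linear index."""

    def __init__(self, n_maps: int, side: int):
        self.n_maps = n_maps
        self.side = side
        self.size = n_maps * side * side

    def reset(self) -> None:
        pass

    def process(self, t: int, payload: tuple) -> list[tuple]:
        x, y, sign, fm = (int(v) for v in payload[:4])
        if not (0 <= x < self.side and 0 <= y < self.side
                and 0 <= fm < self.n_maps):
            raise ValueError(f"event (fm={fm}, x={x}, y={y}) outside pooled "
                             f"geometry {self.n_maps}x{self.side}x{self.side}")
        return [(flatten_index(fm, x, y, self.side), 0, sign, NO_FM)]


class FCLayer:
    """Fully-connected spiking classifier: one positive-only LIF per class.

    Input index ``j`` with sign ``s`` delivers ``s * W[c, j]`` to every class
    neuron ``c``.  Output payloads carry the class index in the x field.
    """

    def __init__(self, weights: np.ndarray, params: NeuronParams):
        weights = np.asarray(weights)
        if weights.ndim != 2:
            raise ValueError("weights must be (classes, flatten_size)")
        self.weights = weights
        self.n_classes, self.input_size = weights.shape
        self.params = params
        self.neurons = NeuronArray((self.n_classes,), params)

    def reset(self) -> None:
        self.neurons.reset()

    def process(self, t: int, payload: tuple) -> list[tuple]:
        j, sign = int(payload[0]), int(payload[2])
        if not 0 <= j < self.input_size:
            raise ValueError(f"flatten index {j} out of range "
                             f"[0, {self.input_size})")
        fired_pos, fired_neg = self.neurons.inject(
            slice(None), self.weights[:, j], sign, t)
        emitting = fired_pos | fired_neg if self.params.emit_negative \
            else fired_pos
        return [(int(c), 0, 1 if fired_pos[c] else -1, NO_FM)
                for c in np.flatnonzero(emitting)]
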