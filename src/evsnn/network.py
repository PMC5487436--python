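"""The single-convolution-layer spiking network and its two execution paths.

Topology: source -> C1 (Gabor convolution, 18 feature maps) -> S1
(subsampling pooling) -> Flatten -> fully-connected spiking classifier.

Two equivalent ways to execute it are provided:

* :func:`build_convnet_netlist` wires the layers into a
  :class:`~evsnn.scheduler.Netlist` and lets the event-driven kernel
  dispatch globally-earliest-first (any node can be recorded);
* :class:`ConvNetPipeline.run_stream` cascades each input event depth-first
  through the feed-forward chain.  With zero module delays the two orders
  deliver the identical event sequence to every layer, so the results match
  event-for-event (asserted in the test suite); the pipeline path simply
  skips the dispatch queue and is used for large runs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .aer import EventStream
from .config import NetConfig
from .kernels import build_bank, quantize_kernels
from .layers import ConvLayer, FCLayer, FlattenLayer, SubsampleLayer
from .scheduler import Netlist, Node

__all__ = ["ConvNetPipeline", "build_convnet_netlist"]

_TAPS = ("input", "c1", "s1", "flatten", "fc")


class ConvNetPipeline:
    """The feature-extraction network plus (optionally) the spiking classifier.

    Parameters
    ----------
    config : NetConfig
        Geometry, Gabor bank and neuron parameter blocks.
    weights : ndarray (n_classes, flatten_size) of integers, optional
        Integer-scaled classifier weights; without them the network stops at
        the Flatten stage (the configuration used while building training
        histograms).
    leak : bool
        One-Pass (leaky) regime if true; sample-by-sample (no leak) if false.
    """

    def __init__(self, config: NetConfig, weights: Optional[np.ndarray] = None,
                 leak: bool = False):
        self.config = config
        self.leak = leak
        bank = build_bank(config.gabor.thetas, config.gabor.psis,
                          sigma=config.gabor.sigma, lam=config.gabor.lam,
                          gamma=config.gabor.gamma, size=config.kernel_size)
        quantize_kernels(bank, config.kernel_scale)
        self.bank = bank
        self.conv = ConvLayer(bank.spiking_kernels, config.conv_params(leak),
                              config.input_size)
        self.pool = SubsampleLayer(config.pool_factor, config.pool_mode,
                                   m=config.pool_m,
                                   n_maps=config.n_feature_maps,
                                   in_size=config.c1_size)
        self.flatten = FlattenLayer(config.n_feature_maps, config.s1_size)
        self.fc: Optional[FCLayer] = None
        if weights is not None:
            self.set_weights(weights)

    def set_weights(self, weights: np.ndarray) -> None:
        weights = np.asarray(weights)
        if weights.shape != (self.config.n_classes, self.flatten_size):
            raise ValueError(
                f"weights shape {weights.shape} != "
                f"({self.config.n_classes}, {self.flatten_size})")
        self.fc = FCLayer(weights, self.config.fc_params(self.leak))

    @property
    def flatten_size(self) -> int:
        return self.flatten.size

    @property
    def layers(self):
        out = [self.conv, self.pool, self.flatten]
        if self.fc is not None:
            out.append(self.fc)
        return out

    def reset(self) -> None:
        for layer in self.layers:
            layer.reset()

    # -- execution ---------------------------------------------------------

    def run_stream(self, stream: EventStream, reset: bool = True,
                   record: Sequence[str] = ("flatten", "fc"),
                   reset_at_boundaries: bool = False,
                   ) -> dict[str, EventStream]:
        """Feed a stream through the network and record the requested taps.

        ``reset_at_boundaries`` re-initializes all layer state at each
        annotated sample start (the explicit-reset One-Pass variant).
        Recorded taps: ``input``, ``c1``, ``s1``, ``flatten``, ``fc``.
        """
        unknown = set(record) - set(_TAPS)
        if unknown:
            raise ValueError(f"unknown taps {sorted(unknown)}")
        if reset:
            self.reset()
        logs: dict[str, list[tuple]] = {name: [] for name in record}
        boundaries = [w.t_start for w in stream.samples] if reset_at_boundaries else []
        next_b = 0
        chain = [(self.conv, "c1"), (self.pool, "s1"), (self.flatten, "flatten")]
        if self.fc is not None:
            chain.append((self.fc, "fc"))
        for row in stream.data:
            t = int(row[0])
            while next_b < len(boundaries) and t >= boundaries[next_b]:
                self.reset()
                next_b += 1
            payloads = [tuple(int(v) for v in row[1:])]
            if "input" in logs:
                logs["input"].extend((t,) + p for p in payloads)
            for layer, name in chain:
                nxt: list[tuple] = []
                for p in payloads:
                    nxt.extend(layer.process(t, p))
                payloads = nxt
                if name in logs:
                    logs[name].extend((t,) + p for p in payloads)
                if not payloads:
                    break
        out: dict[str, EventStream] = {}
        geoms = {
            "input": (stream.width, stream.height),
            "c1": (self.conv.out_size, self.conv.out_size),
            "s1": (self.pool.out_size, self.pool.out_size),
            "flatten": (self.flatten.size, 1),
            "fc": (self.config.n_classes, 1),
        }
        for name in record:
            w, h = geoms[name]
            data = np.array(logs[name], dtype=np.int64).reshape(-1, 5)
            out[name] = EventStream(data, w, h, stream.duration,
                                    list(stream.samples))
        return out


    def run_compiled(self, stream: EventStream, reset: bool = True,
                     reset_at_boundaries: bool = False) -> dict:
        """Compiled whole-stream execution (identical results, much faster).

        Returns ``{"input": stream, "flatten": EventStream,
        "fc": EventStream | None, "counts": {tap: spike count}}``.  Falls
        back to the per-event reference path when the compiled kernel is
        unavailable or the classifier emits negative spikes.
        """
        from . import _fastpath

        if not _fastpath.HAVE_NUMBA or (
                self.fc is not None and self.fc.params.emit_negative):
            record = ["input", "c1", "s1", "flatten"]
            if self.fc is not None:
                record.append("fc")
            taps = self.run_stream(stream, reset=reset, record=record,
                                   reset_at_boundaries=reset_at_boundaries)
            return {"input": stream, "flatten": taps["flatten"],
                    "fc": taps.get("fc"),
                    "counts": {k: len(v) for k, v in taps.items()}}
        if reset:
            self.reset()
        boundaries = np.asarray(
            [w.t_start for w in stream.samples] if reset_at_boundaries else [],
            dtype=np.int64)
        res = _fastpath.run_chain(stream.data, boundaries, self.conv,
                                  self.pool, self.flatten, self.fc)
        fl = res["flatten"]
        fl_data = np.column_stack([
            fl[:, 0], fl[:, 1], np.zeros(len(fl), np.int64), fl[:, 2],
            np.full(len(fl), -1, np.int64)])
        out = {
            "input": stream,
            "flatten": EventStream(fl_data, self.flatten.size, 1,
                                   stream.duration, list(stream.samples)),
            "fc": None,
            "counts": res["counts"],
        }
        if self.fc is not None:
            fc = res["fc"]
            fc_data = np.column_stack([
                fc[:, 0], fc[:, 1], np.zeros(len(fc), np.int64),
                np.ones(len(fc), np.int64), np.full(len(fc), -1, np.int64)])
            out["fc"] = EventStream(fc_data, self.config.n_classes, 1,
                                    stream.duration, list(stream.samples))
        return out


def build_convnet_netlist(config: NetConfig, input_stream: EventStream,
                          weights: Optional[np.ndarray] = None,
                          leak: bool = False,
                          ) -> tuple[Netlist, dict[str, Node]]:
    """Wire the network into a scheduler netlist fed by ``input_stream``.

    Returns the netlist plus a tap dictionary mapping layer names to their
    output nodes, from which processed events can be read after ``run()``.
    """
    pipe = ConvNetPipeline(config, weights=weights, leak=leak)
    net = Netlist()
    taps: dict[str, Node] = {}
    taps["input"] = net.add_source("input", input_stream)
    taps["c1"] = net.add_module("c1", pipe.conv, taps["input"])
    taps["s1"] = net.add_module("s1", pipe.pool, taps["c1"])
    taps["flatten"] = net.add_module("flatten", pipe.flatten, taps["s1"])
    if pipe.fc is not None:
        taps["fc"] = net.add_module("fc", pipe.fc, taps["flatten"])
    return net, taps
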