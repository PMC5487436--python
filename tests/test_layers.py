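"""Layer semantics: event-driven convolution vs dense-frame oracles,
pooling counters, flatten bijection, classifier accumulation, and the
compiled fast path vs the per-event reference path."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from evsnn.aer import EventStream
from evsnn.config import NetConfig
from evsnn.layers import (ConvLayer, FCLayer, FlattenLayer, SubsampleLayer,
                          flatten_index, unflatten_index)
from evsnn.kernels import build_bank, quantize_kernels
from evsnn.neuron import NeuronParams
from evsnn.network import ConvNetPipeline
from helpers import random_stream

HUGE = 2**61


def int_kernels(n_maps=3, k=5, seed=0, scale=1000):
    rng = np.random.default_rng(seed)
    return rng.integers(-scale, scale, (n_maps, k, k)).astype(np.int64)


def quiet_params():
    return NeuronParams(th_plus=HUGE, th_minus=-HUGE)


class TestConvLayer:
    def test_single_center_event_writes_kernel_pattern(self):
        kernels = int_kernels(n_maps=2, k=5)
        layer = ConvLayer(kernels, quiet_params(), input_size=12)
        layer.process(0, (6, 6, 1, -1))
        vm = layer.membrane_map()
        # oracle: dense correlation of a one-pixel image
        img = np.zeros((12, 12))
        img[6, 6] = 1
        for f in range(2):
            expected = correlate2d(img, kernels[f], mode="valid")
            assert np.array_equal(vm[f], expected)
        # exactly k^2 membranes touched per feature map
        assert np.count_nonzero(layer.neurons.t_last[0]) == 0  # t stays 0
        touched = np.count_nonzero(vm[0] != 0)
        assert touched <= 25

    def test_corner_event_updates_one_neuron_per_map(self):
        kernels = int_kernels(n_maps=2, k=5)
        layer = ConvLayer(kernels, quiet_params(), input_size=12)
        out_before = layer.membrane_map()
        layer.process(0, (0, 0, 1, -1))
        vm = layer.membrane_map()
        changed = np.argwhere(vm != out_before)
        assert {tuple(c[1:]) for c in changed} == {(0, 0)}
        assert vm[0, 0, 0] == kernels[0, 0, 0]

    def test_frame_equivalence_oracle(self, rng):
        """Leak off, infinite thresholds: final membranes equal the valid
        correlation of the signed event-count image, integer-exact."""
        kernels = int_kernels(n_maps=4, k=5, seed=3)
        layer = ConvLayer(kernels, quiet_params(), input_size=10)
        stream = random_stream(rng, n_events=300, width=10, height=10)
        img = np.zeros((10, 10))
        for e in stream:
            layer.process(e.t, (e.x, e.y, e.sign, -1))
            img[e.y, e.x] += e.sign
        vm = layer.membrane_map()
        for f in range(4):
            expected = correlate2d(img, kernels[f], mode="valid")
            assert np.array_equal(vm[f], expected)

    def test_out_of_geometry_event_rejected(self):
        layer = ConvLayer(int_kernels(), quiet_params(), input_size=12)
        with pytest.raises(ValueError, match="outside"):
            layer.process(0, (12, 0, 1, -1))

    def test_spikes_emitted_at_threshold(self):
        kernels = np.full((1, 3, 3), 100, dtype=np.int64)
        p = NeuronParams(th_plus=100, th_minus=-100)
        layer = ConvLayer(kernels, p, input_size=5)
        out = layer.process(0, (2, 2, 1, -1))
        # every receptive neuron receives exactly +100 and fires
        assert len(out) == 9
        assert all(s == 1 for _, _, s, _ in out)
        assert np.all(layer.membrane_map() == 0)


class TestSubsample:
    def test_remap_decimates_addresses(self):
        layer = SubsampleLayer(2, "remap", n_maps=1, in_size=6)
        assert layer.process(0, (4, 5, 1, 0)) == [(2, 2, 1, 0)]
        assert layer.process(0, (5, 4, -1, 0)) == [(2, 2, -1, 0)]

    def test_accumulate_counter_semantics(self):
        layer = SubsampleLayer(2, "accumulate", m=4, n_maps=1, in_size=6)
        outs = []
        for xy in [(4, 4), (4, 5), (5, 4), (5, 5)]:
            outs += layer.process(0, (*xy, 1, 0))
        assert outs == [(2, 2, 1, 0)]

    def test_counting_oracle(self, rng):
        n = 500
        xs = rng.integers(0, 6, n)
        ys = rng.integers(0, 6, n)
        signs = rng.choice([-1, 1], n)
        remap = SubsampleLayer(2, "remap", n_maps=1, in_size=6)
        acc = SubsampleLayer(2, "accumulate", m=3, n_maps=1, in_size=6)
        n_remap = sum(len(remap.process(0, (x, y, s, 0)))
                      for x, y, s in zip(xs, ys, signs))
        assert n_remap == n  # remap conserves event count
        emitted = np.zeros((3, 3), dtype=int)
        for x, y, s in zip(xs, ys, signs):
            for _, _, so, _ in acc.process(0, (x, y, s, 0)):
                emitted[y // 2, x // 2] += so
        # net emitted events x m + residual counter = net input count
        net = np.zeros((3, 3), dtype=int)
        np.add.at(net, (ys // 2, xs // 2), signs)
        assert np.array_equal(emitted * 3 + acc._counters[0], net)


class TestFlatten:
    def test_origin_maps_to_zero(self):
        layer = FlattenLayer(18, 11)
        assert layer.process(0, (0, 0, 1, 0)) == [(0, 0, 1, -1)]

    def test_full_geometry_range(self):
        # 28x28 input, 7x7 kernel, pool 2 -> 18 maps of 11x11 = 2178
        layer = FlattenLayer(18, 11)
        top = layer.process(0, (10, 10, 1, 17))[0][0]
        assert top == 2177
        assert layer.size == 2178

    def test_bijection_exhaustive(self):
        side, n_maps = 7, 5
        seen = set()
        for fm in range(n_maps):
            for y in range(side):
                for x in range(side):
                    j = flatten_index(fm, x, y, side)
                    assert unflatten_index(j, side) == (fm, x, y)
                    seen.add(j)
        assert seen == set(range(n_maps * side * side))

    def test_out_of_geometry_rejected(self):
        layer = FlattenLayer(2, 4)
        with pytest.raises(ValueError):
            layer.process(0, (4, 0, 1, 0))
        with pytest.raises(ValueError):
            layer.process(0, (0, 0, 1, 2))


class TestFCLayer:
    def test_threshold_weight_fires_immediately(self):
        W = np.zeros((3, 10), dtype=np.int64)
        W[1, 4] = 10_000_000
        layer = FCLayer(W, NeuronParams(th_plus=10_000_000))
        out = layer.process(0, (4, 0, 1, -1))
        assert out == [(1, 0, 1, -1)]

    def test_zero_weights_silent(self, rng):
        layer = FCLayer(np.zeros((3, 10), dtype=np.int64),
                        NeuronParams(th_plus=10_000_000))
        for t in range(100):
            assert layer.process(t, (int(rng.integers(0, 10)), 0, 1, -1)) == []

    def test_accumulator_oracle(self, rng):
        """Leak off: per-class spike counts match a scalar carry
        accumulator driven by the same weight sequence."""
        th = 1000
        W = rng.integers(-400, 400, (4, 20)).astype(np.int64)
        layer = FCLayer(W, NeuronParams(th_plus=th))
        ids = rng.integers(0, 20, 500)
        got = np.zeros(4, dtype=int)
        for t, j in enumerate(ids):
            for c, _, s, _ in layer.process(int(t), (int(j), 0, 1, -1)):
                got[c] += 1
        acc = np.zeros(4)
        want = np.zeros(4, dtype=int)
        for j in ids:
            acc += W[:, j]
            fired = acc >= th
            want += fired
            acc[fired] = 0
            acc[acc <= -(2**31)] = 0
        assert np.array_equal(got, want)

    def test_index_out_of_range(self):
        layer = FCLayer(np.zeros((2, 5), dtype=np.int64),
                        NeuronParams(th_plus=10))
        with pytest.raises(ValueError, match="out of range"):
            layer.process(0, (5, 0, 1, -1))


# -- compiled fast path vs reference path -----------------------------------

@pytest.mark.parametrize("leak,boundaries", [(False, False), (True, False),
                                             (True, True)])
def test_compiled_path_matches_reference(rng, leak, boundaries):
    cfg = NetConfig(input_size=10, kernel_size=5, n_classes=3,
                    conv_th_plus=2_000_000, conv_th_minus=-2_000_000,
                    conv_tl_plus=300, conv_tl_minus=300)
    weights = rng.integers(-10**7, 10**7,
                           (3, cfg.flatten_size)).astype(np.int64)
    stream = random_stream(rng, n_events=400, width=10, height=10,
                           duration=3000)
    if boundaries:
        from evsnn.aer import SampleWindow
        stream.samples.extend([SampleWindow(0, 0, 1500),
                               SampleWindow(1, 1500, 3000)])

    ref_pipe = ConvNetPipeline(cfg, weights=weights, leak=leak)
    ref = ref_pipe.run_stream(stream, record=("flatten", "fc"),
                              reset_at_boundaries=boundaries)
    fast_pipe = ConvNetPipeline(cfg, weights=weights, leak=leak)
    fast = fast_pipe.run_compiled(stream, reset_at_boundaries=boundaries)

    assert np.array_equal(ref["flatten"].data, fast["flatten"].data)
    assert np.array_equal(ref["fc"].data[:, [0, 1]], fast["fc"].data[:, [0, 1]])
    assert fast["counts"]["flatten"] == len(ref["flatten"])
    # final membrane state evolves identically on both paths
    assert np.array_equal(ref_pipe.conv.neurons.vm, fast_pipe.conv.neurons.vm)
    assert np.array_equal(ref_pipe.fc.neurons.vm, fast_pipe.fc.neurons.vm)
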