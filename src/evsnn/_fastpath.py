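"""Compiled execution of the conv -> pool -> flatten -> classifier chain.

The reference implementation in :mod:`evsnn.layers` processes one event at
a time through small vectorized numpy updates, which is convenient for
inspection but dominated by per-event interpreter overhead.  This module
holds a numba-compiled kernel that runs the identical per-neuron arithmetic
over a whole stream in one call.  The two paths are semantically equal
event-for-event (asserted in the test suite); the pipeline uses this one
for large runs.

Spikes are emitted in feature-map-major, row-major neuron order at each
event time, matching the reference path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]

__all__ = ["HAVE_NUMBA", "run_chain"]


@njit(cache=True)
def _leak_scalar(vm, elapsed, rest, rate_p, rate_m):
    if elapsed > 0:
        if vm > rest and rate_p > 0.0:
            vm = max(rest, vm - elapsed * rate_p)
        elif vm < rest and rate_m > 0.0:
            vm = min(rest, vm + elapsed * rate_m)
    return vm


@njit(cache=True)
def _chain_kernel(events, boundaries, kernels,
                  c_vm, c_tlast, c_tref,
                  c_th_p, c_th_m, c_rest, c_rate_p, c_rate_m,
                  c_emit_neg, c_refrac,
                  pool_factor, pool_accumulate, pool_m, pool_cnt,
                  fl_side,
                  W, f_vm, f_tlast, f_tref,
                  f_th_p, f_th_m, f_rest, f_rate_p, f_rate_m, f_refrac,
                  has_fc, out_fl, out_fc):
    n_maps, k, _ = kernels.shape
    out_side = c_vm.shape[1]
    n_fl = 0
    n_fc = 0
    n_c1 = 0
    n_s1 = 0
    n_classes = W.shape[0]
    b_idx = 0
    n_bounds = boundaries.shape[0]
    for i in range(events.shape[0]):
        t = events[i, 0]
        x = events[i, 1]
        y = events[i, 2]
        sign = events[i, 3]
        while b_idx < n_bounds and t >= boundaries[b_idx]:
            c_vm[:, :, :] = c_rest
            c_tlast[:, :, :] = 0
            c_tref[:, :, :] = 0
            pool_cnt[:, :, :] = 0
            f_vm[:] = f_rest
            f_tlast[:] = 0
            f_tref[:] = 0
            b_idx += 1
        ax = max(0, x - k + 1)
        bx = min(out_side - 1, x)
        ay = max(0, y - k + 1)
        by = min(out_side - 1, y)
        for f in range(n_maps):
            for oy in range(ay, by + 1):
                for ox in range(ax, bx + 1):
                    vm = _leak_scalar(c_vm[f, oy, ox], t - c_tlast[f, oy, ox],
                                      c_rest, c_rate_p, c_rate_m)
                    c_tlast[f, oy, ox] = t
                    s_out = 0
                    if t >= c_tref[f, oy, ox]:
                        vm += sign * kernels[f, y - oy, x - ox]
                        if vm >= c_th_p:
                            s_out = 1
                        elif vm <= c_th_m:
                            s_out = -1
                        if s_out != 0:
                            vm = c_rest
                            if c_refrac > 0:
                                c_tref[f, oy, ox] = t + c_refrac
                    c_vm[f, oy, ox] = vm
                    if s_out == 0 or (s_out == -1 and not c_emit_neg):
                        continue
                    n_c1 += 1
                    # pooling
                    xs = ox // pool_factor
                    ys = oy // pool_factor
                    if pool_accumulate:
                        cnt = pool_cnt[f, ys, xs] + s_out
                        n_pool_out = 0
                        while cnt >= pool_m:
                            cnt -= pool_m
                            n_pool_out += 1
                        while cnt <= -pool_m:
                            cnt += pool_m
                            n_pool_out -= 1
                        pool_cnt[f, ys, xs] = cnt
                    else:
                        n_pool_out = s_out
                    if n_pool_out == 0:
                        continue
                    s_pool = 1 if n_pool_out > 0 else -1
                    for _rep in range(abs(n_pool_out)):
                        n_s1 += 1
                        j = f * fl_side * fl_side + ys * fl_side + xs
                        if n_fl >= out_fl.shape[0]:
                            return n_fl, n_fc, n_c1, n_s1, 1
                        out_fl[n_fl, 0] = t
                        out_fl[n_fl, 1] = j
                        out_fl[n_fl, 2] = s_pool
                        n_fl += 1
                        if not has_fc:
                            continue
                        for c in range(n_classes):
                            vmc = _leak_scalar(f_vm[c], t - f_tlast[c],
                                               f_rest, f_rate_p, f_rate_m)
                            f_tlast[c] = t
                            fired = 0
                            if t >= f_tref[c]:
                                vmc += s_pool * W[c, j]
                                if vmc >= f_th_p:
                                    fired = 1
                                elif vmc <= f_th_m:
                                    fired = -1
                                if fired != 0:
                                    vmc = f_rest
                                    if f_refrac > 0:
                                        f_tref[c] = t + f_refrac
                            f_vm[c] = vmc
                            if fired == 1:
                                if n_fc >= out_fc.shape[0]:
                                    return n_fl, n_fc, n_c1, n_s1, 1
                                out_fc[n_fc, 0] = t
                                out_fc[n_fc, 1] = c
                                n_fc += 1
                            # negative classifier spikes are never
                            # communicated (degenerate positive-only model)
    return n_fl, n_fc, n_c1, n_s1, 0


def run_chain(events: np.ndarray, boundaries: np.ndarray,
              conv, pool, flatten, fc) -> dict:
    """Run a whole event array through the layer chain in compiled code.

    ``conv``/``pool``/``flatten``/``fc`` are the live layer objects of a
    :class:`~evsnn.network.ConvNetPipeline`; their state arrays are mutated
    exactly as the per-event reference path would.  Returns flatten and
    classifier event arrays plus per-tap spike counts.
    """
    cp = conv.params
    kernels = conv.kernels.astype(np.float64)
    if fc is not None:
        fp = fc.params
        W = fc.weights.astype(np.float64)
        f_vm, f_tlast, f_tref = (fc.neurons.vm, fc.neurons.t_last,
                                 fc.neurons.t_refrac_end)
        fc_args = (float(fp.th_plus), float(fp.th_minus),
                   float(fp.memb_reset), fp.leak_rate_plus,
                   fp.leak_rate_minus, np.int64(fp.refractory_us))
    else:
        W = np.zeros((0, 1), dtype=np.float64)
        f_vm = np.zeros(0, dtype=np.float64)
        f_tlast = np.zeros(0, dtype=np.int64)
        f_tref = np.zeros(0, dtype=np.int64)
        fc_args = (1.0, -1.0, 0.0, 0.0, 0.0, np.int64(0))
    cap_fl = max(1024, 8 * len(events))
    cap_fc = max(1024, len(events))
    while True:
        out_fl = np.empty((cap_fl, 3), dtype=np.int64)
        out_fc = np.empty((cap_fc, 2), dtype=np.int64)
        saved = (conv.neurons.vm.copy(), conv.neurons.t_last.copy(),
                 conv.neurons.t_refrac_end.copy(), pool._counters.copy(),
                 f_vm.copy(), f_tlast.copy(), f_tref.copy())
        n_fl, n_fc, n_c1, n_s1, overflow = _chain_kernel(
            np.ascontiguousarray(events[:, :4]), boundaries, kernels,
            conv.neurons.vm, conv.neurons.t_last, conv.neurons.t_refrac_end,
            float(cp.th_plus), float(cp.th_minus), float(cp.memb_reset),
            cp.leak_rate_plus, cp.leak_rate_minus,
            cp.emit_negative, np.int64(cp.refractory_us),
            np.int64(pool.factor), pool.mode == "accumulate",
            np.int64(pool.m), pool._counters,
            np.int64(flatten.side),
            W, f_vm, f_tlast, f_tref, *fc_args,
            fc is not None, out_fl, out_fc)
        if not overflow:
            break
        # restore pre-run state and retry with bigger buffers
        conv.neurons.vm[:] = saved[0]
        conv.neurons.t_last[:] = saved[1]
        conv.neurons.t_refrac_end[:] = saved[2]
        pool._counters[:] = saved[3]
        f_vm[:] = saved[4]
        f_tlast[:] = saved[5]
        f_tref[:] = saved[6]
        cap_fl *= 4
        cap_fc *= 4
    return {
        "flatten": out_fl[:n_fl],
        "fc": out_fc[:n_fc],
        "counts": {"input": len(events), "c1": int(n_c1), "s1": int(n_s1),
                   "flatten": int(n_fl), "fc": int(n_fc)},
    }
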