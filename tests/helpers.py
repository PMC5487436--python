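"""Shared test utilities: random stream construction and the clock-driven
reference integrator used as the independent oracle for the event-driven
neuron model."""

import numpy as np

from evsnn.aer import EventStream


def random_stream(rng, n_events=50, width=8, height=8, duration=1000,
                  signed=True):
    """A random but valid event stream for property tests."""
    t = np.sort(rng.integers(0, duration, n_events))
    x = rng.integers(0, width, n_events)
    y = rng.integers(0, height, n_events)
    sign = rng.choice([-1, 1], n_events) if signed \
        else np.ones(n_events, dtype=np.int64)
    fm = np.full(n_events, -1, dtype=np.int64)
    data = np.stack([t, x, y, sign, fm], axis=1).astype(np.int64)
    return EventStream(data, width, height, duration)


def euler_lif(params, events, resolution_us=1):
    """Clock-driven reference integrator of the linear-leak LIF.

    Steps the membrane at a fixed resolution, applying the constant leak
    rate and clamping at rest; each event's weighted input is delivered at
    its timestamp under the same threshold/reset/refractory rules as the
    event-driven model.  ``events`` is a list of (t, weight, sign) with
    integer multiples of the resolution as times; returns the emitted
    (t, sign) spikes and the membrane value right after each event.
    """
    vm = float(params.memb_reset)
    rest = float(params.memb_reset)
    t_ref_end = 0
    out = []
    vm_at_events = []
    events = sorted(events, key=lambda e: e[0])
    t_end = events[-1][0] if events else 0
    ev_idx = 0
    t_now = 0
    while t_now <= t_end:
        while ev_idx < len(events) and events[ev_idx][0] == t_now:
            t, w, s = events[ev_idx]
            ev_idx += 1
            if t_now >= t_ref_end:
                vm += s * w
                if vm >= params.th_plus:
                    vm = rest
                    t_ref_end = t_now + params.refractory_us
                    out.append((t_now, 1))
                elif vm <= params.th_minus:
                    vm = rest
                    t_ref_end = t_now + params.refractory_us
                    if params.emit_negative:
                        out.append((t_now, -1))
            vm_at_events.append(vm)
        if vm > rest and params.tl_plus:
            vm = max(rest, vm - resolution_us * params.leak_rate_plus)
        elif vm < rest and params.tl_minus:
            vm = min(rest, vm + resolution_us * params.leak_rate_minus)
        t_now += resolution_us
    return out, vm_at_events
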