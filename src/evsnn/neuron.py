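"""Event-driven signed leaky integrate-and-fire neuron with linear leakage.

The neuron state is only touched when an event arrives: the linear leak
accrued since the last update is applied first, then the synaptic weight is
added instantaneously (delta-Dirac synapse).  Between events the membrane
decays toward the resting level ``memb_reset`` at a constant rate
``(th_plus - memb_reset) / tl_plus`` when above rest and
``(memb_reset - th_minus) / tl_minus`` when below, clamping at rest.

Crossing ``th_plus`` emits a +1 spike and resets to rest; crossing
``th_minus`` resets as well and emits a -1 spike only when
``emit_negative`` is set (the degenerate positive-only variant used for the
classifier layer silently resets or, with the sentinel negative threshold,
never resets from below).

Numerical representation: membranes are float64 while weights and thresholds
are integers.  Every event update is therefore exact (integers below 2^53
are exactly representable); the leak alone introduces sub-unit fractional
parts, which tracks the continuous linear-leak trajectory instead of
accumulating a per-interval rounding bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["NeuronParams", "NeuronState", "NeuronArray", "apply_leak", "receive"]

#: sentinel negative threshold that disables below-rest reset entirely
TH_MINUS_DISABLED = -(2**31)


@dataclass(frozen=True)
class NeuronParams:
    """Shared parameter block of one layer of LIF neurons.

    Parameters
    ----------
    th_plus : int
        Positive firing threshold (membrane units).
    th_minus : int
        Negative threshold; reaching it always resets the membrane to rest
        (a -1 spike is emitted only when ``emit_negative`` is set).  The
        conventional value ``-2**31`` — the numerical-precision limit —
        makes the layer behave as a positive-only LIF whose membrane is
        bounded below; with that value the below-rest leak rate mirrors the
        above-rest magnitude rather than the astronomically large literal.
    tl_plus, tl_minus : int
        Linear-leak time constants in microseconds: the time for a membrane
        at threshold to decay to rest.  ``0`` disables leakage (the
        sample-by-sample regime).
    memb_reset : int
        Resting / post-spike membrane level.
    refractory_us : int
        Events arriving within this window after a spike are discarded.
    emit_negative : bool
        Whether a below-rest reset communicates a -1 spike.
    """

    th_plus: int
    th_minus: int = TH_MINUS_DISABLED
    tl_plus: int = 0
    tl_minus: int = 0
    memb_reset: int = 0
    refractory_us: int = 0
    emit_negative: bool = False

    def __post_init__(self):
        if not (self.th_plus > self.memb_reset):
            raise ValueError("th_plus must exceed memb_reset")
        if not (self.th_minus < self.memb_reset):
            raise ValueError("th_minus must lie below memb_reset")
        if self.tl_plus < 0 or self.tl_minus < 0:
            raise ValueError("leak time constants must be >= 0 (0 = no leak)")

    @property
    def th_minus_effective(self) -> int:
        """Negative threshold magnitude used for the below-rest leak rate."""
        if self.th_minus == TH_MINUS_DISABLED:
            return 2 * self.memb_reset - self.th_plus  # symmetric magnitude
        return self.th_minus

    @property
    def leak_rate_plus(self) -> float:
        return (self.th_plus - self.memb_reset) / self.tl_plus if self.tl_plus else 0.0

    @property
    def leak_rate_minus(self) -> float:
        if not self.tl_minus:
            return 0.0
        return (self.memb_reset - self.th_minus_effective) / self.tl_minus


@dataclass
class NeuronState:
    """Dynamic state of a single neuron."""

    vm: float = 0.0
    t_last: int = 0
    t_refrac_end: int = 0


def apply_leak(state: NeuronState, params: NeuronParams, t_now: int) -> NeuronState:
    """Advance the membrane to ``t_now`` under leakage only (in place)."""
    if t_now < state.t_last:
        raise ValueError("time must not run backwards")
    elapsed = t_now - state.t_last
    rest = params.memb_reset
    if elapsed > 0:
        if state.vm > rest and params.tl_plus:
            state.vm = max(rest, state.vm - elapsed * params.leak_rate_plus)
        elif state.vm < rest and params.tl_minus:
            state.vm = min(rest, state.vm + elapsed * params.leak_rate_minus)
    state.t_last = t_now
    return state


def receive(state: NeuronState, params: NeuronParams, weight: int, sign: int,
            t_now: int) -> tuple[NeuronState, Optional[int]]:
    """Deliver one weighted input spike; return the emitted spike sign if any.

    Leak is applied first; inside the refractory window the input is
    discarded.  The input spike sign combines multiplicatively with the
    synaptic weight sign to set the update direction.
    """
    apply_leak(state, params, t_now)
    if t_now < state.t_refrac_end:
        return state, None
    state.vm += sign * weight
    if state.vm >= params.th_plus:
        state.vm = params.memb_reset
        state.t_refrac_end = t_now + params.refractory_us
        return state, 1
    if state.vm <= params.th_minus:
        # the sentinel -2**31 is simply a very large threshold (the
        # numerical-precision limit): reaching it still resets, bounding
        # how far below rest a membrane can travel
        state.vm = params.memb_reset
        state.t_refrac_end = t_now + params.refractory_us
        return state, -1 if params.emit_negative else None
    return state, None


class NeuronArray:
    """Vectorized bank of LIF neurons sharing one parameter block.

    Used by the convolutional and fully-connected layers, which update many
    neurons per incoming event.  Semantics are identical to the scalar
    :func:`receive` path (tested for equivalence).
    """

    def __init__(self, shape: tuple[int, ...], params: NeuronParams):
        self.shape = shape
        self.params = params
        self.vm = np.full(shape, float(params.memb_reset), dtype=np.float64)
        self.t_last = np.zeros(shape, dtype=np.int64)
        self.t_refrac_end = np.zeros(shape, dtype=np.int64)

    def reset(self) -> None:
        self.vm.fill(self.params.memb_reset)
        self.t_last.fill(0)
        self.t_refrac_end.fill(0)

    def leak(self, idx, t_now: int) -> None:
        """Apply leakage to the sub-array ``idx`` up to ``t_now``."""
        p = self.params
        vm = self.vm[idx]
        elapsed = t_now - self.t_last[idx]
        if p.tl_plus:
            above = vm > p.memb_reset
            if np.any(above):
                vm = np.where(
                    above,
                    np.maximum(p.memb_reset, vm - elapsed * p.leak_rate_plus),
                    vm,
                )
        if p.tl_minus:
            below = vm < p.memb_reset
            if np.any(below):
                vm = np.where(
                    below,
                    np.minimum(p.memb_reset, vm + elapsed * p.leak_rate_minus),
                    vm,
                )
        self.vm[idx] = vm
        self.t_last[idx] = t_now

    def inject(self, idx, weights: np.ndarray, sign: int, t_now: int
               ) -> tuple[np.ndarray, np.ndarray]:
        """Leak then add ``sign * weights`` to the sub-array ``idx``.

        Returns boolean masks ``(fired_pos, fired_neg)`` over the sub-array;
        fired neurons are reset and their refractory window started.
        Events inside a refractory window are discarded.
        """
        p = self.params
        self.leak(idx, t_now)
        vm = self.vm[idx]
        open_mask = t_now >= self.t_refrac_end[idx]
        vm = np.where(open_mask, vm + sign * weights, vm)
        fired_pos = vm >= p.th_plus
        fired_neg = vm <= p.th_minus
        fired = fired_pos | fired_neg
        vm = np.where(fired, p.memb_reset, vm)
        self.vm[idx] = vm
        if p.refractory_us:
            refrac = self.t_refrac_end[idx]
            self.t_refrac_end[idx] = np.where(fired, t_now + p.refractory_us,
                                              refrac)
        return fired_pos, fired_neg
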