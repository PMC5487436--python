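"""Event-driven simulation kernel.

The simulator dispatches address-events through a netlist of modules
interconnected by AER links ("nodes").  Source nodes are preloaded with
timestamped events; every other node is the output of exactly one module.
The kernel repeatedly picks the globally earliest *unprocessed* event,
marks it processed, and hands it to the consumer modules of its node; any
events a module emits are queued on its output node with
``pre_rqst = now`` and a request time of ``now + processing delay``.

Each processed event keeps the (pre-request, request, acknowledge) timing
triple of the AER handshake; an event is unprocessed while its request and
acknowledge times are -1.  Simultaneous events are ordered deterministically
by node registration order, then first-in-first-out within a node.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Protocol, Sequence

import numpy as np

from .aer import EventStream

__all__ = ["Netlist", "Node", "ProcessedEvent", "LivelockError"]

UNPROCESSED = -1


class LivelockError(RuntimeError):
    """Raised when the processed-event budget is exhausted (e.g. a
    zero-delay cycle keeps generating events)."""


class ProcessedEvent(NamedTuple):
    """One event after dispatch, with its AER handshake timing triple."""

    pre_rqst: int
    rqst: int
    ack: int
    payload: tuple  # (x, y, sign, fm)


class Processor(Protocol):
    def process(self, t: int, payload: tuple) -> Sequence[tuple]:
        ...


@dataclass
class Node:
    """An AER link: a queue of pending events plus the processed record."""

    name: str
    index: int
    pending: int = 0
    processed: list[ProcessedEvent] = field(default_factory=list)

    def to_stream(self, width: int, height: int,
                  duration: Optional[int] = None) -> EventStream:
        """View the processed record as an :class:`EventStream`."""
        rows = [(ev.rqst,) + ev.payload for ev in self.processed]
        data = np.array(rows, dtype=np.int64).reshape(-1, 5)
        if duration is None:
            duration = int(data[:, 0].max()) + 1 if len(data) else 0
        return EventStream(data, width, height, duration)


class _FnModule:
    """Adapter wrapping a plain callback ``fn(t, payload) -> [payload, ...]``."""

    def __init__(self, fn: Callable[[int, tuple], Sequence[tuple]]):
        self.fn = fn

    def process(self, t: int, payload: tuple) -> Sequence[tuple]:
        return self.fn(t, payload)


class Netlist:
    """A directed netlist of processing modules linked by AER nodes."""

    def __init__(self):
        self.nodes: list[Node] = []
        self._heap: list[tuple[int, int, int]] = []  # (t, node index, seq)
        self._payloads: dict[tuple[int, int, int], tuple[int, tuple]] = {}
        self._seq = itertools.count()
        # node index -> list of (module, delay, output node index)
        self._consumers: dict[int, list[tuple[Processor, int, int]]] = {}

    # -- construction ------------------------------------------------------

    def _new_node(self, name: str) -> Node:
        node = Node(name=name, index=len(self.nodes))
        self.nodes.append(node)
        return node

    def add_source(self, name: str, events) -> Node:
        """Register a source node preloaded with timestamped events.

        ``events`` is an :class:`EventStream` or an iterable of
        ``(t, x, y, sign, fm)`` rows.
        """
        node = self._new_node(name)
        if isinstance(events, EventStream):
            rows = [tuple(int(v) for v in row) for row in events.data]
        else:
            rows = [tuple(int(v) for v in row) for row in events]
        for row in rows:
            t, payload = row[0], row[1:]
            self._queue(node.index, pre_rqst=t, t_avail=t, payload=payload)
        return node

    def add_module(self, name: str, processor, input_node: Node,
                   delay: int = 0) -> Node:
        """Attach a module consuming ``input_node``; returns its output node.

        ``processor`` is either an object with ``process(t, payload)`` or a
        plain callable ``fn(t, payload) -> sequence of payloads``.
        """
        if delay < 0:
            raise ValueError("processing delay must be >= 0")
        if not hasattr(processor, "process"):
            processor = _FnModule(processor)
        out = self._new_node(name)
        self._consumers.setdefault(input_node.index, []).append(
            (processor, delay, out.index))
        return out

    # -- dispatch ----------------------------------------------------------

    def _queue(self, node_idx: int, pre_rqst: int, t_avail: int,
               payload: tuple) -> None:
        key = (t_avail, node_idx, next(self._seq))
        heapq.heappush(self._heap, key)
        self._payloads[key] = (pre_rqst, payload)
        self.nodes[node_idx].pending += 1

    def run(self, t_max: Optional[int] = None,
            max_events: int = 50_000_000) -> dict[str, list[ProcessedEvent]]:
        """Dispatch events until exhaustion or past ``t_max``.

        Returns the per-node processed event lists keyed by node name.
        Raises :class:`LivelockError` once ``max_events`` events have been
        processed, guarding against zero-delay generation cycles.
        """
        n_processed = 0
        while self._heap:
            t_avail = self._heap[0][0]
            if t_max is not None and t_avail > t_max:
                break
            key = heapq.heappop(self._heap)
            t_avail, node_idx, _ = key
            pre_rqst, payload = self._payloads.pop(key)
            node = self.nodes[node_idx]
            node.pending -= 1
            node.processed.append(
                ProcessedEvent(pre_rqst, t_avail, t_avail, payload))
            n_processed += 1
            if n_processed > max_events:
                raise LivelockError(
                    f"processed-event budget of {max_events} exhausted")
            for module, delay, out_idx in self._consumers.get(node_idx, ()):
                for out_payload in module.process(t_avail, payload):
                    self._queue(out_idx, pre_rqst=t_avail,
                                t_avail=t_avail + delay,
                                payload=tuple(out_payload))
        return {node.name: node.processed for node in self.nodes}
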