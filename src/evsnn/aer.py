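"""Address-Event Representation (AER) data model and I/O.

Spikes are timestamped (t, x, y, sign) tuples, optionally tagged with a
feature-map index once they originate inside the network.  Conventions used
throughout the package:

* coordinates are 0-based, ``x`` is the column, ``y`` the row, origin top-left;
* timestamps are integer microseconds since the stream origin;
* time windows are half-open ``[t_start, t_end)``;
* ``sign`` is +1 (ON) or -1 (OFF).

The canonical interchange format is ``ev-csv``: a UTF-8, LF-terminated text
file with a ``# width=<w> height=<h> duration_us=<d>`` header, optional
``# sample=<label>,<t0>,<t1>`` annotation lines, and one ``t,x,y,sign[,fm]``
row per event.  Readers for the 5-byte N-MNIST binary format and the 8-byte
jAER DAT2.0 (DVS128) format are provided for real recordings.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "Event",
    "EventStream",
    "SampleSet",
    "read_events",
    "write_events",
    "slice_stream",
    "concat_op_stream",
    "split_op_stream",
]

# column layout of EventStream.data
T, X, Y, SIGN, FM = range(5)
NO_FM = -1  # sensor/input events carry no feature-map index


class Event(NamedTuple):
    """A single AER spike."""

    t: int
    x: int
    y: int
    sign: int
    fm: int = NO_FM


class SampleWindow(NamedTuple):
    """Boundary annotation of one sample inside a continuous stream."""

    label: int
    t_start: int
    t_end: int


class AERFormatError(ValueError):
    """Malformed AER file; message names the offending line or byte offset."""


@dataclass
class EventStream:
    """A time-sorted sequence of events with geometry metadata.

    Parameters
    ----------
    data : ndarray of shape (n_events, 5), int64
        Columns ``t, x, y, sign, fm`` (``fm = -1`` for sensor events).
    width, height : int
        Geometry of the address space.
    duration : int
        Stream duration in microseconds; events lie in ``[0, duration]``.
    samples : list of SampleWindow, optional
        Non-overlapping, ordered per-sample boundary annotations.
    """

    data: np.ndarray
    width: int
    height: int
    duration: int
    samples: list[SampleWindow] = field(default_factory=list)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_events(
        cls,
        events: Iterable[tuple],
        width: int,
        height: int,
        duration: Optional[int] = None,
        samples: Optional[Sequence[SampleWindow]] = None,
        sort: bool = True,
    ) -> "EventStream":
        rows = [tuple(e) + (NO_FM,) * (5 - len(tuple(e))) for e in events]
        data = np.array(rows, dtype=np.int64).reshape(-1, 5)
        if duration is None:
            duration = int(data[:, T].max()) + 1 if len(data) else 0
        stream = cls(data, int(width), int(height), int(duration),
                     list(samples) if samples else [])
        if sort:
            stream = stream.sorted()
        stream.validate()
        return stream

    @classmethod
    def empty(cls, width: int, height: int, duration: int = 0) -> "EventStream":
        return cls(np.empty((0, 5), dtype=np.int64), width, height, duration)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return self.data.shape[0]

    def __iter__(self) -> Iterator[Event]:
        for row in self.data:
            yield Event(*(int(v) for v in row))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.width == other.width
            and self.height == other.height
            and self.duration == other.duration
            and self.samples == other.samples
            and self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
        )

    @property
    def t(self) -> np.ndarray:
        return self.data[:, T]

    @property
    def sign(self) -> np.ndarray:
        return self.data[:, SIGN]

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        d = self.data
        if len(d) == 0:
            return
        if d[:, T].min() < 0 or d[:, T].max() > self.duration:
            raise ValueError("event timestamps outside [0, duration]")
        if np.any(d[:, T][1:] < d[:, T][:-1]):
            raise ValueError("events not sorted by timestamp")
        if d[:, X].min() < 0 or d[:, X].max() >= self.width:
            raise ValueError("x coordinate outside declared geometry")
        if d[:, Y].min() < 0 or d[:, Y].max() >= self.height:
            raise ValueError("y coordinate outside declared geometry")
        if not np.all(np.isin(d[:, SIGN], (-1, 1))):
            raise ValueError("sign must be +1 or -1")
        prev_end = 0
        for w in self.samples:
            if w.t_start < prev_end:
                raise ValueError("sample windows overlap or are unordered")
            prev_end = w.t_end

    # -- transforms --------------------------------------------------------

    def sorted(self) -> "EventStream":
        """Stable sort by timestamp; ties keep input order."""
        order = np.argsort(self.data[:, T], kind="stable")
        return replace(self, data=self.data[order])

    def shifted(self, dt: int) -> "EventStream":
        data = self.data.copy()
        data[:, T] += dt
        samples = [SampleWindow(w.label, w.t_start + dt, w.t_end + dt)
                   for w in self.samples]
        return replace(self, data=data, duration=self.duration + dt,
                       samples=samples)

    def window(self, t_start: int, t_end: int, retime: bool = True) -> "EventStream":
        """Events with ``t_start <= t < t_end``, optionally re-timed to 0."""
        lo = int(np.searchsorted(self.data[:, T], t_start, side="left"))
        hi = int(np.searchsorted(self.data[:, T], t_end, side="left"))
        data = self.data[lo:hi].copy()
        if retime:
            data[:, T] -= t_start
        return EventStream(data, self.width, self.height,
                           t_end - t_start if retime else self.duration)

    def rectified(self) -> "EventStream":
        """All polarities mapped to +1 (for pipelines that ignore OFF sign)."""
        data = self.data.copy()
        data[:, SIGN] = 1
        return replace(self, data=data)


@dataclass
class SampleSet:
    """Labeled samples, either one stream per sample (SBS) or sliced views.

    ``items`` holds ``(EventStream, label)`` pairs sharing geometry;
    ``partial`` flags trailing slices shorter than the nominal slice length.
    """

    items: list[tuple[EventStream, int]]
    class_count: int
    partial: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


# ---------------------------------------------------------------------------
# ev-csv I/O
# ---------------------------------------------------------------------------

def _write_ev_csv(stream: EventStream, fh: io.TextIOBase) -> None:
    fh.write(f"# width={stream.width} height={stream.height} "
             f"duration_us={stream.duration}\n")
    for w in stream.samples:
        fh.write(f"# sample={w.label},{w.t_start},{w.t_end}\n")
    has_fm = len(stream) > 0 and bool(np.any(stream.data[:, FM] != NO_FM))
    for row in stream.data:
        line = f"{row[T]},{row[X]},{row[Y]},{row[SIGN]}"
        if has_fm:
            line += f",{row[FM]}"
        fh.write(line + "\n")


def _read_ev_csv(fh: io.TextIOBase) -> EventStream:
    width = height = duration = None
    samples: list[SampleWindow] = []
    rows: list[tuple[int, ...]] = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("sample="):
                try:
                    label, t0, t1 = (int(v) for v in body[7:].split(","))
                except ValueError as exc:
                    raise AERFormatError(
                        f"line {lineno}: bad sample annotation {body!r}") from exc
                samples.append(SampleWindow(label, t0, t1))
            else:
                for tok in body.split():
                    if "=" in tok:
                        key, _, val = tok.partition("=")
                        if key == "width":
                            width = int(val)
                        elif key == "height":
                            height = int(val)
                        elif key == "duration_us":
                            duration = int(val)
            continue
        parts = line.split(",")
        if len(parts) not in (4, 5):
            raise AERFormatError(f"line {lineno}: expected 4 or 5 fields, "
                                 f"got {len(parts)}")
        try:
            vals = tuple(int(p) for p in parts)
        except ValueError as exc:
            raise AERFormatError(f"line {lineno}: non-integer field in "
                                 f"{line!r}") from exc
        rows.append(vals if len(vals) == 5 else vals + (NO_FM,))
    if width is None or height is None:
        raise AERFormatError("missing geometry header "
                             "('# width=<w> height=<h> duration_us=<d>')")
    data = np.array(rows, dtype=np.int64).reshape(-1, 5)
    order = np.argsort(data[:, T], kind="stable")
    data = data[order]
    if duration is None:
        duration = int(data[:, T].max()) + 1 if len(data) else 0
    stream = EventStream(data, width, height, duration, samples)
    stream.validate()
    return stream


# ---------------------------------------------------------------------------
# N-MNIST binary (5 bytes / event)
# ---------------------------------------------------------------------------
# byte 0: x; byte 1: y; byte 2: bit 7 = polarity (1 = ON), bits 6..0 =
# timestamp bits 22..16; bytes 3-4: timestamp bits 15..0.  Timestamps in us.

def _read_nmnist(fh: io.BufferedIOBase, width: int, height: int) -> EventStream:
    raw = fh.read()
    if len(raw) % 5:
        raise AERFormatError(f"byte offset {len(raw) - len(raw) % 5}: "
                             "truncated 5-byte event record")
    arr = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 5).astype(np.int64)
    x = arr[:, 0]
    y = arr[:, 1]
    pol = (arr[:, 2] >> 7) & 1
    t = ((arr[:, 2] & 0x7F) << 16) | (arr[:, 3] << 8) | arr[:, 4]
    sign = np.where(pol == 1, 1, -1)
    fm = np.full_like(t, NO_FM)
    data = np.stack([t, x, y, sign, fm], axis=1)
    data = data[np.argsort(data[:, T], kind="stable")]
    duration = int(data[:, T].max()) + 1 if len(data) else 0
    stream = EventStream(data, width, height, duration)
    stream.validate()
    return stream


def _write_nmnist(stream: EventStream, fh: io.BufferedIOBase) -> None:
    for row in stream.data:
        t = int(row[T])
        if t >= 1 << 23:
            raise AERFormatError("timestamp exceeds 23-bit N-MNIST range")
        pol = 1 if row[SIGN] > 0 else 0
        fh.write(bytes([int(row[X]) & 0xFF, int(row[Y]) & 0xFF,
                        (pol << 7) | ((t >> 16) & 0x7F),
                        (t >> 8) & 0xFF, t & 0xFF]))


# ---------------------------------------------------------------------------
# jAER DAT2.0 / DVS128 (8 bytes / event, big-endian)
# ---------------------------------------------------------------------------
# 32-bit address: bit 0 = polarity (1 = OFF), bits 1-7 = x, bits 8-14 = y;
# 32-bit timestamp in us.  ASCII '#' header lines precede the binary body.

def _read_aedat(fh: io.BufferedIOBase, width: int, height: int) -> EventStream:
    # skip ASCII header lines
    offset = 0
    while True:
        pos = fh.tell()
        line = fh.readline()
        if line.startswith(b"#"):
            offset = fh.tell()
            continue
        fh.seek(pos)
        break
    raw = fh.read()
    if len(raw) % 8:
        raise AERFormatError(f"byte offset {offset + len(raw) - len(raw) % 8}: "
                             "truncated 8-byte AEDAT record")
    arr = np.frombuffer(raw, dtype=">u4").reshape(-1, 2).astype(np.int64)
    addr, t = arr[:, 0], arr[:, 1]
    pol = addr & 1
    x = (addr >> 1) & 0x7F
    y = (addr >> 8) & 0x7F
    sign = np.where(pol == 1, -1, 1)  # jAER DVS128: polarity bit set = OFF
    fm = np.full_like(t, NO_FM)
    data = np.stack([t, x, y, sign, fm], axis=1)
    data = data[np.argsort(data[:, T], kind="stable")]
    duration = int(data[:, T].max()) + 1 if len(data) else 0
    stream = EventStream(data, width, height, duration)
    stream.validate()
    return stream


def _write_aedat(stream: EventStream, fh: io.BufferedIOBase) -> None:
    fh.write(b"#!AER-DAT2.0\n")
    for row in stream.data:
        pol = 0 if row[SIGN] > 0 else 1
        addr = ((int(row[Y]) & 0x7F) << 8) | ((int(row[X]) & 0x7F) << 1) | pol
        fh.write(struct.pack(">II", addr, int(row[T])))


_FORMATS = {"ev-csv", "nmnist-bin", "aedat"}


def read_events(path, format_id: str = "ev-csv", *, width: int = 34,
                height: int = 34, rectify: bool = False) -> EventStream:
    """Read an event file into a sorted :class:`EventStream`.

    ``width``/``height`` are only used by the binary formats, whose records
    carry no geometry; ``rectify=True`` maps OFF events to sign +1.
    """
    if format_id not in _FORMATS:
        raise ValueError(f"unknown format {format_id!r}; expected one of "
                         f"{sorted(_FORMATS)}")
    if format_id == "ev-csv":
        with open(path, "r", encoding="utf-8") as fh:
            stream = _read_ev_csv(fh)
    elif format_id == "nmnist-bin":
        with open(path, "rb") as fh:
            stream = _read_nmnist(fh, width, height)
    else:
        with open(path, "rb") as fh:
            stream = _read_aedat(fh, width, height)
    return stream.rectified() if rectify else stream


def write_events(stream: EventStream, path, format_id: str = "ev-csv") -> None:
    """Write a stream to disk; ``read_events`` round-trips ev-csv exactly."""
    if format_id not in _FORMATS:
        raise ValueError(f"unknown format {format_id!r}; expected one of "
                         f"{sorted(_FORMATS)}")
    if format_id == "ev-csv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            _write_ev_csv(stream, fh)
    elif format_id == "nmnist-bin":
        with open(path, "wb") as fh:
            _write_nmnist(stream, fh)
    else:
        with open(path, "wb") as fh:
            _write_aedat(stream, fh)


# ---------------------------------------------------------------------------
# Slicing and one-pass concatenation
# ---------------------------------------------------------------------------

def slice_stream(stream: EventStream, slice_len_us: int,
                 label: int = 0, class_count: int = 1) -> SampleSet:
    """Cut a stream into consecutive non-overlapping fixed-length slices.

    Each slice is re-timed to start at 0; a trailing partial slice is kept
    and flagged in ``SampleSet.partial``.
    """
    if slice_len_us <= 0:
        raise ValueError("slice_len_us must be positive")
    items: list[tuple[EventStream, int]] = []
    partial: list[bool] = []
    n_slices = max(1, -(-stream.duration // slice_len_us))
    for i in range(n_slices):
        t0 = i * slice_len_us
        t1 = min(t0 + slice_len_us, stream.duration)
        items.append((stream.window(t0, t1), label))
        partial.append(t1 - t0 < slice_len_us)
    return SampleSet(items, class_count, partial)


def concat_op_stream(samples: Sequence[tuple[EventStream, int]],
                     gap_us: int = 0) -> EventStream:
    """Concatenate labeled samples into one annotated One-Pass stream.

    Sample ``i`` is offset by the cumulative duration of its predecessors
    plus ``i * gap_us``; boundary annotations record each sample's window.
    """
    if gap_us < 0:
        raise ValueError("gap_us must be non-negative")
    seq = list(samples)
    if not seq:
        raise ValueError("no samples to concatenate")
    width, height = seq[0][0].width, seq[0][0].height
    chunks: list[np.ndarray] = []
    windows: list[SampleWindow] = []
    offset = 0
    for i, (s, label) in enumerate(seq):
        if (s.width, s.height) != (width, height):
            raise ValueError("samples must share geometry")
        chunk = s.data.copy()
        chunk[:, T] += offset
        chunks.append(chunk)
        windows.append(SampleWindow(label, offset, offset + s.duration))
        offset += s.duration + gap_us
    total = windows[-1].t_end
    data = np.concatenate(chunks) if chunks else np.empty((0, 5), np.int64)
    return EventStream(data, width, height, total, windows)


def split_op_stream(stream: EventStream,
                    class_count: Optional[int] = None) -> SampleSet:
    """Invert :func:`concat_op_stream` using the boundary annotations."""
    if not stream.samples:
        raise ValueError("stream carries no sample annotations")
    items = [(stream.window(w.t_start, w.t_end), w.label)
             for w in stream.samples]
    if class_count is None:
        class_count = max(w.label for w in stream.samples) + 1
    return SampleSet(items, class_count, [False] * len(items))
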