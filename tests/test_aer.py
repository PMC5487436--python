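"""AER data model, canonical ev-csv I/O, binary readers, slicing and
one-pass concatenation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evsnn.aer import (AERFormatError, EventStream, SampleWindow,
                       concat_op_stream, read_events, slice_stream,
                       split_op_stream, write_events, _write_nmnist,
                       _write_aedat)
from helpers import random_stream


def test_read_ev_csv_basic(tmp_path):
    path = tmp_path / "ev.csv"
    path.write_text("# width=4 height=4 duration_us=10\n"
                    "0,1,2,1\n5,0,0,-1\n")
    s = read_events(path)
    assert len(s) == 2
    assert s.duration >= 5
    assert list(s)[0].x == 1 and list(s)[1].sign == -1


def test_read_ev_csv_empty_body(tmp_path):
    path = tmp_path / "ev.csv"
    path.write_text("# width=32 height=32 duration_us=0\n")
    s = read_events(path)
    assert len(s) == 0 and (s.width, s.height) == (32, 32)


def test_read_sorts_shuffled_input(tmp_path, rng):
    stream = random_stream(rng, n_events=100)
    rows = stream.data.copy()
    rng.shuffle(rows, axis=0)
    path = tmp_path / "ev.csv"
    with open(path, "w") as fh:
        fh.write(f"# width=8 height=8 duration_us={stream.duration}\n")
        for r in rows:
            fh.write(f"{r[0]},{r[1]},{r[2]},{r[3]}\n")
    out = read_events(path)
    # sorted, and the event multiset is unchanged
    assert np.all(np.diff(out.t) >= 0)
    key = lambda d: sorted(map(tuple, d[:, :4]))
    assert key(out.data) == key(stream.data)


def test_stable_sort_keeps_tie_order():
    s = EventStream.from_events(
        [(5, 0, 0, 1), (5, 1, 0, 1), (0, 2, 0, 1), (5, 3, 0, 1)], 4, 1)
    xs_at_5 = [e.x for e in s if e.t == 5]
    assert xs_at_5 == [0, 1, 3]


def test_ev_csv_round_trip_exact(tmp_path, rng):
    stream = random_stream(rng, n_events=1000, duration=100_000)
    path = tmp_path / "rt.csv"
    write_events(stream, path)
    assert read_events(path) == stream


@settings(derandomize=True, max_examples=30, deadline=None)
@given(events=st.lists(
    st.tuples(st.integers(0, 10**6), st.integers(0, 15), st.integers(0, 15),
              st.sampled_from([-1, 1])),
    max_size=60))
def test_ev_csv_round_trip_property(events):
    """Any valid stream survives write -> read bit-exactly."""
    stream = EventStream.from_events(events, 16, 16)
    import tempfile, os

    fd, path = tempfile.mkstemp(suffix=".csv")
    os.close(fd)
    try:
        write_events(stream, path)
        assert read_events(path) == stream
    finally:
        os.unlink(path)


def test_ev_csv_round_trip_with_annotations_and_fm(tmp_path):
    data = np.array([[0, 1, 0, 1, 3], [7, 2, 1, -1, 0]], dtype=np.int64)
    stream = EventStream(data, 4, 4, 10,
                         [SampleWindow(0, 0, 5), SampleWindow(1, 5, 10)])
    path = tmp_path / "rt.csv"
    write_events(stream, path)
    assert read_events(path) == stream


def test_empty_stream_writes_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_events(EventStream.empty(5, 6, 9), path)
    lines = path.read_text().splitlines()
    assert lines == ["# width=5 height=6 duration_us=9"]


@pytest.mark.parametrize("body,msg", [
    ("0,1,2\n", "line 2"),
    ("0,a,2,1\n", "line 2"),
])
def test_malformed_rows_name_the_line(tmp_path, body, msg):
    path = tmp_path / "bad.csv"
    path.write_text("# width=4 height=4 duration_us=10\n" + body)
    with pytest.raises(AERFormatError, match=msg):
        read_events(path)


def test_out_of_geometry_rejected(tmp_path):
    path = tmp_path / "oob.csv"
    path.write_text("# width=4 height=4 duration_us=10\n0,4,0,1\n")
    with pytest.raises(ValueError, match="geometry"):
        read_events(path)


def test_missing_header_rejected(tmp_path):
    path = tmp_path / "nohdr.csv"
    path.write_text("0,1,2,1\n")
    with pytest.raises(AERFormatError, match="geometry header"):
        read_events(path)


# -- binary formats ---------------------------------------------------------

def test_nmnist_round_trip(tmp_path, rng):
    stream = random_stream(rng, n_events=200, width=34, height=34,
                           duration=300_000)
    path = tmp_path / "sample.bin"
    with open(path, "wb") as fh:
        _write_nmnist(stream, fh)
    assert path.stat().st_size == 5 * len(stream)
    out = read_events(path, "nmnist-bin", width=34, height=34)
    key = lambda d: sorted(map(tuple, d[:, :4]))
    assert key(out.data) == key(stream.data)


def test_nmnist_known_bytes(tmp_path):
    # x=3, y=7, ON polarity, t=0x012345 us
    path = tmp_path / "one.bin"
    path.write_bytes(bytes([3, 7, 0x80 | 0x01, 0x23, 0x45]))
    s = read_events(path, "nmnist-bin", width=34, height=34)
    e = list(s)[0]
    assert (e.t, e.x, e.y, e.sign) == (0x012345, 3, 7, 1)


def test_nmnist_truncated_record_names_offset(tmp_path):
    path = tmp_path / "bad.bin"
    path.write_bytes(bytes(7))
    with pytest.raises(AERFormatError, match="byte offset 5"):
        read_events(path, "nmnist-bin")


def test_aedat_round_trip(tmp_path, rng):
    stream = random_stream(rng, n_events=150, width=128, height=128,
                           duration=1_000_000)
    path = tmp_path / "rec.aedat"
    with open(path, "wb") as fh:
        _write_aedat(stream, fh)
    out = read_events(path, "aedat", width=128, height=128)
    key = lambda d: sorted(map(tuple, d[:, :4]))
    assert key(out.data) == key(stream.data)


def test_rectify_maps_off_events_positive(tmp_path, rng):
    stream = random_stream(rng, n_events=100)
    path = tmp_path / "r.csv"
    write_events(stream, path)
    out = read_events(path, rectify=True)
    assert np.all(out.sign == 1)
    assert len(out) == len(stream)


# -- slicing / concatenation ------------------------------------------------

def test_slice_counts():
    # 300 ms recording in 100 ms slots -> 3 slices
    data = np.array([[t, 0, 0, 1, -1] for t in range(0, 300_000, 1000)],
                    dtype=np.int64)
    s = EventStream(data, 2, 2, 300_000)
    ss = slice_stream(s, 100_000)
    assert len(ss) == 3
    assert ss.partial == [False, False, False]


def test_slice_longer_than_stream():
    s = EventStream.from_events([(0, 0, 0, 1)], 2, 2, duration=100)
    ss = slice_stream(s, 1000)
    assert len(ss) == 1
    assert ss.partial == [True]
    assert len(ss.items[0][0]) == 1


def test_slice_uniform_counting_oracle():
    # one event per ms over 10 ms, 2 ms slices -> 5 slices of 2 events
    data = np.array([[t * 1000, 0, 0, 1, -1] for t in range(10)],
                    dtype=np.int64)
    s = EventStream(data, 1, 1, 10_000)
    ss = slice_stream(s, 2000)
    assert [len(item[0]) for item in ss.items] == [2] * 5
    # every slice re-timed to start at 0
    assert all(item[0].t.min() < 2000 for item in ss.items)


def test_concat_offsets_and_duration():
    a = EventStream.from_events([(0, 0, 0, 1)], 2, 2, duration=255)
    b = EventStream.from_events([(10, 1, 1, 1)], 2, 2, duration=255)
    op = concat_op_stream([(a, 0), (b, 1)], gap_us=1000)
    assert op.samples[1].t_start == 1255
    assert list(op)[1].t == 1265
    op0 = concat_op_stream([(a, 0), (b, 1)], gap_us=0)
    assert op0.duration == 510


def test_concat_geometry_mismatch():
    a = EventStream.empty(2, 2, 10)
    b = EventStream.empty(3, 2, 10)
    with pytest.raises(ValueError, match="geometry"):
        concat_op_stream([(a, 0), (b, 1)])


def test_concat_split_round_trip(rng):
    samples = [(random_stream(rng, n_events=30, duration=500), i % 3)
               for i in range(10)]
    op = concat_op_stream(samples, gap_us=777)
    back = split_op_stream(op)
    assert len(back) == 10
    for (orig, lab_o), (rec, lab_r) in zip(samples, back.items):
        assert lab_o == lab_r
        assert np.array_equal(orig.data, rec.data)


def test_slice_concat_reconstructs_multiset(rng):
    stream = random_stream(rng, n_events=200, duration=10_000)
    ss = slice_stream(stream, 2500)
    op = concat_op_stream(ss.items, gap_us=0)
    key = lambda d: sorted(map(tuple, d[:, :4]))
    assert key(op.data) == key(stream.data)
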