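import numpy as np
import pytest

from scism.segments import Segment, SegmentSet


def make_segment(values, errors=None, tid="t0", index=0, start=0.0):
    values = np.asarray(values, dtype=float)
    if errors is None:
        errors = np.zeros_like(values)
    return Segment(tid, index, start, values, np.asarray(errors, dtype=float))


def make_segment_set(value_rows, errors=None, observable_range=None):
    """SegmentSet from a list/array of per-segment value rows (one trajectory)."""
    segs = [
        make_segment(row, None if errors is None else errors[i], index=i)
        for i, row in enumerate(value_rows)
    ]
    n = len(segs)
    adjacency = np.array([True] * (n - 1) + [False]) if n else np.zeros(0, bool)
    return SegmentSet(segs, adjacency, np.full(n, 1.0 / n), observable_range)


@pytest.fixture
def grouped_segments():
    """60 zero-error segments in three tight, well-separated groups."""
    rng = np.random.default_rng(42)
    rows = np.concatenate(
        [
            rng.normal(0.2, 0.01, size=(20, 12)),
            rng.normal(0.5, 0.01, size=(20, 12)),
            rng.normal(0.8, 0.01, size=(20, 12)),
        ]
    )
    return make_segment_set(rows, errors=np.full_like(rows, 0.01))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
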