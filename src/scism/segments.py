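"""Segmentation of trajectories into fixed-length windows treated as
empirical distributions (local pmfs) of the observable."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Trajectory

__all__ = ["Segment", "SegmentSet", "segment_trajectory", "build_segment_set", "segment_cdf"]


@dataclass
class Segment:
    """A fixed-length window of a trajectory, represented as an empirical
    distribution of its member observable values.

    ``member_values`` keeps time order; ``sorted_values`` caches the order
    statistics used for CDF evaluation and Wasserstein-1 distances.
    """

    trajectory_id: str
    segment_index: int
    start_time: float
    member_values: np.ndarray
    member_errors: np.ndarray
    sorted_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.member_values = np.asarray(self.member_values, dtype=float)
        self.member_errors = np.asarray(self.member_errors, dtype=float)
        if len(self.member_values) < 2:
            raise ValueError("a segment needs at least 2 points")
        if len(self.member_values) != len(self.member_errors):
            raise ValueError("member_values and member_errors must match in length")
        self.sorted_values = np.sort(self.member_values)

    def __len__(self) -> int:
        return len(self.member_values)


@dataclass
class SegmentSet:
    """All segments across trajectories with a prior p(g_i) and adjacency.

    ``adjacency[i]`` is True iff segment i+1 exists, lies in the same
    trajectory, and is temporally contiguous with segment i; it is always
    False at trajectory boundaries and for the last segment.
    ``observable_range`` bounds the observable (e.g. (0, 1) for FRET
    efficiency) and is used to clip bootstrap realizations; None means
    unbounded.
    """

    segments: list[Segment]
    adjacency: np.ndarray
    prior: np.ndarray
    observable_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.prior = np.asarray(self.prior, dtype=float)
        n = len(self.segments)
        if len(self.adjacency) != n or len(self.prior) != n:
            raise ValueError("adjacency and prior must match the number of segments")
        if n and abs(self.prior.sum() - 1.0) > 1e-9:
            raise ValueError("segment prior must sum to 1")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def segment_length(self) -> int:
        return len(self.segments[0]) if self.segments else 0

    def value_matrix(self, sort: bool = True) -> np.ndarray:
        """(N, L) array of member values, sorted within each segment if asked."""
        attr = "sorted_values" if sort else "member_values"
        return np.stack([getattr(s, attr) for s in self.segments])

    def error_matrix(self) -> np.ndarray:
        return np.stack([s.member_errors for s in self.segments])

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        """Subset by index; adjacency recomputed conservatively (only pairs
        that were adjacent in the parent and remain consecutive survive)."""
        idx = np.asarray(idx)
        segs = [self.segments[i] for i in idx]
        adj = np.zeros(len(idx), dtype=bool)
        for k in range(len(idx) - 1):
            adj[k] = (idx[k + 1] == idx[k] + 1) and self.adjacency[idx[k]]
        prior = np.full(len(idx), 1.0 / len(idx))
        return SegmentSet(segs, adj, prior, self.observable_range)

    def to_frame(self) -> pd.DataFrame:
        """Segment table for TSV export."""
        return pd.DataFrame(
            {
                "trajectory_id": [s.trajectory_id for s in self.segments],
                "segment_index": [s.segment_index for s in self.segments],
                "start_time_s": [s.start_time for s in self.segments],
                "member_values": [",".join(f"{v:.6g}" for v in s.member_values) for s in self.segments],
            }
        )


def segment_trajectory(traj: Trajectory, segment_length: int) -> list[Segment]:
    """Cut a trajectory into floor(n/L) non-overlapping windows of L points.

    Windows containing any invalid bin are dropped whole; the trailing
    remainder shorter than L is dropped.
    """
    if segment_length < 2:
        raise ValueError("segment_length must be >= 2")
    n = len(traj)
    if n < segment_length:
        warnings.warn(
            f"trajectory {traj.trajectory_id!r} has {n} points < segment length "
            f"{segment_length}; no segments produced",
            stacklevel=2,
        )
        return []
    valid = traj.valid if traj.valid is not None else np.ones(n, dtype=bool)
    out: list[Segment] = []
    n_windows = n // segment_length
    for w in range(n_windows):
        sl = slice(w * segment_length, (w + 1) * segment_length)
        if not valid[sl].all():
            continue
        out.append(
            Segment(
                trajectory_id=traj.trajectory_id,
                segment_index=w,
                start_time=float(traj.times[sl.start]) - 0.5 * traj.bin_width,
                member_values=traj.values[sl],
                member_errors=traj.errors[sl],
            )
        )
    return out


def build_segment_set(
    trajs: Sequence[Trajectory],
    segment_length: int,
    observable_range: tuple[float, float] | None = None,
) -> SegmentSet:
    """Concatenate segments from all trajectories with a uniform prior.

    Adjacency marks within-trajectory consecutive windows only (windows
    separated by a dropped invalid window are not adjacent).
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    segments: list[Segment] = []
    adjacency: list[bool] = []
    for traj in trajs:
        segs = segment_trajectory(traj, segment_length)
        for a, b in zip(segs, segs[1:]):
            adjacency.append(b.segment_index == a.segment_index + 1)
        if segs:
            adjacency.append(False)  # trajectory boundary / terminal
        segments.extend(segs)
    if not segments:
        raise ValueError("no segments could be formed from the given trajectories")
    n = len(segments)
    prior = np.full(n, 1.0 / n)
    return SegmentSet(segments, np.asarray(adjacency), prior, observable_range)


def segment_cdf(seg: Segment, x: float | np.ndarray) -> np.ndarray | float:
    """Right-continuous empirical CDF of a segment evaluated at ``x``."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    res = np.searchsorted(seg.sorted_values, xs, side="right") / len(seg)
    return float(res[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else res
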