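"""Kantorovich (Wasserstein-1) distances between segment distributions and
the classical-MDS diagnostic embedding.

The Kantorovich distance between two empirical distributions equals the
area between their CDFs, integrated exactly on the merged support (no
observable-axis binning). When both segments hold the same number of
points L this reduces to the quantile form, mean |sorted differences|,
which is the fast path used for pairwise matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .segments import Segment, SegmentSet

__all__ = [
    "DistanceMatrix",
    "kantorovich_distance",
    "pairwise_distances",
    "pairwise_from_values",
    "cross_distances",
    "classical_mds",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise Kantorovich distances in observable units."""

    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("distance matrix must be square")
        if self.labels is None:
            self.labels = np.arange(self.values.shape[0])

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _w1_from_sorted(a: np.ndarray, b: np.ndarray) -> float:
    # exact CDF-area integral on the merged support of two empirical
    # distributions with arbitrary (possibly unequal) sizes
    support = np.concatenate([a, b])
    support.sort(kind="mergesort")
    if support[0] == support[-1]:
        return 0.0
    deltas = np.diff(support)
    cdf_a = np.searchsorted(a, support[:-1], side="right") / len(a)
    cdf_b = np.searchsorted(b, support[:-1], side="right") / len(b)
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def kantorovich_distance(a: Segment | np.ndarray, b: Segment | np.ndarray) -> float:
    """Wasserstein-1 distance between two segments (or raw value arrays)."""
    va = a.sorted_values if isinstance(a, Segment) else np.sort(np.asarray(a, dtype=float))
    vb = b.sorted_values if isinstance(b, Segment) else np.sort(np.asarray(b, dtype=float))
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("cannot compute a distance involving an empty segment")
    if len(va) == len(vb):
        return float(np.mean(np.abs(va - vb)))
    return _w1_from_sorted(va, vb)


def pairwise_from_values(sorted_values: np.ndarray) -> np.ndarray:
    """All-pairs W1 matrix from an (N, L) array of per-segment sorted values."""
    n, length = sorted_values.shape
    return squareform(pdist(sorted_values, metric="cityblock") / length)


def pairwise_distances(segs: SegmentSet) -> DistanceMatrix:
    """Kantorovich distance between every segment pair (quantile fast path)."""
    if len(segs) < 2:
        raise ValueError("need at least 2 segments")
    return DistanceMatrix(pairwise_from_values(segs.value_matrix(sort=True)))


def cross_distances(sorted_a: np.ndarray, sorted_b: np.ndarray) -> np.ndarray:
    """W1 distances between rows of two (n, L) sorted-value arrays."""
    length = sorted_a.shape[1]
    return cdist(sorted_a, sorted_b, metric="cityblock") / length


def classical_mds(dist: DistanceMatrix | np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and returns the top
    ``n_dims`` coordinates scaled by sqrt of the (clipped non-negative)
    eigenvalues. This is a plotting/diagnostic aid only; it plays no role
    in the clustering itself. Sign convention: within each output
    dimension, the coordinate with the largest magnitude is positive.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if n_dims > n:
        raise ValueError(f"n_dims={n_dims} exceeds the number of points {n}")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1][:n_dims]
    lam = evals[order]
    if np.any(lam < -1e-10 * max(1.0, abs(evals).max())):
        warnings.warn(
            "negative MDS eigenvalues clipped to zero (non-Euclidean distance matrix)",
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords
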