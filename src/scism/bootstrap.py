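"""Bootstrap error model for segment distributions.

A realization of a segment captures both finite-sampling error (resample
the L member points with replacement) and empirical error (perturb each
resampled point by a Gaussian with its per-point SD). Distances between
independent realizations of the *same* segment define the self-distortion
distribution whose upper percentile is the distortion cutoff used in
model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distances import DistanceMatrix, pairwise_from_values
from .segments import Segment, SegmentSet

__all__ = [
    "BootstrapEnsemble",
    "SelfDistortion",
    "bootstrap_segment",
    "realize_segment_values",
    "self_distortion",
    "bootstrap_distance_matrices",
    "ks_converged",
]


@dataclass
class SelfDistortion:
    """Pooled intra-segment bootstrap distances and the distortion cutoff."""

    samples: np.ndarray
    cutoff: float
    percentile: float
    n_boot: int
    converged: bool
    ks_pvalues: list[float] = field(default_factory=list)


@dataclass
class BootstrapEnsemble:
    """Sorted-value arrays of independent realizations of every segment.

    ``realizations`` has shape (n_boot, N, L): realization b of segment i is
    ``realizations[b, i]`` (sorted). Reproducible from (segs, n_boot, seed).
    """

    realizations: np.ndarray
    seed: int | None = None

    @property
    def n_boot(self) -> int:
        return self.realizations.shape[0]


def _realize(
    values: np.ndarray,
    errors: np.ndarray,
    rng: np.random.Generator,
    n_real: int,
    bounds: tuple[float, float] | None,
    sort: bool = True,
) -> np.ndarray:
    """n_real realizations of one (N, L) block of segments; returns
    (n_real, N, L), sorted along the last axis if requested."""
    n, length = values.shape
    idx = rng.integers(0, length, size=(n_real, n, length))
    rows = np.arange(n)[None, :, None]
    vals = values[rows, idx] + rng.standard_normal((n_real, n, length)) * errors[rows, idx]
    if bounds is not None:
        np.clip(vals, bounds[0], bounds[1], out=vals)
    if sort:
        vals.sort(axis=-1)
    return vals


def realize_segment_values(
    segs: SegmentSet, rng: np.random.Generator, n_real: int, sort: bool = True
) -> np.ndarray:
    """(n_real, N, L) bootstrap realizations of every segment in the set."""
    return _realize(
        segs.value_matrix(sort=False),
        segs.error_matrix(),
        rng,
        n_real,
        segs.observable_range,
        sort=sort,
    )


def bootstrap_segment(
    seg: Segment,
    rng: np.random.Generator,
    observable_range: tuple[float, float] | None = None,
) -> Segment:
    """One bootstrap realization of a single segment.

    Resamples the member points with replacement, then perturbs each draw
    by Normal(0, SD of that point); values are clipped to the observable
    range when one is given (e.g. [0, 1] for FRET efficiency).
    """
    if seg.member_errors is None or len(seg.member_errors) != len(seg.member_values):
        raise ValueError("segment lacks per-point error SDs; supply or compute them first")
    vals = _realize(
        seg.member_values[None, :], seg.member_errors[None, :], rng, 1, observable_range, sort=False
    )[0, 0]
    return Segment(
        trajectory_id=seg.trajectory_id,
        segment_index=seg.segment_index,
        start_time=seg.start_time,
        member_values=vals,
        member_errors=seg.member_errors.copy(),
    )


def ks_converged(
    old_samples: np.ndarray, combined_samples: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-sample two-sided K-S test; converged iff p >= alpha."""
    old_samples = np.asarray(old_samples)
    combined_samples = np.asarray(combined_samples)
    if len(old_samples) == 0 or len(combined_samples) == 0:
        raise ValueError("both samples must be non-empty")
    p = float(stats.ks_2samp(old_samples, combined_samples, method="asymp").pvalue)
    if np.array_equal(np.sort(old_samples), np.sort(combined_samples)):
        p = 1.0
    return p >= alpha, p


def self_distortion(
    segs: SegmentSet,
    rng: np.random.Generator,
    batch: int = 100,
    max_boot: int = 5000,
    alpha: float = 0.05,
    percentile: float = 95.0,
) -> SelfDistortion:
    """Self-distortion distribution and cutoff.

    Per batch, ``batch`` realizations of every segment are drawn and paired
    into batch//2 independent (realization, realization) distances per
    segment, pooled across segments. Batches are appended until a
    two-sample K-S test finds the pooled distribution unchanged by the
    newest batch (or ``max_boot`` realizations per segment are reached).
    The cutoff is the configured percentile of the pooled samples.
    """
    if batch < 2:
        raise ValueError("batch must be >= 2")
    pooled: np.ndarray | None = None
    pvals: list[float] = []
    converged = False
    n_done = 0
    while n_done < max_boot:
        reals = realize_segment_values(segs, rng, batch)  # (batch, N, L)
        half = batch // 2
        d = np.mean(np.abs(reals[:half] - reals[half : 2 * half]), axis=-1).ravel()
        n_done += batch
        if pooled is None:
            pooled = d
            continue
        combined = np.concatenate([pooled, d])
        converged, p = ks_converged(pooled, combined, alpha)
        pvals.append(p)
        pooled = combined
        if converged:
            break
    if not converged and n_done >= max_boot:
        warnings.warn("self-distortion pool did not converge before the bootstrap cap", stacklevel=2)
    cutoff = float(np.percentile(pooled, percentile)) if pooled.size else 0.0
    return SelfDistortion(
        samples=pooled,
        cutoff=cutoff,
        percentile=percentile,
        n_boot=n_done,
        converged=converged,
        ks_pvalues=pvals,
    )


def bootstrap_distance_matrices(
    segs: SegmentSet,
    rng: np.random.Generator,
    n_boot: int = 50,
    dtype=np.float32,
    block: int = 10,
) -> list[DistanceMatrix]:
    """One pairwise distance matrix per independent realization of the set.

    Matrices are stored at reduced precision (float32 by default) because a
    long run can hold tens of N x N matrices.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    out: list[DistanceMatrix] = []
    remaining = n_boot
    while remaining > 0:
        take = min(block, remaining)
        reals = realize_segment_values(segs, rng, take)
        for b in range(take):
            out.append(DistanceMatrix(pairwise_from_values(reals[b]).astype(dtype)))
        remaining -= take
    return out
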