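"""Reading, binning and writing of single-molecule photon streams and trajectories.

A photon stream is a two-column delimited text file (arrival time in
seconds, detection channel ``D`` or ``A``); a trajectory is a uniformly
binned observable (typically FRET efficiency) with a per-point error SD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhotonStream",
    "Trajectory",
    "CorrectionConfig",
    "read_photon_stream",
    "write_photon_stream",
    "bin_photons",
    "compute_fret_trajectory",
    "read_trajectories",
    "write_trajectories",
]

_VALID_CHANNELS = ("D", "A")


@dataclass
class PhotonStream:
    """Arrival times (s, sorted ascending) and channel labels of detected photons."""

    arrival_times: np.ndarray
    channels: np.ndarray  # array of 'D'/'A' labels
    duration: float

    def __post_init__(self) -> None:
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        self.channels = np.asarray(self.channels)
        if self.arrival_times.ndim != 1 or len(self.arrival_times) != len(self.channels):
            raise ValueError("arrival_times and channels must be 1-D and equal length")
        if np.any(np.diff(self.arrival_times) < 0):
            raise ValueError("photon arrival times must be sorted ascending")
        bad = ~np.isin(self.channels, _VALID_CHANNELS)
        if bad.any():
            raise ValueError(
                f"invalid channel label(s): {sorted(set(self.channels[bad]))!r}; "
                f"expected one of {_VALID_CHANNELS}"
            )
        if len(self.arrival_times) and self.duration < self.arrival_times[-1]:
            raise ValueError("duration must cover the last arrival time")

    def __len__(self) -> int:
        return len(self.arrival_times)


@dataclass
class Trajectory:
    """A uniformly binned observable time series for one molecule.

    ``values`` is the observable (FRET efficiency is dimensionless in [0, 1]),
    ``errors`` the per-point SD in the same units, ``times`` the bin centers
    in seconds. ``counts`` optionally holds per-bin (n_D, n_A) photon counts.
    ``valid`` flags bins with enough photons to be usable.
    """

    trajectory_id: str
    bin_width: float
    times: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    counts: np.ndarray | None = None  # shape (n, 2): donor, acceptor
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        n = len(self.times)
        if not (len(self.values) == len(self.errors) == n):
            raise ValueError("times/values/errors must have equal lengths")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.errors < 0):
            raise ValueError("errors must be non-negative")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CorrectionConfig:
    """Background and donor→acceptor crosstalk corrections (all default off)."""

    background_rate_D: float = 0.0  # photons / s
    background_rate_A: float = 0.0  # photons / s
    crosstalk_alpha: float = 0.0  # fraction of donor photons detected as acceptor

    def __post_init__(self) -> None:
        if self.background_rate_D < 0 or self.background_rate_A < 0:
            raise ValueError("background rates must be non-negative")
        if not (0 <= self.crosstalk_alpha < 1):
            raise ValueError("crosstalk_alpha must lie in [0, 1)")


def read_photon_stream(
    path: str | Path,
    delimiter: str | None = None,
    duplicate_fraction_limit: float = 0.01,
) -> PhotonStream:
    """Parse a two-column (time_s, channel) photon file; '#' starts a comment.

    Duplicate identical timestamps are tolerated up to
    ``duplicate_fraction_limit`` of all photons (warned), beyond that an
    error is raised.
    """
    path = Path(path)
    times: list[float] = []
    chans: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split() if delimiter is None else line.split(delimiter)
            parts = [p for p in (q.strip() for q in parts) if p]
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable time {parts[0]!r}") from exc
            ch = parts[1].upper()
            if ch not in _VALID_CHANNELS:
                raise ValueError(f"{path}:{lineno}: invalid channel label {parts[1]!r}")
            times.append(t)
            chans.append(ch)
    if not times:
        raise ValueError(f"{path}: no photons")
    t_arr = np.asarray(times)
    if np.any(np.diff(t_arr) < 0):
        bad = int(np.argmax(np.diff(t_arr) < 0)) + 2
        raise ValueError(f"{path}: arrival times not sorted ascending (near line {bad})")
    n_dup = int(np.sum(np.diff(t_arr) == 0))
    if n_dup:
        frac = n_dup / len(t_arr)
        if frac > duplicate_fraction_limit:
            raise ValueError(
                f"{path}: {n_dup} duplicate timestamps ({frac:.1%}) exceed the "
                f"allowed fraction {duplicate_fraction_limit:.1%}"
            )
        warnings.warn(f"{path}: {n_dup} duplicate photon timestamps", stacklevel=2)
    return PhotonStream(t_arr, np.asarray(chans), duration=float(t_arr[-1]))


def write_photon_stream(stream: PhotonStream, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# time_s channel\n")
        for t, c in zip(stream.arrival_times, stream.channels):
            fh.write(f"{t:.9f} {c}\n")


def bin_photons(stream: PhotonStream, bin_width: float) -> np.ndarray:
    """Count photons per channel in uniform bins of ``bin_width`` seconds.

    Returns an (n_bins, 2) integer array of (donor, acceptor) counts. The
    trailing partial bin is dropped, so photons are conserved exactly over
    [0, n_bins * bin_width).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(stream.duration / bin_width))
    counts = np.zeros((n_bins, 2), dtype=np.int64)
    if n_bins == 0 or len(stream) == 0:
        return counts
    edges = np.arange(n_bins + 1) * bin_width
    is_a = stream.channels == "A"
    counts[:, 0] = np.histogram(stream.arrival_times[~is_a], bins=edges)[0]
    counts[:, 1] = np.histogram(stream.arrival_times[is_a], bins=edges)[0]
    return counts


def compute_fret_trajectory(
    counts: np.ndarray,
    bin_width: float,
    corrections: CorrectionConfig | None = None,
    trajectory_id: str = "traj0",
    min_photons: int = 10,
) -> Trajectory:
    """FRET efficiency per bin, E = n_A'/(n_A' + n_D'), with shot-noise SD.

    Corrected counts subtract the expected background per bin and the
    donor→acceptor crosstalk fraction, clipped at zero. The per-point error
    follows binomial (shot-noise) propagation, SD = sqrt(E(1-E)/n_total).
    Bins with fewer than ``min_photons`` corrected photons are flagged
    invalid.
    """
    corrections = corrections or CorrectionConfig()
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("counts must have shape (n_bins, 2)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n_d = counts[:, 0].astype(float)
    n_a = counts[:, 1].astype(float)
    n_d_corr = np.clip(n_d - corrections.background_rate_D * bin_width, 0.0, None)
    n_a_corr = np.clip(
        n_a - corrections.background_rate_A * bin_width - corrections.crosstalk_alpha * n_d_corr,
        0.0,
        None,
    )
    total = n_d_corr + n_a_corr
    valid = total >= min_photons
    if not valid.any():
        raise ValueError("no usable bins: all bins fall below min_photons after corrections")
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, n_a_corr / np.where(total > 0, total, 1.0), np.nan)
        sd = np.where(total > 0, np.sqrt(np.clip(e * (1.0 - e), 0.0, None) / np.where(total > 0, total, 1.0)), np.nan)
    e = np.where(valid, e, np.nan)
    sd = np.where(valid, sd, np.nan)
    times = (np.arange(len(counts)) + 0.5) * bin_width
    return Trajectory(
        trajectory_id=trajectory_id,
        bin_width=bin_width,
        times=times,
        values=np.nan_to_num(e, nan=0.0),
        errors=np.nan_to_num(sd, nan=0.0),
        counts=counts,
        valid=valid,
    )


def write_trajectories(trajs: Sequence[Trajectory], path: str | Path, decimals: int = 9) -> None:
    """Write trajectories as delimited text (trajectory_id, time_s, value, error_sd)."""
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": tr.trajectory_id,
                    "time_s": np.round(tr.times, decimals),
                    "value": np.round(tr.values, decimals),
                    "error_sd": np.round(tr.errors, decimals),
                    "valid": tr.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read trajectories written by :func:`write_trajectories` (or compatible).

    The ``error_sd`` column is required: without per-bin photon counts there
    is no way to reconstruct a shot-noise error model.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"trajectory_id", "time_s", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    if "error_sd" not in df.columns:
        raise ValueError(
            f"{path}: no error_sd column; supply per-point error SDs or compute "
            "them from photon counts via compute_fret_trajectory"
        )
    out = []
    for tid, sub in df.groupby("trajectory_id", sort=False):
        sub = sub.sort_values("time_s")
        t = sub["time_s"].to_numpy(float)
        widths = np.diff(t)
        bw = float(np.median(widths)) if len(widths) else 1.0
        valid = sub["valid"].to_numpy(bool) if "valid" in sub.columns else None
        out.append(
            Trajectory(
                trajectory_id=str(tid),
                bin_width=bw,
                times=t,
                values=sub["value"].to_numpy(float),
                errors=sub["error_sd"].to_numpy(float),
                valid=valid,
            )
        )
    if not out:
        raise ValueError(f"{path}: no trajectories")
    return out


def write_json(obj, path: str | Path) -> None:
    """Write a JSON artifact, converting numpy scalars/arrays transparently."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
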