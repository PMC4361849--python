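"""State sequences, transition counting, escape times, survival curves
and detailed-balance tests.

The reported network and all point estimates come from the most probable
state sequence (per-segment argmax of p(S_k | g_i)); uncertainty comes
from sequence realizations sampled independently per segment from the
conditionals. Residence runs touching a trajectory boundary are censored
and excluded from escape times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .cluster import ClusterModel
from .segments import SegmentSet

__all__ = [
    "StateSequence",
    "CountMatrix",
    "KineticsSummary",
    "most_probable_sequence",
    "sample_sequences",
    "transition_counts",
    "residence_runs",
    "escape_times",
    "survival_and_exp_test",
    "detailed_balance_test",
    "network_export",
]


@dataclass
class StateSequence:
    """State label per segment plus the adjacency mask of the segment set."""

    labels: np.ndarray
    adjacency: np.ndarray
    tau_seg: float  # seconds per segment
    n_states: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if len(self.labels) != len(self.adjacency):
            raise ValueError("labels and adjacency must match in length")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.n_states):
            raise ValueError("labels out of range")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class CountMatrix:
    """Transition counts N_ij over adjacent segment pairs and visit counts N_i."""

    n_ij: np.ndarray
    n_i: np.ndarray

    @property
    def n_transitions(self) -> int:
        """Total transition observations N = sum_ij N_ij."""
        return int(self.n_ij.sum())

    @property
    def n_visits(self) -> int:
        return int(self.n_i.sum())


@dataclass
class KineticsSummary:
    escape_time_s: dict[int, float]
    escape_ci_s: dict[int, tuple[float, float]]
    survival: dict[int, tuple[np.ndarray, np.ndarray]]  # state -> (t, S(t))
    exp_fit_pvalues: dict[int, float]
    detailed_balance_pvalues: dict[tuple[int, int], float]
    detailed_balance_rejected: bool

    def to_dict(self) -> dict:
        return {
            "escape_time_s": {str(k): v for k, v in self.escape_time_s.items()},
            "escape_ci_s": {str(k): list(v) for k, v in self.escape_ci_s.items()},
            "exp_fit_pvalues": {str(k): v for k, v in self.exp_fit_pvalues.items()},
            "detailed_balance_pvalues": {f"{i}-{j}": p for (i, j), p in self.detailed_balance_pvalues.items()},
            "detailed_balance_rejected": bool(self.detailed_balance_rejected),
        }


def most_probable_sequence(model: ClusterModel, segs: SegmentSet, tau_seg: float | None = None) -> StateSequence:
    """Per-segment argmax of p(S_k | g_i); ties resolve to the lowest index."""
    a = model.assignment
    if len(segs) != a.shape[0]:
        raise ValueError("model does not cover the segment set")
    labels = np.argmax(a, axis=1)  # np.argmax takes the first (lowest) index on ties
    row_max = a[np.arange(len(labels)), labels]
    n_ties = int(np.sum(np.sum(np.isclose(a, row_max[:, None]), axis=1) > 1))
    if n_ties:
        warnings.warn(f"{n_ties} segments had tied state probabilities; lowest index taken", stacklevel=2)
    if tau_seg is None:
        tau_seg = float(len(segs.segments[0]))  # fall back to units of bins
    return StateSequence(labels, segs.adjacency, tau_seg, model.assignment.shape[1])


def sample_sequences(
    model: ClusterModel,
    segs: SegmentSet,
    n_realizations: int,
    rng: np.random.Generator | int | None = None,
    tau_seg: float | None = None,
) -> list[StateSequence]:
    """Sequence realizations with each label drawn from p(. | g_i) independently."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(rng)
    a = model.assignment
    n, k = a.shape
    if tau_seg is None:
        tau_seg = float(len(segs.segments[0]))
    cum = np.cumsum(a, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n_realizations, n, 1))
    draws = (u > cum[None, :, :]).sum(axis=2)
    return [StateSequence(draws[r], segs.adjacency, tau_seg, k) for r in range(n_realizations)]


def transition_counts(seq: StateSequence) -> CountMatrix:
    """Count i->j over consecutive pairs within trajectories (self-pairs count)."""
    k = seq.n_states
    n_ij = np.zeros((k, k), dtype=np.int64)
    ok = seq.adjacency[:-1] if len(seq) else np.zeros(0, dtype=bool)
    src = seq.labels[:-1][ok]
    dst = seq.labels[1:][ok]
    np.add.at(n_ij, (src, dst), 1)
    n_i = np.bincount(seq.labels, minlength=k)
    return CountMatrix(n_ij, n_i)


def residence_runs(seq: StateSequence) -> dict[int, list[int]]:
    """Complete (non-boundary-censored) residence runs per state, in segments.

    A run is complete only if both the segment before it and after it lie
    in the same trajectory (so the entry and exit transitions were
    observed).
    """
    runs: dict[int, list[int]] = {k: [] for k in range(seq.n_states)}
    labels = seq.labels
    n = len(labels)
    i = 0
    while i < n:
        j = i
        # extend run while contiguous and same state
        while j + 1 < n and seq.adjacency[j] and labels[j + 1] == labels[i]:
            j += 1
        left_ok = i > 0 and seq.adjacency[i - 1]
        right_ok = j + 1 < n and seq.adjacency[j]
        if left_ok and right_ok:
            runs[labels[i]].append(j - i + 1)
        i = j + 1
    return runs


def escape_times(
    realizations: list[StateSequence],
    point_sequence: StateSequence | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[dict[int, float], dict[int, tuple[float, float]]]:
    """Mean residence time per state (seconds) with percentile CIs.

    The point estimate comes from ``point_sequence`` (the most probable
    sequence) when given, else from the first realization; the CI is the
    percentile interval of the per-realization means.
    """
    if not realizations:
        raise ValueError("need at least one realization")
    n_states = realizations[0].n_states
    tau = realizations[0].tau_seg
    ref = point_sequence if point_sequence is not None else realizations[0]
    point: dict[int, float] = {}
    cis: dict[int, tuple[float, float]] = {}
    ref_runs = residence_runs(ref)
    per_real: dict[int, list[float]] = {k: [] for k in range(n_states)}
    for seq in realizations:
        rr = residence_runs(seq)
        for k in range(n_states):
            if rr[k]:
                per_real[k].append(float(np.mean(rr[k])) * tau)
    for k in range(n_states):
        if not ref_runs[k] and not per_real[k]:
            warnings.warn(f"state {k}: no complete residence runs; escape time undefined", stacklevel=2)
            point[k] = float("nan")
            cis[k] = (float("nan"), float("nan"))
            continue
        point[k] = float(np.mean(ref_runs[k])) * tau if ref_runs[k] else float(np.median(per_real[k]))
        if per_real[k]:
            lo, hi = np.percentile(per_real[k], ci)
            cis[k] = (float(lo), float(hi))
        else:
            cis[k] = (point[k], point[k])
    return point, cis


def survival_and_exp_test(
    residences: np.ndarray, min_runs: int = 5, n_bins: int | None = None
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Empirical survival curve of residence times and a chi^2 test against
    the maximum-likelihood single exponential.

    The ML exponential has rate 1/mean. The chi^2 statistic compares
    observed counts in equal-probability bins of the fitted exponential
    (so every expected count is n/m >= 5) with df = bins - 2 (one fitted
    parameter plus normalization). Returns ((t, S(t)), p_value); with
    fewer than ``min_runs`` residences the p-value is NaN.
    """
    residences = np.sort(np.asarray(residences, dtype=float))
    n = len(residences)
    t = np.concatenate([[0.0], residences])
    s = 1.0 - np.arange(n + 1) / max(n, 1)
    curve = (t, s)
    if n < min_runs:
        warnings.warn(f"only {n} complete runs (< {min_runs}); exponential test undefined", stacklevel=2)
        return curve, float("nan")
    mean = residences.mean()
    if mean <= 0:
        return curve, 0.0
    rate = 1.0 / mean
    m = n_bins if n_bins is not None else int(np.clip(n // 5, 3, 30))
    # equal-probability bin edges under the fitted exponential
    qs = np.linspace(0.0, 1.0, m + 1)
    edges = -np.log1p(-qs[:-1]) / rate
    edges = np.append(edges, np.inf)
    observed, _ = np.histogram(residences, bins=edges)
    expected = np.full(m, n / m)
    if residences.max() == residences.min():
        # a single-step survival curve cannot be exponential
        return curve, 0.0
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = max(m - 2, 1)
    return curve, float(stats.chi2.sf(stat, df))


def detailed_balance_test(counts: CountMatrix, alpha: float = 0.05) -> tuple[dict[tuple[int, int], float], bool]:
    """Exact two-sided binomial test of N_ij = N_ji per unordered pair.

    Under detailed balance each of the N_ij + N_ji observed crossings is
    equally likely to be forward or backward. The overall verdict uses a
    Bonferroni correction: rejected iff min adjusted p < alpha.
    """
    k = counts.n_ij.shape[0]
    pvals: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            tot = int(counts.n_ij[i, j] + counts.n_ij[j, i])
            if tot == 0:
                continue
            pvals[(i, j)] = float(
                stats.binomtest(int(counts.n_ij[i, j]), tot, 0.5, alternative="two-sided").pvalue
            )
    if not pvals:
        return pvals, False
    n_tests = len(pvals)
    rejected = min(p * n_tests for p in pvals.values()) < alpha
    return pvals, bool(rejected)


def network_export(
    counts: CountMatrix,
    model: ClusterModel,
    segs: SegmentSet,
    free_energies: dict[int, float] | None = None,
) -> nx.Graph:
    """Undirected state network with node populations, mean observables and
    free energies; edges carry raw and symmetrized transition counts."""
    g = nx.Graph()
    seg_means = np.array([s.member_values.mean() for s in segs.segments])
    w = model.assignment * segs.prior[:, None]
    pk = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_e = np.where(pk > 0, (w * seg_means[:, None]).sum(axis=0) / np.where(pk > 0, pk, 1.0), np.nan)
    for k in range(counts.n_ij.shape[0]):
        g.add_node(
            k,
            p=float(pk[k]) if k < len(pk) else 0.0,
            mean_observable=float(mean_e[k]) if k < len(mean_e) else float("nan"),
            free_energy=float(free_energies.get(k, float("nan"))) if free_energies else float("nan"),
        )
    k_states = counts.n_ij.shape[0]
    for i in range(k_states):
        for j in range(i + 1, k_states):
            fwd = int(counts.n_ij[i, j])
            bwd = int(counts.n_ij[j, i])
            if fwd + bwd:
                g.add_edge(i, j, n_forward=fwd, n_backward=bwd, weight=(fwd + bwd) / 2.0)
    return g
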