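"""Rate-distortion soft clustering of segments by Blahut-Arimoto-style
alternating minimization.

The functional minimized over soft assignments p(S_k | g_i) is

    F = I(S; g) + beta * <d>,

where I is the mutual information between states and segments and <d> is
the mean within-state pairwise Kantorovich distance,

    <d> = sum_k p(S_k) sum_{i,j} p(g_i|S_k) p(g_j|S_k) d_ij .

Setting the constrained derivative of F (in nats) to zero gives the
Boltzmann-form stationary point

    p(S_k|g_i) = p(S_k) exp(-beta * d_eff(g_i, S_k)) / Z(g_i; beta),
    d_eff(g_i, S_k) = 2 sum_j p(g_j|S_k) d_ij
                      - sum_{j,l} p(g_j|S_k) p(g_l|S_k) d_jl ,

which is iterated alternately with the marginal update
p(S_k) = sum_i p(g_i) p(S_k|g_i) until the functional converges. The
assignment matrix is randomly initialized, so the optimization is run
from multiple restarts and the best (lowest-F) solution is kept.

Mutual information is reported in bits; the exponent above uses beta in
nats-per-observable-unit internally, so the functional optimized is
F_nats = I_nats + beta * <d> (any base rescales F by a constant and
changes no minimizer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, rel_entr

from .distances import DistanceMatrix

__all__ = [
    "ClusterModel",
    "mean_distortion",
    "effective_distortion",
    "ba_step",
    "cluster",
    "mutual_information",
    "posterior_for_distances",
]

_P_FLOOR = 1e-10  # states below this marginal are frozen out
# Two states are duplicates when their membership distributions p(g|S_k)
# coincide, i.e. their conditional columns are proportional (exact
# duplication leaves I(S;g) and <d> invariant). Empirically duplicated
# states sit at relative sup-distance <~ 5e-3 while distinct states sit at
# ~1, so 0.05 separates the two regimes with a wide margin.
_DUP_TOL = 0.05


@dataclass
class ClusterModel:
    """Soft-assignment model p(S_k | g_i) for a fixed (N_s, beta).

    ``assignment`` is (N, N_s) row-stochastic; ``state_probs`` is the
    state marginal p(S_k). ``mutual_info`` is I(S; g) in bits,
    ``mean_distortion`` in observable units, ``functional_value`` is
    I_nats + beta * <d>.
    """

    n_states: int
    beta: float
    assignment: np.ndarray
    state_probs: np.ndarray
    mutual_info: float
    mean_distortion: float
    functional_value: float
    converged: bool = True
    monotone: bool = True
    iterations: int = 0
    n_restarts: int = 1
    seed: int | None = None
    functional_history: np.ndarray | None = None

    @property
    def effective_n_states(self) -> int:
        """Number of distinct, populated states (duplicates counted once)."""
        return len(_distinct_state_groups(self.assignment, self.state_probs))

    def to_dict(self) -> dict:
        return {
            "n_states": int(self.n_states),
            "effective_n_states": int(self.effective_n_states),
            "beta": float(self.beta),
            "assignment": self.assignment.tolist(),
            "state_probs": self.state_probs.tolist(),
            "mutual_info_bits": float(self.mutual_info),
            "mean_distortion": float(self.mean_distortion),
            "functional_value": float(self.functional_value),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "n_restarts": int(self.n_restarts),
            "seed": self.seed,
        }


def _cluster_weights(assignment: np.ndarray, pg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """State marginals p_k and membership weights q[k, j] = p(g_j | S_k)."""
    w = assignment * pg[:, None]  # (N, K): joint p(S_k, g_i)
    pk = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(pk[None, :] > 0, w / np.where(pk[None, :] > 0, pk[None, :], 1.0), 0.0)
    return pk, q.T  # q as (K, N)


def mean_distortion(
    dist: DistanceMatrix | np.ndarray, assignment: np.ndarray, pg: np.ndarray
) -> float:
    """<d> = sum_k p(S_k) sum_{i,j} p(g_i|S_k) p(g_j|S_k) d_ij."""
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    pk, q = _cluster_weights(np.asarray(assignment, dtype=float), np.asarray(pg, dtype=float))
    # per-state pairwise distortion c_k = q_k^T D q_k
    c = np.einsum("kj,jl,kl->k", q, d, q, optimize=True)
    return float(np.dot(pk, c))


def effective_distortion(
    dist: DistanceMatrix | np.ndarray, assignment: np.ndarray, pg: np.ndarray
) -> np.ndarray:
    """(N, K) effective distortion d_eff(g_i, S_k); zero-weight states get 0."""
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    pk, q = _cluster_weights(np.asarray(assignment, dtype=float), np.asarray(pg, dtype=float))
    a = q @ d  # (K, N): sum_j p(g_j|S_k) d_ji
    c = np.einsum("kj,kj->k", q, a)  # per-state pairwise distortion
    return (2.0 * a - c[:, None]).T


def mutual_information(assignment: np.ndarray, pg: np.ndarray, base: float = 2.0) -> float:
    """I(S; g) = sum_{i,k} p(g_i) p(S_k|g_i) log[p(S_k|g_i)/p(S_k)] (bits)."""
    assignment = np.asarray(assignment, dtype=float)
    pg = np.asarray(pg, dtype=float)
    pk = (assignment * pg[:, None]).sum(axis=0)
    contrib = pg[:, None] * rel_entr(assignment, np.broadcast_to(pk, assignment.shape))
    return float(contrib.sum() / np.log(base))


def _functional(d: np.ndarray, assignment: np.ndarray, pg: np.ndarray, beta_nats: float) -> float:
    return mutual_information(assignment, pg, base=np.e) + beta_nats * mean_distortion(
        d, assignment, pg
    )


def ba_step(
    dist: DistanceMatrix | np.ndarray,
    assignment: np.ndarray,
    pg: np.ndarray,
    beta_nats: float,
) -> np.ndarray:
    """One alternating update: recompute p(S_k), then the Boltzmann assignment.

    The exponentials are evaluated in log space (per-row max subtracted) so
    large beta never underflows Z.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    assignment = np.asarray(assignment, dtype=float)
    pg = np.asarray(pg, dtype=float)
    pk = (assignment * pg[:, None]).sum(axis=0)
    active = pk > _P_FLOOR
    d_eff = effective_distortion(d, assignment, pg)
    with np.errstate(divide="ignore"):
        log_w = np.where(active[None, :], np.log(np.where(active, pk, 1.0))[None, :], -np.inf)
    log_p = log_w - beta_nats * d_eff
    log_z = logsumexp(log_p, axis=1, keepdims=True)
    if not np.all(np.isfinite(log_z)):
        raise FloatingPointError("normalization Z underflowed despite log-space evaluation")
    return np.exp(log_p - log_z)


def _random_assignment(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    a = rng.random((n, k)) + 1e-3
    return a / a.sum(axis=1, keepdims=True)


def cluster(
    dist: DistanceMatrix | np.ndarray,
    pg: np.ndarray,
    n_states: int,
    beta: float,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    rng: np.random.Generator | int | None = None,
    init: np.ndarray | list[np.ndarray] | None = None,
) -> ClusterModel:
    """Minimize F over soft assignments for fixed (n_states, beta).

    ``beta`` is interpreted in nats per observable unit (the exponent of
    the Boltzmann update is exactly -beta*d_eff). ``init`` may supply one
    or more warm-start assignment matrices used in addition to the random
    restarts. The best restart (lowest functional) is returned; within a
    restart the functional history is recorded and an increase beyond
    tolerance terminates the restart with ``monotone=False``.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    pg = np.asarray(pg, dtype=float)
    n = d.shape[0]
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    inits: list[np.ndarray] = []
    if init is not None:
        if isinstance(init, np.ndarray):
            inits.append(np.asarray(init, dtype=float))
        else:
            inits.extend(np.asarray(m, dtype=float) for m in init)
    inits.extend(_random_assignment(rng, n, n_states) for _ in range(n_restarts))

    best: ClusterModel | None = None
    for a0 in inits:
        if a0.shape != (n, n_states):
            raise ValueError("init assignment has wrong shape")
        a = a0
        f_prev = np.inf
        history: list[float] = []
        converged = False
        monotone = True
        it = 0
        for it in range(max_iter + 1):
            # one fused pass: the K x N product q @ D yields both the mean
            # distortion of the current assignment and the d_eff driving the
            # next update
            pk, q = _cluster_weights(a, pg)
            qd = q @ d
            c = np.einsum("kj,kj->k", q, qd)
            f_new = mutual_information(a, pg, base=np.e) + beta * float(np.dot(pk, c))
            history.append(f_new)
            if np.isfinite(f_prev) and abs(f_new - f_prev) <= tol * max(abs(f_new), 1e-12):
                converged = True
                break
            if f_new > f_prev + 1e-9 * max(1.0, abs(f_prev)):
                monotone = False
                break
            f_prev = f_new
            if it == max_iter:
                break
            d_eff = (2.0 * qd - c[:, None]).T
            active = pk > _P_FLOOR
            with np.errstate(divide="ignore"):
                log_w = np.where(active[None, :], np.log(np.where(active, pk, 1.0))[None, :], -np.inf)
            log_p = log_w - beta * d_eff
            log_z = logsumexp(log_p, axis=1, keepdims=True)
            if not np.all(np.isfinite(log_z)):
                raise FloatingPointError("normalization Z underflowed despite log-space evaluation")
            a = np.exp(log_p - log_z)
        pk = (a * pg[:, None]).sum(axis=0)
        model = ClusterModel(
            n_states=n_states,
            beta=beta,
            assignment=a,
            state_probs=pk,
            mutual_info=mutual_information(a, pg, base=2.0),
            mean_distortion=mean_distortion(d, a, pg),
            functional_value=f_prev,
            converged=converged,
            monotone=monotone,
            iterations=it,
            n_restarts=len(inits),
            seed=seed,
            functional_history=np.asarray(history),
        )
        if best is None or model.functional_value < best.functional_value:
            best = model
    assert best is not None
    if not best.converged:
        warnings.warn(
            f"no restart converged within max_iter={max_iter}; returning best effort",
            stacklevel=2,
        )
    return best


def _distinct_state_groups(
    assignment: np.ndarray, pk: np.ndarray, p_floor: float = _P_FLOOR, dup_tol: float = _DUP_TOL
) -> list[list[int]]:
    """Group populated states whose membership distributions coincide.

    Columns are compared after L1 normalization (membership shape), so
    exactly duplicated states — proportional conditional columns — land in
    the same group whatever their marginal split.
    """
    keep = [k for k in range(assignment.shape[1]) if pk[k] > p_floor]
    norms = {}
    for k in keep:
        col = assignment[:, k]
        norms[k] = col / col.sum()
    groups: list[list[int]] = []
    for k in keep:
        placed = False
        for grp in groups:
            ref = norms[grp[0]]
            rel = np.max(np.abs(norms[k] - ref)) / max(norms[k].max(), ref.max())
            if rel < dup_tol:
                grp.append(k)
                placed = True
                break
        if not placed:
            groups.append([k])
    return groups


def merge_degenerate_states(
    assignment: np.ndarray, pg: np.ndarray, p_floor: float = _P_FLOOR, dup_tol: float = _DUP_TOL
) -> tuple[np.ndarray, list[list[int]]]:
    """Collapse a soft assignment to its effective states.

    Drops states with negligible marginal and merges duplicated states
    (identical membership distributions; their conditional probabilities
    add). Returns the (N, K_eff) row-renormalized assignment and the
    groups of original state indices behind each effective state.
    """
    assignment = np.asarray(assignment, dtype=float)
    pg = np.asarray(pg, dtype=float)
    pk = (assignment * pg[:, None]).sum(axis=0)
    groups = _distinct_state_groups(assignment, pk, p_floor, dup_tol)
    merged = np.stack([assignment[:, grp].sum(axis=1) for grp in groups], axis=1)
    merged /= merged.sum(axis=1, keepdims=True)
    return merged, groups


def posterior_for_distances(
    cross_d: np.ndarray, model: ClusterModel, pg_train: np.ndarray, d_train: np.ndarray
) -> np.ndarray:
    """Out-of-sample soft assignment for new segments.

    Given W1 distances ``cross_d`` (n_new, N_train) from new segments to
    the training segments, evaluates d_eff of each new segment against the
    fitted clusters and applies the same Boltzmann rule at the model's
    beta. Training segments reproduce their in-sample posterior.
    """
    pk, q = _cluster_weights(model.assignment, np.asarray(pg_train, dtype=float))
    a = q @ cross_d.T  # (K, n_new): sum_j p(g_j|S_k) d(new, g_j)
    c = np.einsum("kj,jl,kl->k", q, d_train, q, optimize=True)
    d_eff = (2.0 * a - c[:, None]).T
    active = pk > _P_FLOOR
    with np.errstate(divide="ignore"):
        log_w = np.where(active[None, :], np.log(np.where(active, pk, 1.0))[None, :], -np.inf)
    log_p = log_w - model.beta * d_eff
    return np.exp(log_p - logsumexp(log_p, axis=1, keepdims=True))
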