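"""Model selection: sweep (N_s, beta), apply the error-based distortion
cutoff, and keep the simplest adequate model.

A candidate model is "adequate" when its bootstrap mean-distortion
distribution falls within the distortion attributable to error alone
(default rule: median <= the self-distortion cutoff). Among adequate
candidates the one with the smallest mutual information I(S; g) wins —
the simplest description of the data that fits it to within the noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bootstrap import SelfDistortion, ks_converged
from .cluster import ClusterModel, cluster, mean_distortion
from .distances import DistanceMatrix
from .segments import SegmentSet

__all__ = [
    "SelectionConfig",
    "Candidate",
    "CandidateGrid",
    "candidate_distortion_samples",
    "passes_cutoff",
    "sweep_and_select",
]


@dataclass
class SelectionConfig:
    """Knobs for the (N_s, beta) sweep.

    The beta schedule is geometric: beta_min = beta_min_scale / <d>_1
    (scaled by the one-state distortion so the schedule is unit-free),
    multiplied by beta_ratio each step, at most max_beta_steps steps.
    Each N_s starts from ``restarts_initial`` random restarts at the first
    beta and is annealed with a warm start plus ``restarts_anneal`` fresh
    restarts at every later beta.
    """

    n_max: int = 10
    beta_min_scale: float = 0.01
    beta_ratio: float = 1.5
    max_beta_steps: int = 60
    restarts_initial: int = 8
    restarts_anneal: int = 2
    tol: float = 1e-8
    max_iter: int = 400  # warm-started anneal steps converge in far fewer
    ks_alpha: float = 0.05
    pass_rule: str = "median"  # "median" | "all" | "fraction"
    pass_fraction: float = 0.9
    min_improvement_stop: int = 2  # consecutive non-improving N_s before stopping


@dataclass
class Candidate:
    model: ClusterModel
    distortion_samples: np.ndarray
    passed: bool
    termination: str = ""

    @property
    def median_distortion(self) -> float:
        return float(np.median(self.distortion_samples))


@dataclass
class CandidateGrid:
    candidates: list[Candidate]
    cutoff: float
    selected: Candidate | None
    adequate: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def selected_model(self) -> ClusterModel:
        return self.selected.model

    def to_dict(self) -> dict:
        return {
            "cutoff": float(self.cutoff),
            "adequate": bool(self.adequate),
            "selected": self.selected.model.to_dict() if self.selected else None,
            "grid": [
                {
                    "n_states": c.model.n_states,
                    "effective_n_states": c.model.effective_n_states,
                    "beta": c.model.beta,
                    "mutual_info_bits": c.model.mutual_info,
                    "median_distortion": c.median_distortion,
                    "passed": bool(c.passed),
                    "termination": c.termination,
                }
                for c in self.candidates
            ],
            "diagnostics": self.diagnostics,
        }


def candidate_distortion_samples(
    model: ClusterModel, boot_dists: list[DistanceMatrix | np.ndarray], pg: np.ndarray
) -> np.ndarray:
    """One <d> per bootstrap distance matrix with the assignment held fixed."""
    return np.asarray(
        [mean_distortion(d, model.assignment, pg) for d in boot_dists], dtype=float
    )


def passes_cutoff(
    samples: np.ndarray, cutoff: float, rule: str = "median", fraction: float = 0.9
) -> bool:
    """Does a candidate's <d> distribution fall within the error range?

    Default rule: median(samples) <= cutoff (ties pass). Alternatives:
    "all" (every sample <= cutoff) and "fraction" (at least ``fraction``
    of samples <= cutoff).
    """
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("empty distortion sample set")
    if rule == "median":
        return bool(np.median(samples) <= cutoff)
    if rule == "all":
        return bool(np.all(samples <= cutoff))
    if rule == "fraction":
        return bool(np.mean(samples <= cutoff) >= fraction)
    raise ValueError(f"unknown pass rule {rule!r}")


def _selection_key(c: Candidate) -> tuple:
    return (c.model.mutual_info, c.model.effective_n_states, c.model.n_states, c.model.beta)


def sweep_and_select(
    segs: SegmentSet,
    dist: DistanceMatrix,
    boot_dists: list[DistanceMatrix | np.ndarray],
    self_dist: SelfDistortion,
    config: SelectionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> CandidateGrid:
    """Anneal beta for each N_s in 1..n_max and select the adequate model
    with the smallest I(S; g).

    Per N_s the anneal stops when the cutoff is passed, when a K-S test
    finds the <d> distribution unchanged between consecutive beta values
    (armed only after a change has been seen once, since before the anneal
    takes off consecutive distributions are trivially indistinguishable),
    or when the schedule is exhausted. The N_s loop stops early once a
    passing model exists and ``min_improvement_stop`` consecutive N_s
    values fail to improve on its I.
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(rng)
    pg = segs.prior
    if config.n_max < 1:
        raise ValueError("empty candidate grid: n_max must be >= 1")
    cutoff = self_dist.cutoff

    # unit-free beta floor from the one-state (global) distortion
    ones = np.ones((len(segs), 1))
    d1 = mean_distortion(dist, ones, pg)
    beta_min = config.beta_min_scale / d1 if d1 > 0 else config.beta_min_scale

    candidates: list[Candidate] = []
    diagnostics: dict = {"one_state_distortion": d1, "beta_min": beta_min, "per_n_states": {}}
    best_passing_I = np.inf
    n_no_improve = 0

    for n_states in range(1, config.n_max + 1):
        seed_ns = int(rng.integers(0, 2**31 - 1))
        rng_ns = np.random.default_rng(seed_ns)
        warm: ClusterModel | None = None
        prev_samples: np.ndarray | None = None
        ks_armed = False
        termination = "schedule exhausted"
        passed_here = False
        beta = beta_min
        for step in range(config.max_beta_steps):
            model = cluster(
                dist,
                pg,
                n_states,
                beta,
                n_restarts=config.restarts_initial if warm is None else config.restarts_anneal,
                tol=config.tol,
                max_iter=config.max_iter,
                rng=rng_ns,
                init=warm.assignment if warm is not None else None,
            )
            samples = candidate_distortion_samples(model, boot_dists, pg)
            ok = passes_cutoff(samples, cutoff, config.pass_rule, config.pass_fraction)
            cand = Candidate(model, samples, ok)
            candidates.append(cand)
            if ok:
                cand.termination = "cutoff passed"
                termination = "cutoff passed"
                passed_here = True
                break
            if n_states == 1:
                # a single state is beta-independent; one evaluation suffices
                cand.termination = termination = "single state"
                break
            if prev_samples is not None and n_states > 1:
                stagnant, p = ks_converged(prev_samples, samples, config.ks_alpha)
                if not stagnant:
                    ks_armed = True
                elif ks_armed:
                    cand.termination = "K-S stagnation"
                    termination = "K-S stagnation"
                    break
            prev_samples = samples
            warm = model
            beta *= config.beta_ratio
        diagnostics["per_n_states"][n_states] = {
            "termination": termination,
            "passed": passed_here,
            "steps": step + 1,
        }
        if passed_here:
            ns_best_I = min(
                c.model.mutual_info for c in candidates if c.passed and c.model.n_states == n_states
            )
            if ns_best_I < best_passing_I - 1e-12:
                best_passing_I = ns_best_I
                n_no_improve = 0
            else:
                n_no_improve += 1
        elif np.isfinite(best_passing_I):
            n_no_improve += 1
        if np.isfinite(best_passing_I) and n_no_improve >= config.min_improvement_stop:
            diagnostics["stopped_early_at"] = n_states
            break

    passing = [c for c in candidates if c.passed]
    if passing:
        selected = min(passing, key=_selection_key)
        adequate = True
    else:
        warnings.warn("no adequate model: no candidate passed the distortion cutoff", stacklevel=2)
        selected = min(candidates, key=lambda c: c.median_distortion) if candidates else None
        adequate = False
    if selected is None:
        raise ValueError("empty candidate grid")
    return CandidateGrid(candidates, cutoff, selected, adequate, diagnostics)
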