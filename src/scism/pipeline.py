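"""End-to-end orchestration: trajectories in, states/kinetics/landscape out.

The stages are: segmentation -> pairwise Kantorovich distances ->
self-distortion cutoff -> bootstrap distance matrices -> (N_s, beta)
sweep with model selection -> state sequences and kinetics -> TRDG.

For large inputs the distance/bootstrap/clustering stages run on a
uniformly subsampled training subset of segments (``max_train_segments``);
the selected model then assigns every segment through the out-of-sample
rate-distortion posterior, and kinetics use the full sequence.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from . import io as io_mod
from .bootstrap import SelfDistortion, bootstrap_distance_matrices, self_distortion
from .cluster import ClusterModel, merge_degenerate_states, posterior_for_distances
from .distances import DistanceMatrix, cross_distances, pairwise_distances
from .kinetics import (
    CountMatrix,
    KineticsSummary,
    StateSequence,
    detailed_balance_test,
    escape_times,
    most_probable_sequence,
    network_export,
    residence_runs,
    sample_sequences,
    survival_and_exp_test,
    transition_counts,
)
from .segments import SegmentSet, build_segment_set
from .selection import CandidateGrid, SelectionConfig, sweep_and_select
from .trdg import ThermoParams, TRDGTree, build_trdg, state_free_energies, to_newick

__all__ = ["RunConfig", "ScismResult", "run_scism", "run_on_trajectories"]


@dataclass
class RunConfig:
    """Everything a full run needs besides the data."""

    bin_width: float = 3e-3  # s, photon binning
    min_photons: int = 10
    segment_length: int = 33  # points per segment
    observable_range: tuple[float, float] | None = None  # (0, 1) for FRET
    # bootstrap / error model
    boot_batch: int = 100
    boot_cap: int = 5000
    boot_ks_alpha: float = 0.05
    cutoff_percentile: float = 95.0
    n_boot_dist: int = 50
    # model selection
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    # kinetics
    n_realizations: int = 200
    db_alpha: float = 0.05
    # thermodynamics
    temperature: float = 298.0
    tau0: float = 1e-6
    # scalability
    max_train_segments: int = 1500
    seed: int = 0

    def config_hash(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            return o

        blob = json.dumps(clean(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScismResult:
    config: RunConfig
    segments: SegmentSet
    train_indices: np.ndarray
    self_distortion: SelfDistortion
    grid: CandidateGrid
    model: ClusterModel  # selected model on the training subset
    assignment: np.ndarray  # effective-state soft assignment over ALL segments
    state_groups: list[list[int]]
    sequence: StateSequence
    realizations: list[StateSequence]
    counts: CountMatrix
    kinetics: KineticsSummary
    free_energies: dict[int, float]
    tree: TRDGTree | None
    network: nx.Graph
    timings: dict[str, float]
    manifest: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        """Effective number of states of the selected model."""
        return self.assignment.shape[1]

    def state_distribution(self, state: int, mode: str = "assigned") -> tuple[np.ndarray, np.ndarray]:
        """(values, weights) of the observable distribution of one state.

        ``mode="assigned"`` (default) pools the member values of segments
        whose most probable state is ``state``, weighted by the assignment
        confidence p(S_k | g_i) — ambiguous (e.g. transition-straddling)
        segments are downweighted. ``mode="soft"`` weights every segment
        by its conditional probability instead.
        """
        vals = self.segments.value_matrix(sort=False)
        if mode == "assigned":
            sel = self.sequence.labels == state
            if not sel.any():
                return np.empty(0), np.empty(0)
            w = np.repeat(self.assignment[sel, state], vals.shape[1])
            return vals[sel].ravel(), w
        if mode == "soft":
            w = np.repeat(self.assignment[:, state], vals.shape[1])
            return vals.ravel(), w
        raise ValueError(f"unknown mode {mode!r}")

    def state_mean_observables(self) -> np.ndarray:
        vals = self.segments.value_matrix(sort=False).mean(axis=1)
        w = self.assignment * self.segments.prior[:, None]
        pk = w.sum(axis=0)
        return (w * vals[:, None]).sum(axis=0) / pk


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_on_trajectories(
    trajs: Sequence[io_mod.Trajectory],
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> ScismResult:
    """Run the full state-extraction pipeline on binned trajectories."""
    config = config or RunConfig()
    timings: dict[str, float] = {}
    rng_boot, rng_bootd, rng_sweep, rng_kin = _spawn_rngs(config.seed, 4)

    t0 = time.perf_counter()
    segs = build_segment_set(trajs, config.segment_length, config.observable_range)
    timings["segmentation"] = time.perf_counter() - t0

    if len(segs) > config.max_train_segments:
        idx = np.unique(np.round(np.linspace(0, len(segs) - 1, config.max_train_segments)).astype(int))
        train = segs.subset(idx)
    else:
        idx = np.arange(len(segs))
        train = segs

    t0 = time.perf_counter()
    dist = pairwise_distances(train)
    timings["distances"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sd = self_distortion(
        train,
        rng_boot,
        batch=config.boot_batch,
        max_boot=config.boot_cap,
        alpha=config.boot_ks_alpha,
        percentile=config.cutoff_percentile,
    )
    boot_dists = bootstrap_distance_matrices(train, rng_bootd, n_boot=config.n_boot_dist)
    timings["bootstrap"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    grid = sweep_and_select(train, dist, boot_dists, sd, config.selection, rng_sweep)
    model = grid.selected_model
    timings["selection"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if len(train) < len(segs):
        cross = cross_distances(segs.value_matrix(sort=True), train.value_matrix(sort=True))
        assignment_full = posterior_for_distances(cross, model, train.prior, dist.values)
    else:
        assignment_full = model.assignment
    assignment_eff, groups = merge_degenerate_states(assignment_full, segs.prior)
    timings["assignment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tau_seg = config.segment_length * trajs[0].bin_width
    eff_model = ClusterModel(
        n_states=assignment_eff.shape[1],
        beta=model.beta,
        assignment=assignment_eff,
        state_probs=(assignment_eff * segs.prior[:, None]).sum(axis=0),
        mutual_info=model.mutual_info,
        mean_distortion=model.mean_distortion,
        functional_value=model.functional_value,
        seed=config.seed,
    )
    seq = most_probable_sequence(eff_model, segs, tau_seg=tau_seg)
    reals = sample_sequences(eff_model, segs, config.n_realizations, rng_kin, tau_seg=tau_seg)
    counts = transition_counts(seq)
    esc, esc_ci = escape_times(reals, point_sequence=seq)
    survival: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    exp_p: dict[int, float] = {}
    runs = residence_runs(seq)
    for k in range(assignment_eff.shape[1]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve, p = survival_and_exp_test(np.asarray(runs[k], dtype=float) * tau_seg)
        survival[k] = curve
        exp_p[k] = p
    db_p, db_rej = detailed_balance_test(counts, alpha=config.db_alpha)
    kin = KineticsSummary(esc, esc_ci, survival, exp_p, db_p, db_rej)
    timings["kinetics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    thermo = ThermoParams(temperature=config.temperature, tau0=config.tau0, tau_seg=tau_seg)
    fe = state_free_energies(counts, thermo) if counts.n_transitions > 0 else {}
    tree: TRDGTree | None = None
    if len(fe) >= 2:
        pk = eff_model.state_probs
        vals = segs.value_matrix(sort=False).mean(axis=1)
        w = assignment_eff * segs.prior[:, None]
        mean_obs = (w * vals[:, None]).sum(axis=0) / np.where(pk > 0, pk, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = build_trdg(
                fe,
                counts,
                thermo,
                mean_observables={k: float(mean_obs[k]) for k in fe},
                populations={k: float(pk[k]) for k in fe},
            )
    net = network_export(counts, eff_model, segs, free_energies=fe)
    timings["trdg"] = time.perf_counter() - t0

    result = ScismResult(
        config=config,
        segments=segs,
        train_indices=idx,
        self_distortion=sd,
        grid=grid,
        model=model,
        assignment=assignment_eff,
        state_groups=groups,
        sequence=seq,
        realizations=reals,
        counts=counts,
        kinetics=kin,
        free_energies=fe,
        tree=tree,
        network=net,
        timings=timings,
    )
    result.manifest = _manifest(result)
    if output_dir is not None:
        write_artifacts(result, output_dir)
    return result


def run_scism(
    photon_paths: Sequence[str | Path] | None = None,
    trajectory_path: str | Path | None = None,
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> ScismResult:
    """Full run from files: photon streams (binned to FRET efficiency) or a
    pre-binned trajectory table."""
    config = config or RunConfig()
    if (photon_paths is None) == (trajectory_path is None):
        raise ValueError("give exactly one of photon_paths or trajectory_path")
    if photon_paths is not None:
        trajs = []
        for i, p in enumerate(photon_paths):
            stream = io_mod.read_photon_stream(p)
            counts = io_mod.bin_photons(stream, config.bin_width)
            trajs.append(
                io_mod.compute_fret_trajectory(
                    counts, config.bin_width, trajectory_id=f"traj{i}", min_photons=config.min_photons
                )
            )
        if config.observable_range is None:
            config.observable_range = (0.0, 1.0)
    else:
        trajs = io_mod.read_trajectories(trajectory_path)
    return run_on_trajectories(trajs, config, output_dir)


def _manifest(result: ScismResult) -> dict:
    seq_digest = hashlib.sha256(result.sequence.labels.tobytes()).hexdigest()[:16]
    assign_digest = hashlib.sha256(np.ascontiguousarray(result.assignment).tobytes()).hexdigest()[:16]
    return {
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "n_segments": len(result.segments),
        "n_train_segments": len(result.train_indices),
        "n_states": result.n_states,
        "cutoff": result.self_distortion.cutoff,
        "adequate": result.grid.adequate,
        "sequence_sha": seq_digest,
        "assignment_sha": assign_digest,
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
    }


def write_artifacts(result: ScismResult, output_dir: str | Path) -> dict[str, Path]:
    """Write every stage artifact; returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["model"] = out / "model.json"
    io_mod.write_json(result.model.to_dict(), paths["model"])
    paths["grid"] = out / "selection_grid.json"
    io_mod.write_json(result.grid.to_dict(), paths["grid"])
    paths["self_distortion"] = out / "self_distortion.json"
    io_mod.write_json(
        {
            "cutoff": result.self_distortion.cutoff,
            "percentile": result.self_distortion.percentile,
            "n_boot": result.self_distortion.n_boot,
            "converged": result.self_distortion.converged,
            "samples": result.self_distortion.samples,
        },
        paths["self_distortion"],
    )
    paths["kinetics"] = out / "kinetics.json"
    io_mod.write_json(result.kinetics.to_dict(), paths["kinetics"])
    paths["free_energies"] = out / "free_energies.json"
    io_mod.write_json({str(k): v for k, v in result.free_energies.items()}, paths["free_energies"])

    # state sequence TSV with per-state conditionals
    seq_path = out / "state_sequence.tsv"
    frame = result.segments.to_frame()[["trajectory_id", "segment_index", "start_time_s"]].copy()
    frame["label"] = result.sequence.labels
    for k in range(result.n_states):
        frame[f"p_state{k}"] = result.assignment[:, k]
    frame.to_csv(seq_path, sep="\t", index=False)
    paths["sequence"] = seq_path

    nx.write_graphml(result.network, out / "network.graphml")
    paths["network"] = out / "network.graphml"
    with open(out / "network_edges.tsv", "w") as fh:
        fh.write("state_i\tstate_j\tn_forward\tn_backward\tsymmetrized\n")
        for i, j, data in result.network.edges(data=True):
            fh.write(f"{i}\t{j}\t{data['n_forward']}\t{data['n_backward']}\t{data['weight']}\n")
    paths["edges"] = out / "network_edges.tsv"

    if result.tree is not None:
        (out / "trdg.nwk").write_text(to_newick(result.tree) + "\n")
        paths["trdg"] = out / "trdg.nwk"

    paths["manifest"] = out / "manifest.json"
    io_mod.write_json(result.manifest, paths["manifest"])
    return paths
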