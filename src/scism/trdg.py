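"""Transition disconnectivity graphs: state free energies, Kramers barrier
free energies at max-flow/min-cut dividing surfaces, and the merge tree.

State free energies follow from occupancies,

    F_i = -k_B T ln(N_i / N),

with N the total number of transition observations. A barrier between two
disjoint sets of states follows from Kramers' rate theory,
k = tau0^-1 exp(-(F_barrier - F_i)/k_B T), with the transition frequency
across the dividing surface standing in for the rate: combining with the
occupancy form of F_i and eliminating F_i gives the closed form

    F_IJ = -k_B T ln( (tau0 / tau_seg) * N_cut / N ),

where N_cut is the (symmetrized) number of transitions across the cut and
tau_seg the observation time per network visit. Both F_i and F_IJ are
reported relative to the free energy of the most populous state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .kinetics import CountMatrix

__all__ = [
    "ThermoParams",
    "TRDGNode",
    "TRDGTree",
    "state_free_energies",
    "free_energies_from_occupancy",
    "barrier_free_energy",
    "symmetrize",
    "all_pairs_min_cut",
    "build_trdg",
    "to_newick",
]

KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass
class ThermoParams:
    """Temperature, Kramers prefactor timescale and segment duration."""

    temperature: float = 298.0  # K
    tau0: float = 1e-6  # s, Kramers pre-exponential timescale
    tau_seg: float = 0.099  # s, observation time per segment

    def __post_init__(self) -> None:
        if min(self.temperature, self.tau0, self.tau_seg) <= 0:
            raise ValueError("all thermodynamic parameters must be positive")

    @property
    def kt(self) -> float:
        """k_B T in kcal/mol."""
        return KB_KCAL_PER_MOL_K * self.temperature


@dataclass
class TRDGNode:
    """A leaf (state) or internal node (barrier) of the disconnectivity tree."""

    energy: float  # kcal/mol, relative
    states: tuple[int, ...]
    children: list["TRDGNode"] = field(default_factory=list)
    cut_order: int | None = None  # 1 = highest-barrier top split
    cut_edges: list[tuple[int, int]] | None = None
    mean_observable: float | None = None
    population: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class TRDGTree:
    root: TRDGNode
    state_energies: dict[int, float]
    barriers: dict[tuple[int, int], float]  # pairwise barrier, i < j

    @property
    def leaves(self) -> list[TRDGNode]:
        out: list[TRDGNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children)
        return sorted(out, key=lambda n: n.states[0])

    def barrier_between(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        return self.barriers[key]


def state_free_energies(counts: CountMatrix, params: ThermoParams) -> dict[int, float]:
    """F_i = -k_B T ln(N_i / N), shifted so the most populous state is 0.

    N is the total number of transition observations (sum of N_ij); states
    never visited are excluded with a warning.
    """
    n_total = counts.n_transitions
    if n_total == 0:
        raise ValueError("no transitions observed")
    out: dict[int, float] = {}
    for k, n_k in enumerate(counts.n_i):
        if n_k == 0:
            warnings.warn(f"state {k} never visited; excluded from free energies", stacklevel=2)
            continue
        out[k] = -params.kt * np.log(n_k / n_total)
    ref = min(out.values())
    return {k: v - ref for k, v in out.items()}


def free_energies_from_occupancy(occupancy: dict[int, float] | np.ndarray, temperature: float = 298.0) -> dict[int, float]:
    """Relative free energies from occupation probabilities (need not be
    normalized), zeroed at the most populous state."""
    if not isinstance(occupancy, dict):
        occupancy = {k: p for k, p in enumerate(np.asarray(occupancy, dtype=float))}
    kt = KB_KCAL_PER_MOL_K * temperature
    pmax = max(occupancy.values())
    return {k: -kt * np.log(p / pmax) for k, p in occupancy.items() if p > 0}


def barrier_free_energy(n_cut: float, n_total: int, params: ThermoParams, f_ref: float = 0.0) -> float:
    """F_IJ = -k_B T ln((tau0/tau_seg) * N_cut/N), shifted by ``f_ref`` so it
    shares the zero of the state free energies."""
    if n_cut <= 0:
        raise ValueError("N_cut must be positive (zero flow means a disconnected barrier)")
    return float(-params.kt * np.log((params.tau0 / params.tau_seg) * n_cut / n_total) - f_ref)


def symmetrize(counts: CountMatrix) -> np.ndarray:
    """Symmetric capacity matrix C_ij = (N_ij + N_ji)/2 (diagonal zeroed).

    Run and record a detailed-balance test before trusting the resulting
    landscape; symmetrization is only meaningful when N_ij ~ N_ji.
    """
    c = (counts.n_ij + counts.n_ij.T) / 2.0
    np.fill_diagonal(c, 0.0)
    return c


def all_pairs_min_cut(capacity: np.ndarray) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], list[tuple[int, int]]]]:
    """All-pairs min-cut values (and representative cut edge sets) of an
    undirected capacitated graph via its Gomory-Hu tree.

    Disconnected pairs get cut value 0.0 (zero flow), which downstream
    becomes an infinite barrier.
    """
    capacity = np.asarray(capacity, dtype=float)
    n = capacity.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if capacity[i, j] > 0:
                g.add_edge(i, j, capacity=capacity[i, j])
    cuts: dict[tuple[int, int], float] = {}
    cut_edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    components = list(nx.connected_components(g))
    comp_of = {v: ci for ci, comp in enumerate(components) for v in comp}
    trees = {}
    for ci, comp in enumerate(components):
        sub = g.subgraph(comp)
        if len(comp) > 1:
            trees[ci] = nx.gomory_hu_tree(sub, capacity="capacity")
    for i, j in combinations(range(n), 2):
        if comp_of[i] != comp_of[j]:
            cuts[(i, j)] = 0.0
            cut_edges[(i, j)] = []
            continue
        tree = trees[comp_of[i]]
        path = nx.shortest_path(tree, i, j)
        # min-cut value is the lightest edge on the Gomory-Hu tree path
        weights = [(tree[u][v]["weight"], (u, v)) for u, v in zip(path, path[1:])]
        w_min, (u, v) = min(weights, key=lambda t: t[0])
        cuts[(i, j)] = float(w_min)
        # representative cut: edges crossing the two sides of the tree split
        tree_cut = tree.copy()
        tree_cut.remove_edge(u, v)
        side = nx.node_connected_component(tree_cut, i)
        cut_edges[(i, j)] = [
            (a, b) for a in range(n) for b in range(a + 1, n)
            if capacity[a, b] > 0 and ((a in side) != (b in side))
        ]
    return cuts, cut_edges


def build_trdg(
    free_energies: dict[int, float],
    counts: CountMatrix,
    params: ThermoParams,
    mean_observables: dict[int, float] | None = None,
    populations: dict[int, float] | None = None,
) -> TRDGTree:
    """Assemble the disconnectivity tree.

    Pairwise min-cut flows of the symmetrized network are converted to
    barrier free energies and merged agglomeratively from the lowest
    barrier up (single linkage on the barrier ultrametric). The cut order
    index counts internal nodes from the top split (highest barrier)
    downward, matching the order in which dividing surfaces partition the
    network.
    """
    states = sorted(free_energies)
    if any(not np.isfinite(free_energies[s]) for s in states):
        raise ValueError("all state free energies must be finite")
    n_total = counts.n_transitions
    capacity = symmetrize(counts)
    # the free energies were shifted so the most populous state is 0; shift
    # barriers by the same reference
    raw_ref = -params.kt * np.log(counts.n_i.max() / n_total)
    cuts, cut_edges = all_pairs_min_cut(capacity)
    barriers: dict[tuple[int, int], float] = {}
    for (i, j), flow in cuts.items():
        if i not in free_energies or j not in free_energies:
            continue
        if flow <= 0:
            barriers[(i, j)] = float("inf")
            warnings.warn(f"states {i} and {j} are disconnected (infinite barrier)", stacklevel=2)
        else:
            barriers[(i, j)] = barrier_free_energy(flow, n_total, params, f_ref=raw_ref)

    nodes: dict[frozenset, TRDGNode] = {
        frozenset([s]): TRDGNode(
            energy=free_energies[s],
            states=(s,),
            mean_observable=None if mean_observables is None else mean_observables.get(s),
            population=None if populations is None else populations.get(s),
        )
        for s in states
    }
    merges: list[TRDGNode] = []
    while len(nodes) > 1:
        best = None
        for ka, kb in combinations(nodes, 2):
            # single linkage: lowest cross-pair barrier merges first (on the
            # min-cut ultrametric all cross pairs agree up to ties)
            b = min(barriers[(min(i, j), max(i, j))] for i in ka for j in kb)
            if best is None or b < best[0]:
                best = (b, ka, kb)
        b, ka, kb = best
        merged = frozenset(ka | kb)
        node = TRDGNode(
            energy=b,
            states=tuple(sorted(merged)),
            children=[nodes.pop(ka), nodes.pop(kb)],
            cut_edges=sorted(
                {e for i in ka for j in kb for e in cut_edges[(min(i, j), max(i, j))]}
            ),
        )
        nodes[merged] = node
        merges.append(node)
    root = next(iter(nodes.values()))
    # cut order: 1 at the top split (highest barrier), increasing downward
    for rank, node in enumerate(sorted(merges, key=lambda m: -m.energy), start=1):
        node.cut_order = rank
    return TRDGTree(root=root, state_energies=dict(free_energies), barriers=barriers)


def _newick_node(node: TRDGNode, parent_energy: float | None) -> str:
    if node.is_leaf:
        s = node.states[0]
        name = f"S{s}" + (f"_E{node.mean_observable:.2f}" if node.mean_observable is not None else "")
        length = (parent_energy - node.energy) if parent_energy is not None else 0.0
        return f"{name}:{length:.6g}"
    inner = ",".join(_newick_node(c, node.energy) for c in node.children)
    label = f"[&F={node.energy:.6g}]"
    if parent_energy is None:
        return f"({inner}){label}"
    return f"({inner}){label}:{(parent_energy - node.energy):.6g}"


def to_newick(tree: TRDGTree) -> str:
    """Newick text of the tree; branch lengths are energy drops from the
    parent barrier to the child (barrier or state) energy."""
    if tree.root.is_leaf:
        node = tree.root
        name = f"S{node.states[0]}" + (
            f"_E{node.mean_observable:.2f}" if node.mean_observable is not None else ""
        )
        return f"{name};"
    return _newick_node(tree.root, None) + ";"
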