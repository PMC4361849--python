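"""State/barrier free energies, min-cuts and disconnectivity trees."""

import itertools

import numpy as np
import pytest
from io import StringIO

from Bio import Phylo

from scism.kinetics import CountMatrix
from scism.trdg import (
    ThermoParams,
    all_pairs_min_cut,
    barrier_free_energy,
    build_trdg,
    free_energies_from_occupancy,
    state_free_energies,
    symmetrize,
    to_newick,
)

KT298 = 0.0019872041 * 298.0


class TestStateFreeEnergies:
    def test_occupancy_worked_examples(self):
        # two-decimal arithmetic on printed occupation probabilities
        fe = free_energies_from_occupancy({0: 0.41, 1: 0.16, 2: 0.11}, temperature=298.0)
        assert fe[0] == 0.0
        assert round(fe[1], 2) == 0.56
        assert round(fe[2], 2) == 0.78

    def test_equal_occupancy_zero_delta(self):
        fe = free_energies_from_occupancy([0.5, 0.5])
        assert fe[0] == fe[1] == 0.0

    def test_counts_version_zeroed_at_most_populous(self):
        n = np.array([[50, 10], [10, 30]])
        cm = CountMatrix(n, np.array([60, 40]))
        fe = state_free_energies(cm, ThermoParams())
        assert fe[0] == 0.0
        assert fe[1] == pytest.approx(-KT298 * np.log(40 / 60) - 0.0)

    def test_unvisited_state_excluded(self):
        n = np.array([[5, 0], [0, 0]])
        cm = CountMatrix(n, np.array([5, 0]))
        with pytest.warns(UserWarning, match="never visited"):
            fe = state_free_energies(cm, ThermoParams())
        assert 1 not in fe


class TestBarrierFreeEnergy:
    def test_log_of_one_is_zero(self):
        params = ThermoParams(tau_seg=0.099)
        n_cut = 0.099 / 1e-6  # N_cut/N = tau_seg/tau0 with N = 1
        assert barrier_free_energy(n_cut, 1, params) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation(self):
        params = ThermoParams(temperature=298.0, tau0=1e-6, tau_seg=0.099)
        expect = KT298 * np.log(0.099 * 1e4 / (1e-6 * 50))
        assert barrier_free_energy(50, 10_000, params) == pytest.approx(expect, abs=1e-10)

    def test_doubling_flow_lowers_by_kt_ln2(self):
        params = ThermoParams()
        f1 = barrier_free_energy(25, 10_000, params)
        f2 = barrier_free_energy(50, 10_000, params)
        assert f1 - f2 == pytest.approx(KT298 * np.log(2), abs=1e-12)

    def test_zero_cut_raises(self):
        with pytest.raises(ValueError):
            barrier_free_energy(0, 100, ThermoParams())


class TestSymmetrize:
    def test_average(self):
        n = np.array([[0, 3], [5, 0]])
        c = symmetrize(CountMatrix(n, n.sum(1)))
        assert c[0, 1] == c[1, 0] == 4.0

    def test_symmetric_unchanged_mass_conserved(self, rng):
        n = rng.integers(0, 20, (4, 4))
        c = symmetrize(CountMatrix(n, n.sum(1)))
        off = ~np.eye(4, dtype=bool)
        assert c.sum() == pytest.approx(n[off].sum())
        np.testing.assert_allclose(c, c.T)


def brute_force_min_cut(capacity, i, j):
    n = capacity.shape[0]
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        side = np.array([(bits >> k) & 1 for k in range(n)], bool)
        if not side[i]:
            side = ~side
        if side[j]:
            continue
        cut = sum(
            capacity[a, b]
            for a in range(n)
            for b in range(n)
            if a < b and side[a] != side[b] and capacity[a, b] > 0
        )
        best = min(best, cut)
    return best


class TestAllPairsMinCut:
    def test_two_nodes(self):
        cuts, _ = all_pairs_min_cut(np.array([[0, 3.0], [3.0, 0]]))
        assert cuts[(0, 1)] == 3.0

    def test_path_graph(self):
        c = np.zeros((3, 3))
        c[0, 1] = c[1, 0] = 5
        c[1, 2] = c[2, 1] = 2
        cuts, edges = all_pairs_min_cut(c)
        assert cuts[(0, 2)] == 2.0
        assert edges[(0, 2)] == [(1, 2)]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        c = rng.integers(0, 8, (n, n)).astype(float)
        c = (c + c.T) / 2
        np.fill_diagonal(c, 0)
        cuts, _ = all_pairs_min_cut(c)
        for i, j in itertools.combinations(range(n), 2):
            assert cuts[(i, j)] == pytest.approx(brute_force_min_cut(c, i, j)), (i, j)

    def test_ultrametric_triples(self, rng):
        n = 6
        c = rng.random((n, n)) * 5
        c = (c + c.T) / 2
        np.fill_diagonal(c, 0)
        cuts, _ = all_pairs_min_cut(c)

        def cut(i, j):
            return cuts[(min(i, j), max(i, j))]

        for i, j, k in itertools.permutations(range(n), 3):
            assert cut(i, k) >= min(cut(i, j), cut(j, k)) - 1e-9


def example_counts(rng, n_states=4, n_steps=5000):
    """Counts from a reversible chain over a linear topology."""
    rates = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        rates[i, i + 1] = rates[i + 1, i] = rng.uniform(0.05, 0.3)
    labels = [0]
    p = rates / np.maximum(rates.sum(1, keepdims=True), 1e-12) * rates.sum(1, keepdims=True).clip(0, 0.9)
    stay = 1 - p.sum(1)
    for _ in range(n_steps):
        s = labels[-1]
        probs = np.append(p[s], stay[s])
        nxt = rng.choice(n_states + 1, p=probs / probs.sum())
        labels.append(s if nxt == n_states else nxt)
    labels = np.asarray(labels)
    n_ij = np.zeros((n_states, n_states), int)
    np.add.at(n_ij, (labels[:-1], labels[1:]), 1)
    return CountMatrix(n_ij, np.bincount(labels, minlength=n_states))


class TestBuildTrdg:
    def test_two_states(self):
        n = np.array([[40, 10], [10, 40]])
        cm = CountMatrix(n, n.sum(1))
        params = ThermoParams(tau_seg=0.099)
        fe = state_free_energies(cm, params)
        tree = build_trdg(fe, cm, params)
        assert not tree.root.is_leaf
        assert len(tree.leaves) == 2
        assert tree.root.cut_order == 1
        # barrier from the tree equals the direct pairwise value
        assert tree.root.energy == pytest.approx(tree.barrier_between(0, 1))

    def test_merge_order_and_ultrametric(self, rng):
        cm = example_counts(rng)
        params = ThermoParams(tau_seg=0.099)
        fe = state_free_energies(cm, params)
        tree = build_trdg(fe, cm, params)
        bar = tree.barriers
        for i, j, k in itertools.permutations(sorted(fe), 3):
            def b(a, c):
                return bar[(min(a, c), max(a, c))]
            assert b(i, k) <= max(b(i, j), b(j, k)) + 1e-9
        # leaves sit at their state free energies, below their parent barrier
        for leaf in tree.leaves:
            assert leaf.energy == pytest.approx(fe[leaf.states[0]])

    def test_barriers_above_state_energies(self, rng):
        cm = example_counts(rng)
        params = ThermoParams(tau_seg=0.099)
        fe = state_free_energies(cm, params)
        tree = build_trdg(fe, cm, params)
        for (i, j), b in tree.barriers.items():
            assert b >= max(fe[i], fe[j]) - 1e-9

    def test_occupancy_orders_free_energy(self, rng):
        cm = example_counts(rng)
        fe = state_free_energies(cm, ThermoParams())
        order_fe = sorted(fe, key=lambda k: fe[k])
        order_occ = sorted(fe, key=lambda k: -cm.n_i[k])
        assert order_fe == order_occ


class TestNewick:
    def test_two_leaf_arithmetic(self):
        n = np.array([[40, 10], [10, 40]])
        cm = CountMatrix(n, n.sum(1))
        params = ThermoParams(tau_seg=0.099)
        fe = state_free_energies(cm, params)
        tree = build_trdg(fe, cm, params)
        text = to_newick(tree)
        assert text.endswith(";")
        assert "S0" in text and "S1" in text

    def test_round_trip_topology(self, rng):
        cm = example_counts(rng)
        params = ThermoParams(tau_seg=0.099)
        fe = state_free_energies(cm, params)
        tree = build_trdg(fe, cm, params)
        clade_tree = Phylo.read(StringIO(to_newick(tree)), "newick")
        names = sorted(t.name.split("_")[0] for t in clade_tree.get_terminals())
        assert names == [f"S{k}" for k in sorted(fe)]
        # branch lengths encode energy drops: depth of each leaf from the root
        # equals root barrier minus leaf energy
        root_energy = tree.root.energy
        for leaf in clade_tree.get_terminals():
            k = int(leaf.name[1:].split("_")[0])
            depth = clade_tree.distance(leaf)
            assert depth == pytest.approx(root_energy - fe[k], abs=1e-4)

    def test_single_leaf(self):
        from scism.trdg import TRDGNode, TRDGTree

        t = TRDGTree(TRDGNode(0.0, (0,)), {0: 0.0}, {})
        assert to_newick(t) == "S0;"
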