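"""Rate-distortion functional, Blahut-Arimoto updates and their invariants."""

import itertools

import numpy as np
import pytest

from scism.cluster import (
    _functional,
    ba_step,
    cluster,
    effective_distortion,
    mean_distortion,
    merge_degenerate_states,
    mutual_information,
)
from scism.distances import pairwise_from_values


def random_instance(seed, n=10, k=3):
    rng = np.random.default_rng(seed)
    d = np.abs(rng.normal(size=(n, n)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    pg = rng.dirichlet(np.ones(n))
    assign = rng.dirichlet(np.ones(k), size=n)
    return d, pg, assign


def two_cloud_matrix(rng, n_per=10, sep=0.6, spread=0.01):
    vals = np.concatenate(
        [rng.normal(0.2, spread, (n_per, 16)), rng.normal(0.2 + sep, spread, (n_per, 16))]
    )
    return pairwise_from_values(np.sort(vals, axis=1)), len(vals)


class TestMeanDistortion:
    def test_single_state_is_global_mean(self, rng):
        d, pg, _ = random_instance(1)
        ones = np.ones((10, 1))
        expect = np.einsum("i,j,ij->", pg, pg, d)
        assert mean_distortion(d, ones, pg) == pytest.approx(expect, abs=1e-14)

    def test_hard_two_cluster_oracle(self, rng):
        d, _, _ = random_instance(2, n=8)
        pg = np.full(8, 1 / 8)
        assign = np.zeros((8, 2))
        assign[:4, 0] = 1
        assign[4:, 1] = 1
        # direct summation oracle
        expect = 0.0
        for grp in (range(4), range(4, 8)):
            w = 0.5
            within = np.mean([d[i, j] for i in grp for j in grp])
            expect += w * within
        assert mean_distortion(d, assign, pg) == pytest.approx(expect, abs=1e-12)

    def test_zero_distance_matrix(self):
        _, pg, assign = random_instance(3)
        assert mean_distortion(np.zeros((10, 10)), assign, pg) == 0.0


class TestEffectiveDistortion:
    def test_zero_diameter_cluster(self):
        # all segments identical: any member has zero effective distortion
        d = np.zeros((4, 4))
        pg = np.full(4, 0.25)
        assign = np.ones((4, 1))
        np.testing.assert_allclose(effective_distortion(d, assign, pg), 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_consistency_identity(self, seed):
        # sum_i p(g_i|S_k) d_eff(g_i, S_k) equals the per-state pairwise distortion
        d, pg, assign = random_instance(seed)
        de = effective_distortion(d, assign, pg)
        w = assign * pg[:, None]
        pk = w.sum(0)
        q = (w / pk).T
        c = np.einsum("kj,jl,kl->k", q, d, q)
        np.testing.assert_allclose((q * de.T).sum(axis=1), c, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_gradient_of_functional(self, seed):
        # d_eff is the distortion part of the exact gradient of F
        d, pg, assign = random_instance(seed, n=7, k=2)
        beta = 2.3
        de = effective_distortion(d, assign, pg)
        pk = (assign * pg[:, None]).sum(0)
        analytic = pg[:, None] * (np.log(assign / pk[None, :]) + beta * de)
        eps = 1e-6
        num = np.zeros_like(assign)
        for i in range(7):
            for k in range(2):
                up, dn = assign.copy(), assign.copy()
                up[i, k] += eps
                dn[i, k] -= eps
                num[i, k] = (_functional(d, up, pg, beta) - _functional(d, dn, pg, beta)) / (2 * eps)
        np.testing.assert_allclose(num, analytic, atol=1e-6)


class TestMutualInformation:
    def test_independent_assignment_zero(self):
        pg = np.full(6, 1 / 6)
        pk = np.array([0.3, 0.7])
        assign = np.tile(pk, (6, 1))
        assert mutual_information(assign, pg) == pytest.approx(0.0, abs=1e-14)

    def test_balanced_hard_partition_one_bit(self):
        pg = np.full(4, 0.25)
        assign = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        assert mutual_information(assign, pg) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_double_sum_oracle(self, seed):
        _, pg, assign = random_instance(seed)
        pk = (assign * pg[:, None]).sum(0)
        expect = sum(
            pg[i] * assign[i, k] * np.log2(assign[i, k] / pk[k])
            for i in range(10)
            for k in range(3)
            if assign[i, k] > 0
        )
        assert mutual_information(assign, pg) == pytest.approx(expect, abs=1e-12)


class TestBaStep:
    def test_beta_zero_gives_marginal(self, rng):
        d, pg, assign = random_instance(5)
        new = ba_step(d, assign, pg, 0.0)
        pk = (assign * pg[:, None]).sum(0)
        np.testing.assert_allclose(new, np.tile(pk, (10, 1)), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        d, pg, assign = random_instance(6)
        new = ba_step(d, assign, pg, 7.0)
        np.testing.assert_allclose(new.sum(axis=1), 1.0, atol=1e-12)

    def test_large_beta_hardens_to_nearest_group(self, rng):
        d, n = two_cloud_matrix(rng)
        pg = np.full(n, 1 / n)
        assign = np.zeros((n, 2)) + 0.5
        assign[: n // 2, 0] = 0.9
        assign[: n // 2, 1] = 0.1
        for _ in range(50):
            assign = ba_step(d, assign, pg, 5000.0)
        hard = np.round(assign)
        np.testing.assert_allclose(np.abs(assign - hard).max(), 0.0, atol=1e-6)
        assert len(set(np.argmax(assign[: n // 2], 1))) == 1
        assert np.argmax(assign[0]) != np.argmax(assign[-1])


class TestCluster:
    def test_one_state_limit(self, rng):
        d, pg, _ = random_instance(7)
        m = cluster(d, pg, 1, beta=3.0, n_restarts=1, rng=0)
        assert m.mutual_info == pytest.approx(0.0, abs=1e-12)
        expect = np.einsum("i,j,ij->", pg, pg, d)
        assert m.functional_value == pytest.approx(3.0 * expect, abs=1e-10)

    def test_two_separated_clouds_vs_brute_force(self, rng):
        d, n = two_cloud_matrix(rng)
        pg = np.full(n, 1 / n)
        m = cluster(d, pg, 2, beta=5000.0, n_restarts=8, rng=1)
        assert m.mutual_info == pytest.approx(1.0, abs=1e-3)
        labels = np.argmax(m.assignment, axis=1)
        # brute force over all hard 2-partitions: the recovered split must be optimal
        best = None
        for mask_bits in range(1, 2 ** (n - 1)):
            mask = np.array([(mask_bits >> i) & 1 for i in range(n)], bool)
            if mask.all() or (~mask).all():
                continue
            assign = np.stack([mask, ~mask], axis=1).astype(float)
            f = _functional(d, np.clip(assign, 1e-12, None) / np.clip(assign, 1e-12, None).sum(1, keepdims=True), pg, 5000.0)
            if best is None or f < best[0]:
                best = (f, mask)
        _, mask = best
        same = (labels == labels[0]) == (mask == mask[0])
        assert same.all()

    def test_functional_monotone_within_restart(self, rng):
        d, pg, _ = random_instance(8, n=14, k=3)
        m = cluster(d, pg, 3, beta=2.0, n_restarts=4, rng=2)
        diffs = np.diff(m.functional_history)
        assert (diffs <= 1e-9 * np.maximum(1.0, np.abs(m.functional_history[:-1]))).all()
        assert m.monotone

    def test_label_permutation_invariance(self, rng):
        d, pg, assign = random_instance(9)
        perm = assign[:, [2, 0, 1]]
        for a in (assign, perm):
            pass
        i1 = mutual_information(assign, pg)
        i2 = mutual_information(perm, pg)
        d1 = mean_distortion(d, assign, pg)
        d2 = mean_distortion(d, perm, pg)
        assert i1 == pytest.approx(i2, abs=1e-12)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_annealed_distortion_non_increasing(self, rng):
        d, n = two_cloud_matrix(rng, sep=0.3, spread=0.05)
        pg = np.full(n, 1 / n)
        warm = None
        prev = np.inf
        for beta in [1.0, 3.0, 10.0, 30.0, 100.0, 300.0]:
            m = cluster(d, pg, 2, beta, n_restarts=2, rng=3, init=warm)
            assert m.mean_distortion <= prev + 1e-9
            prev = m.mean_distortion
            warm = m.assignment

    def test_info_bounds(self, rng):
        d, pg, _ = random_instance(10, n=12, k=4)
        m = cluster(d, pg, 4, beta=50.0, n_restarts=3, rng=4)
        assert 0.0 <= m.mutual_info <= np.log2(4) + 1e-12

    def test_invalid_args(self, rng):
        d, pg, _ = random_instance(11)
        with pytest.raises(ValueError):
            cluster(d, pg, 0, 1.0)
        with pytest.raises(ValueError):
            cluster(d, pg, 2, -1.0)


class TestMergeDegenerateStates:
    def test_duplicate_columns_merge(self):
        pg = np.full(4, 0.25)
        col = np.array([0.6, 0.6, 0.1, 0.1])
        assign = np.stack([col / 2, col / 2, 1 - col], axis=1)
        merged, groups = merge_degenerate_states(assign, pg)
        assert merged.shape[1] == 2
        assert sorted(map(sorted, groups)) == [[0, 1], [2]]
        np.testing.assert_allclose(merged.sum(axis=1), 1.0)

    def test_empty_state_dropped(self):
        pg = np.full(3, 1 / 3)
        assign = np.array([[1, 0], [1, 0], [1, 0]], dtype=float)
        merged, groups = merge_degenerate_states(assign, pg)
        assert merged.shape[1] == 1
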