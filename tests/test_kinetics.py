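"""State sequences, transition counting, escape times, survival and
detailed-balance tests."""

import numpy as np
import pytest
from scipy import stats

from scism.cluster import ClusterModel
from scism.kinetics import (
    CountMatrix,
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

from .conftest import make_segment_set


def model_from_assignment(assign, pg):
    assign = np.asarray(assign, dtype=float)
    pk = (assign * np.asarray(pg)[:, None]).sum(0)
    return ClusterModel(
        n_states=assign.shape[1],
        beta=1.0,
        assignment=assign,
        state_probs=pk,
        mutual_info=0.0,
        mean_distortion=0.0,
        functional_value=0.0,
    )


def seq_from_labels(labels, n_states, tau=0.099, boundaries=()):
    labels = np.asarray(labels)
    adjacency = np.ones(len(labels), bool)
    adjacency[-1] = False
    for b in boundaries:
        adjacency[b] = False
    return StateSequence(labels, adjacency, tau, n_states)


class TestMostProbableSequence:
    def test_hard_assignment(self, rng):
        ss = make_segment_set(rng.random((4, 6)))
        assign = np.array([[1, 0], [0, 1], [0, 1], [1, 0]], dtype=float)
        seq = most_probable_sequence(model_from_assignment(assign, ss.prior), ss)
        assert seq.labels.tolist() == [0, 1, 1, 0]

    def test_tie_goes_to_lowest_index(self, rng):
        ss = make_segment_set(rng.random((2, 6)))
        assign = np.full((2, 3), 1 / 3)
        with pytest.warns(UserWarning, match="tied"):
            seq = most_probable_sequence(model_from_assignment(assign, ss.prior), ss)
        assert seq.labels.tolist() == [0, 0]

    def test_argmax_oracle(self, rng):
        ss = make_segment_set(rng.random((20, 6)))
        assign = rng.dirichlet(np.ones(4), size=20)
        seq = most_probable_sequence(model_from_assignment(assign, ss.prior), ss)
        np.testing.assert_array_equal(seq.labels, assign.argmax(axis=1))


class TestSampleSequences:
    def test_hard_assignment_identical_realizations(self, rng):
        ss = make_segment_set(rng.random((5, 6)))
        assign = np.eye(5)
        reals = sample_sequences(model_from_assignment(assign, ss.prior), ss, 10, rng=0)
        for r in reals:
            np.testing.assert_array_equal(r.labels, np.arange(5))

    def test_marginal_frequency(self, rng):
        ss = make_segment_set(rng.random((1, 6)))
        assign = np.array([[0.7, 0.3]])
        reals = sample_sequences(model_from_assignment(assign, ss.prior), ss, 10_000, rng=1)
        freq = np.mean([r.labels[0] == 0 for r in reals])
        sd = np.sqrt(0.7 * 0.3 / 10_000)
        assert abs(freq - 0.7) < 3 * sd

    def test_seed_reproducibility(self, rng):
        ss = make_segment_set(rng.random((8, 6)))
        assign = rng.dirichlet(np.ones(3), size=8)
        m = model_from_assignment(assign, ss.prior)
        a = sample_sequences(m, ss, 5, rng=42)
        b = sample_sequences(m, ss, 5, rng=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.labels, y.labels)


class TestTransitionCounts:
    def test_small_example(self):
        seq = seq_from_labels([0, 0, 1], 2)
        cm = transition_counts(seq)
        assert cm.n_ij[0, 0] == 1 and cm.n_ij[0, 1] == 1
        assert cm.n_i.tolist() == [2, 1]

    def test_no_counting_across_trajectory_boundary(self):
        seq = StateSequence(np.array([0, 1]), np.array([False, False]), 0.099, 2)
        assert transition_counts(seq).n_ij.sum() == 0

    def test_conservation(self, rng):
        labels = rng.integers(0, 3, 50)
        seq = seq_from_labels(labels, 3, boundaries=[9, 24])
        cm = transition_counts(seq)
        assert cm.n_ij.sum() == seq.adjacency[:-1].sum()

    def test_markov_chain_rates(self, rng):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = [0]
        for _ in range(20_000):
            labels.append(rng.choice(2, p=p[labels[-1]]))
        cm = transition_counts(seq_from_labels(labels, 2))
        est = cm.n_ij / cm.n_ij.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(est, p, atol=0.02)


class TestEscapeTimes:
    def test_censoring_contract(self):
        # [A,A,B,A,A,A,B]: only the middle A-run of 3 is complete
        seq = seq_from_labels([0, 0, 1, 0, 0, 0, 1], 2, tau=0.099)
        runs = residence_runs(seq)
        assert runs[0] == [3]
        point, _ = escape_times([seq], point_sequence=seq)
        assert point[0] == pytest.approx(0.297)

    def test_deterministic_alternation(self):
        seq = seq_from_labels([0, 1] * 10, 2, tau=0.099)
        point, ci = escape_times([seq], point_sequence=seq)
        assert point[0] == pytest.approx(0.099)
        assert point[1] == pytest.approx(0.099)
        assert ci[0][0] <= point[0] <= ci[0][1]

    def test_ctmc_recovery(self, rng):
        # geometric dwell in discrete segments approximates exponential escape
        k = 2.0  # 1/s
        tau = 0.099
        p_stay = np.exp(-k * tau)
        labels = []
        state = 0
        for _ in range(40_000):
            labels.append(state)
            if rng.random() > p_stay:
                state = 1 - state
        seq = seq_from_labels(labels, 2, tau=tau)
        point, ci = escape_times([seq], point_sequence=seq)
        # mean discrete dwell = tau/(1-p_stay) ~ 1/k for k*tau << 1
        assert point[0] == pytest.approx(tau / (1 - p_stay), rel=0.06)

    def test_never_visited_state_warns(self):
        seq = seq_from_labels([0, 0, 0, 0], 2)
        with pytest.warns(UserWarning, match="escape time undefined"):
            point, _ = escape_times([seq], point_sequence=seq)
        assert np.isnan(point[1])


class TestSurvivalExpTest:
    def test_null_calibration(self):
        # iid exponential residences: p-values ~ U(0,1), ~5% rejections
        rejections = 0
        pvals = []
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            res = rng.exponential(0.3, size=500)
            _, p = survival_and_exp_test(res)
            pvals.append(p)
            rejections += p < 0.05
        rate = rejections / 200
        assert 0.005 <= rate <= 0.12  # binomial band around 5%
        # crude uniformity check on p-values
        assert 0.3 < np.mean(pvals) < 0.7

    def test_bimodal_mixture_power(self):
        rejected = 0
        for s in range(50):
            rng = np.random.default_rng(2000 + s)
            res = np.concatenate([rng.exponential(0.05, 250), rng.exponential(2.0, 250)])
            _, p = survival_and_exp_test(res)
            rejected += p < 0.05
        assert rejected >= 45  # >= 90% power

    def test_constant_residences_reject(self):
        (t, s), p = survival_and_exp_test(np.full(50, 0.5))
        assert p == pytest.approx(0.0, abs=1e-10)
        assert s[0] == 1.0 and s[-1] == 0.0

    def test_too_few_runs_nan(self):
        with pytest.warns(UserWarning):
            _, p = survival_and_exp_test(np.array([0.1, 0.2]))
        assert np.isnan(p)

    def test_survival_curve_monotone(self, rng):
        (t, s), _ = survival_and_exp_test(rng.exponential(1.0, 100))
        assert (np.diff(s) <= 0).all()
        assert s[0] == 1.0


class TestDetailedBalance:
    def test_symmetric_counts_not_rejected(self):
        n = np.array([[5, 10, 3], [10, 2, 7], [3, 7, 1]])
        cm = CountMatrix(n, n.sum(1))
        pvals, rejected = detailed_balance_test(cm)
        assert all(p == 1.0 for p in pvals.values())
        assert not rejected

    def test_asymmetric_pair_binomial_oracle(self):
        n = np.zeros((2, 2), int)
        n[0, 1], n[1, 0] = 100, 50
        cm = CountMatrix(n, n.sum(1))
        pvals, rejected = detailed_balance_test(cm, alpha=0.05)
        expect = stats.binomtest(100, 150, 0.5).pvalue
        assert pvals[(0, 1)] == pytest.approx(expect, abs=1e-12)
        assert rejected

    def test_type_one_error_calibration(self):
        # equilibrium (reversible) chain: rejections near alpha
        p = np.array([[0.8, 0.15, 0.05], [0.15, 0.8, 0.05], [0.1, 0.1, 0.8]])
        # make it reversible: symmetric jump proposal => symmetric expected flux
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0)
        p = p / p.sum(1, keepdims=True) * 0.3
        np.fill_diagonal(p, 1 - p.sum(1))
        rejections = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(3000 + s)
            state = 0
            labels = np.empty(2000, int)
            for i in range(2000):
                labels[i] = state
                state = rng.choice(3, p=p[state])
            cm = transition_counts(seq_from_labels(labels, 3))
            _, rejected = detailed_balance_test(cm, alpha=0.05)
            rejections += rejected
        rate = rejections / n_rep
        # Bonferroni across 3 pairs is conservative; allow [0, 2*alpha]
        assert rate <= 0.10


def test_network_export(rng):
    ss = make_segment_set(np.concatenate([np.full((3, 6), 0.2), np.full((3, 6), 0.8)]))
    assign = np.zeros((6, 2))
    assign[:3, 0] = 1
    assign[3:, 1] = 1
    n = np.array([[2, 1], [1, 1]])
    cm = CountMatrix(n, np.array([3, 3]))
    g = network_export(cm, model_from_assignment(assign, ss.prior), ss)
    assert g[0][1]["weight"] == pytest.approx(1.0)
    assert sum(d["p"] for _, d in g.nodes(data=True)) == pytest.approx(1.0)
    assert g.nodes[0]["mean_observable"] == pytest.approx(0.2)
    assert g.nodes[1]["mean_observable"] == pytest.approx(0.8)
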