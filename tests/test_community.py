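"""Louvain, fine-tuning, best-of-R selection, agreement matrices and
consensus clustering, checked against exhaustive enumeration, pair-count
oracles, planted-partition recovery, and networkx's independent Louvain."""

import numpy as np
import pytest

from _oracles import (
    exhaustive_max_modularity,
    modularity_percommunity,
    nmi_entropy,
)
from conftest import random_binary_graph, two_cliques
from restnet import community as cm
from restnet.community import ConsensusParams, Partition


class TestLouvain:
    def test_disconnected_cliques_split_by_component(self):
        part = cm.louvain(two_cliques(3), gamma=1.0, seed=0)
        assert part.module_count == 2
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1

    def test_complete_graph_is_single_module_by_exhaustion(self):
        K6 = np.ones((6, 6)) - np.eye(6)
        part = cm.louvain(K6, gamma=1.0, seed=3)
        assert part.module_count == 1
        q = cm.weighted_modularity(K6, part.labels, 1.0)
        assert np.isclose(q, exhaustive_max_modularity(K6, 1.0), atol=1e-12)

    def test_planted_sbm_blocks_recovered(self, rng):
        truth = np.repeat(np.arange(4), 8)
        p = np.where(truth[:, None] == truth[None, :], 0.9, 0.05)
        a = (rng.random((32, 32)) < p).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        part, _ = cm.best_partition(a, gamma=1.0, runs=10, seed=4)
        assert np.isclose(nmi_entropy(part.labels, truth), 1.0)

    def test_all_zero_weights_raise(self):
        with pytest.raises(ValueError, match="no edges"):
            cm.louvain(np.zeros((4, 4)), 1.0, 0)

    def test_relabeling_invariance_up_to_permutation(self, rng):
        # on a graph with a unique optimum, the recovered structure must not
        # depend on how the nodes happen to be numbered
        truth = np.repeat(np.arange(4), 6)
        p = np.where(truth[:, None] == truth[None, :], 0.95, 0.02)
        a = (rng.random((24, 24)) < p).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        perm = rng.permutation(24)
        part, _ = cm.best_partition(a, 1.0, runs=10, seed=9)
        part_p, _ = cm.best_partition(a[np.ix_(perm, perm)], 1.0, runs=10, seed=10)
        mapped = np.empty(24, dtype=int)
        mapped[perm] = part_p.labels
        assert np.isclose(nmi_entropy(part.labels, mapped), 1.0)

    def test_agrees_with_networkx_on_strongly_modular_graph(self):
        import networkx as nx

        a = two_cliques(5)
        a[0, 5] = a[5, 0] = 1.0  # one bridge
        ours = cm.louvain(a, gamma=1.0, seed=0)
        G = nx.from_numpy_array(a)
        nx_comms = nx.community.louvain_communities(G, resolution=1.0, seed=0)
        nx_labels = np.empty(10, dtype=int)
        for lab, comm in enumerate(nx_comms):
            for node in comm:
                nx_labels[node] = lab
        assert np.isclose(nmi_entropy(ours.labels, nx_labels), 1.0)


class TestFineTune:
    def test_optimal_partition_is_fixed_point(self):
        a = two_cliques(3)
        opt = Partition(np.array([0, 0, 0, 1, 1, 1]))
        assert cm.fine_tune(a, opt, 1.0) == opt

    def test_single_mislabeled_node_restored(self):
        a = two_cliques(3)
        bad = Partition(np.array([0, 0, 1, 1, 1, 1]))
        fixed = cm.fine_tune(a, bad, 1.0)
        assert fixed == Partition(np.array([0, 0, 0, 1, 1, 1]))

    def test_never_decreases_modularity_over_seeded_trials(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            a = random_binary_graph(rng, 12, 0.35)
            init = Partition(rng.integers(0, 4, 12))
            q0 = cm.weighted_modularity(a, init.labels, 1.0)
            q1 = cm.weighted_modularity(a, cm.fine_tune(a, init, 1.0).labels, 1.0)
            assert q1 >= q0 - 1e-12


class TestBestPartition:
    def test_single_run_equals_one_louvain_finetune(self):
        a = two_cliques(4)
        part, q = cm.best_partition(a, 1.0, runs=1, seed=5)
        rng = list(cm._spawn_seeds(5, 1))[0]
        direct = cm.fine_tune(a, cm.louvain(a, 1.0, rng), 1.0)
        assert part == direct

    def test_reaches_exhaustive_maximum_on_two_cliques(self):
        a = two_cliques(3)
        _, q = cm.best_partition(a, 1.0, runs=5, seed=0)
        assert np.isclose(q, exhaustive_max_modularity(a, 1.0), atol=1e-12)
        assert np.isclose(q, 0.5)

    def test_same_seed_identical_output(self, rng):
        a = random_binary_graph(rng, 14, 0.3)
        r1 = cm.best_partition(a, 1.25, runs=8, seed=21)
        r2 = cm.best_partition(a, 1.25, runs=8, seed=21)
        assert r1[0] == r2[0] and r1[1] == r2[1]


class TestAgreement:
    def test_identical_partitions_give_comembership_indicator(self):
        p = Partition(np.array([0, 0, 1, 1]))
        A = cm.agreement([p, p, p])
        expected = (p.labels[:, None] == p.labels[None, :]).astype(float)
        np.testing.assert_allclose(A, expected)

    def test_half_agreement(self):
        p1 = Partition(np.array([0, 0, 1]))
        p2 = Partition(np.array([0, 1, 1]))
        A = cm.agreement([p1, p2])
        assert A[0, 1] == 0.5 and A[1, 2] == 0.5 and A[0, 2] == 0.0

    def test_matches_pair_count_oracle(self, rng):
        parts = [Partition(rng.integers(0, 3, 8)) for _ in range(10)]
        A = cm.agreement(parts)
        for i in range(8):
            for j in range(8):
                count = sum(p.labels[i] == p.labels[j] for p in parts)
                assert A[i, j] == pytest.approx(count / 10)

    def test_mismatched_node_sets_raise(self):
        with pytest.raises(ValueError, match="different node sets"):
            cm.agreement([Partition(np.zeros(4, dtype=int)), Partition(np.zeros(5, dtype=int))])


class TestConsensus:
    def test_unanimous_input_returns_that_partition(self):
        p = Partition(np.array([0, 0, 1, 1, 2, 2]))
        out = cm.consensus_partition([p] * 10, ConsensusParams(runs=5, seed=0))
        assert out == p

    def test_recovers_planted_blocks_from_corrupted_ensemble(self, rng):
        truth = np.repeat(np.arange(4), 8)
        parts = []
        for _ in range(20):
            lab = truth.copy()
            flip = rng.random(32) < 0.10
            lab[flip] = rng.integers(0, 4, int(flip.sum()))
            parts.append(Partition(lab))
        out = cm.consensus_partition(
            parts, ConsensusParams(gamma=1.25, tau=0.5, runs=20, seed=2)
        )
        assert np.isclose(nmi_entropy(out.labels, truth), 1.0)

    def test_saturated_tau_raises(self, rng):
        parts = [Partition(rng.permutation(6) % 3) for _ in range(8)]
        with pytest.raises((ValueError, RuntimeError), match="tau"):
            cm.consensus_partition(parts, ConsensusParams(tau=0.99, runs=5, seed=0))


class TestSubjectGroupConsensus:
    def test_noiseless_block_matrix_recovers_planted_modules(self):
        from restnet.connectivity import ConnectivityMatrix
        from restnet.synthetic import build_block_covariance

        cov = build_block_covariance([6, 6, 6], 0.6, 0.05)
        z = np.arctanh(np.clip(cov - np.eye(18), -0.999999, 0.999999))
        np.fill_diagonal(z, 0.0)
        C = ConnectivityMatrix(values=z, node_ids=tuple(f"n{i}" for i in range(18)))
        part = cm.subject_consensus(C, ConsensusParams(gamma=1.0, runs=10, seed=0))
        assert np.isclose(nmi_entropy(part.labels, np.repeat(np.arange(3), 6)), 1.0)

    def test_subject_consensus_deterministic(self, small_cohort):
        from restnet.connectivity import correlation_matrix

        _, cohort = small_cohort
        C = correlation_matrix(cohort.timeseries[("y01", 1)])
        params = ConsensusParams(runs=8, seed=13)
        assert cm.subject_consensus(C, params) == cm.subject_consensus(C, params)

    def test_uniform_matrix_gives_single_module(self):
        from restnet.connectivity import ConnectivityMatrix

        v = np.full((6, 6), 0.4)
        np.fill_diagonal(v, 0.0)
        C = ConnectivityMatrix(values=v, node_ids=tuple("abcdef"))
        part = cm.subject_consensus(C, ConsensusParams(gamma=1.0, runs=5, seed=0))
        assert part.module_count == 1
        # exhaustive check: one module maximizes Q on the uniform graph
        assert np.isclose(
            cm.weighted_modularity(v, part.labels, 1.0),
            exhaustive_max_modularity(v, 1.0),
            atol=1e-12,
        )

    def test_group_consensus_needs_two_subjects(self):
        with pytest.raises(ValueError, match="two subjects"):
            cm.group_consensus([Partition(np.zeros(4, dtype=int))], ConsensusParams())


class TestSweep:
    def _modular_matrix(self, seed):
        rng = np.random.default_rng(seed)
        truth = np.repeat(np.arange(3), 6)
        base = np.where(truth[:, None] == truth[None, :], 0.7, 0.05)
        w = base * rng.uniform(0.8, 1.2, (18, 18))
        w = np.triu(w, 1)
        w = w + w.T
        return w

    def test_single_point_grid_returns_that_point(self):
        mats = {"g1|1": self._modular_matrix(0)}
        res = cm.sweep_parameters(
            mats, gamma_range=[1.25], tau_range=[0.5],
            params=ConsensusParams(runs=5, seed=0),
        )
        assert (res.gamma, res.tau) == (1.25, 0.5)
        assert len(res.grid) == 1

    def test_default_grid_has_77_points(self):
        mats = {"g1|1": self._modular_matrix(1)}
        res = cm.sweep_parameters(mats, params=ConsensusParams(runs=3, seed=1))
        assert len(res.grid) == 77

    def test_reported_q_self_consistent_with_returned_partitions(self):
        mats = {"g1|1": self._modular_matrix(2), "g2|1": self._modular_matrix(3)}
        res = cm.sweep_parameters(
            mats, gamma_range=[1.0, 1.25], tau_range=[0.4, 0.5],
            params=ConsensusParams(runs=5, seed=2),
        )
        qs = [
            modularity_percommunity(mats[cell], res.partitions[cell].labels, res.gamma)
            for cell in mats
        ]
        assert np.isclose(res.mean_q, np.mean(qs), atol=1e-10)


class TestSmallGraphOptimality:
    def test_best_partition_matches_bell_enumeration_on_tiny_graphs(self):
        rng = np.random.default_rng(8)
        hits = 0
        for trial in range(20):
            n = int(rng.integers(5, 8))
            a = random_binary_graph(rng, n, 0.45)
            _, q = cm.best_partition(a, 1.0, runs=40, seed=trial)
            assert q <= exhaustive_max_modularity(a, 1.0) + 1e-12
            hits += np.isclose(q, exhaustive_max_modularity(a, 1.0), atol=1e-10)
        assert hits >= 19
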