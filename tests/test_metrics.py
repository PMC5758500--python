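"""Graph metrics against closed forms and brute-force oracles; the
consistent-node canonical assignment; module-level connectivity tables."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    global_efficiency_bfs,
    local_efficiency_bfs,
    modularity_pairsum,
    participation_counts,
)
from conftest import random_binary_graph, two_cliques
from restnet import metrics as mt
from restnet.community import Partition


class TestModularity:
    def test_single_module_is_zero(self, rng):
        a = random_binary_graph(rng, 10, 0.4)
        assert mt.modularity(a, np.zeros(10, dtype=int), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_half(self):
        a = two_cliques(3)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert mt.modularity(a, labels, 1.0) == pytest.approx(0.5)

    def test_matches_pairsum_oracle_with_gamma(self, rng):
        for _ in range(10):
            a = random_binary_graph(rng, 8, 0.45)
            labels = rng.integers(0, 3, 8)
            for gamma in (1.0, 1.25):
                assert mt.modularity(a, labels, gamma) == pytest.approx(
                    modularity_pairsum(a, labels, gamma), abs=1e-12
                )

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            mt.modularity(np.zeros((4, 4)), np.zeros(4, dtype=int))


class TestModularityScore:
    def test_two_cliques_score_is_half_for_any_runs(self):
        a = two_cliques(3)
        for runs in (1, 5):
            assert mt.modularity_score(a, gamma=1.0, runs=runs, seed=0) == pytest.approx(0.5)

    def test_single_run_equals_one_partition_q(self, rng):
        a = random_binary_graph(rng, 12, 0.35)
        s1 = mt.modularity_score(a, gamma=1.25, runs=1, seed=42)
        s2 = mt.modularity_score(a, gamma=1.25, runs=1, seed=42)
        assert s1 == s2

    def test_averaging_reduces_variance_across_seeds(self, rng):
        a = random_binary_graph(rng, 14, 0.3)
        single = [mt.modularity_score(a, 1.25, runs=1, seed=s) for s in range(30)]
        averaged = [mt.modularity_score(a, 1.25, runs=10, seed=s) for s in range(30)]
        assert np.var(averaged) <= np.var(single) + 1e-15


class TestEfficiency:
    def test_complete_graph_unit_efficiencies(self):
        a = np.ones((5, 5)) - np.eye(5)
        assert mt.global_efficiency(a) == pytest.approx(1.0)
        np.testing.assert_allclose(mt.local_efficiency(a), 1.0)

    def test_empty_graph_zero_efficiency(self):
        assert mt.global_efficiency(np.zeros((4, 4))) == 0.0

    def test_path_graph_closed_form(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
        assert mt.global_efficiency(a) == pytest.approx(5 / 6)

    def test_star_graph_local_efficiency_zero(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1.0
        np.testing.assert_allclose(mt.local_efficiency(a), 0.0)

    def test_matches_bfs_oracles_on_random_graphs(self, rng):
        for _ in range(10):
            a = random_binary_graph(rng, 12, 0.3)
            assert mt.global_efficiency(a) == pytest.approx(
                global_efficiency_bfs(a), abs=1e-12
            )
            np.testing.assert_allclose(
                mt.local_efficiency(a), local_efficiency_bfs(a), atol=1e-12
            )

    def test_global_efficiency_monotone_under_edge_addition(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = random_binary_graph(rng, 10, 0.25)
            b = a.copy()
            off = np.argwhere(np.triu(b == 0, 1))
            if off.size == 0:
                continue
            i, j = off[rng.integers(len(off))]
            b[i, j] = b[j, i] = 1.0
            assert mt.global_efficiency(b) >= mt.global_efficiency(a) - 1e-12


class TestParticipation:
    def test_provincial_node_is_zero(self):
        a = two_cliques(3)
        labels = np.array([0, 0, 0, 1, 1, 1])
        np.testing.assert_allclose(mt.participation(a, labels), 0.0)

    def test_symmetric_split_is_half(self):
        # degree-4 node with 2 edges into each of two modules
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1.0
        labels = np.array([0, 0, 0, 1, 1])
        assert mt.participation(a, labels)[0] == pytest.approx(0.5)

    def test_matches_count_oracle(self, rng):
        for _ in range(10):
            a = random_binary_graph(rng, 10, 0.4)
            labels = rng.integers(0, 3, 10)
            np.testing.assert_allclose(
                mt.participation(a, labels), participation_counts(a, labels), atol=1e-12
            )

    def test_unlabeled_connected_node_raises(self):
        a = two_cliques(3)
        labels = np.array([0, 0, 0, 1, 1, -1])
        with pytest.raises(ValueError, match="unlabeled"):
            mt.participation(a, labels)


class TestConsistentNodes:
    def _parts(self, *label_lists):
        return {
            f"cell{i}": Partition(np.array(lab)) for i, lab in enumerate(label_lists)
        }

    def test_identical_partitions_all_consistent(self):
        lab = [0, 0, 1, 1, 2, 2]
        out = mt.consistent_nodes(self._parts(lab, lab, lab, lab))
        assert out.consistent.all()

    def test_single_flip_marks_only_that_node(self):
        lab = [0, 0, 0, 1, 1, 1]
        flipped = [0, 0, 1, 1, 1, 1]
        out = mt.consistent_nodes(self._parts(lab, lab, flipped, lab))
        assert not out.consistent[2]
        assert out.consistent.sum() == 5

    def test_label_permutation_resolved_by_matching(self):
        lab = [0, 0, 1, 1, 2, 2]
        permuted = [2, 2, 0, 0, 1, 1]
        out = mt.consistent_nodes(self._parts(lab, permuted, permuted, lab))
        assert out.consistent.all()
        np.testing.assert_array_equal(out.labels, lab)

    def test_matching_agrees_with_hungarian_oracle(self, rng):
        from scipy.optimize import linear_sum_assignment

        ref = rng.integers(0, 4, 30)
        relabel = rng.permutation(4)
        other = relabel[ref]
        out = mt.consistent_nodes(
            {"a": Partition(ref), "b": Partition(other)}
        )
        confusion = np.zeros((4, 4))
        np.add.at(confusion, (Partition(other).labels, Partition(ref).labels), 1)
        rows, cols = linear_sum_assignment(-confusion)
        assert out.consistent.all()


class TestModuleConnectivity:
    def _assignment(self, labels):
        labels = np.array(labels)
        return mt.CanonicalAssignment(
            labels=labels,
            consistent=labels >= 0,
            matched_labels={"ref": labels},
            reference_cell="ref",
        )

    def test_uniform_weights_give_that_weight(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0.0)
        out = mt.module_connectivity(w, self._assignment([0, 0, 0, 0]))
        within = out[(out.kind == "within")]["value"].iloc[0]
        assert within == pytest.approx(0.3)

    def test_empty_graph_gives_zero(self):
        out = mt.module_connectivity(
            np.zeros((6, 6)), self._assignment([0, 0, 0, 1, 1, 1])
        )
        assert (out["value"] == 0).all()

    def test_matches_enumeration_oracle(self, rng):
        w = rng.standard_normal((8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        labels = [0, 0, 0, 1, 1, 2, 2, 2]
        out = mt.module_connectivity(w, self._assignment(labels))
        # within module 0 by hand
        s = w[0, 1] + w[0, 2] + w[1, 2]
        got = out[(out.module_a == 0) & (out.kind == "within")]["value"].iloc[0]
        assert got == pytest.approx(s / 3)
        # between modules 0 and 1 by hand
        s01 = sum(w[i, j] for i in (0, 1, 2) for j in (3, 4))
        got01 = out[(out.module_a == 0) & (out.module_b == 1)]["value"].iloc[0]
        assert got01 == pytest.approx(s01 / 6)

    def test_small_module_within_is_missing(self):
        out = mt.module_connectivity(
            np.zeros((3, 3)), self._assignment([0, 1, 1])
        )
        within0 = out[(out.module_a == 0) & (out.kind == "within")]["value"]
        assert within0.isna().all()


class TestMetricTables:
    def test_row_count_bookkeeping(self, small_cohort):
        from restnet.connectivity import correlation_matrix

        _, cohort = small_cohort
        conn = {
            k: correlation_matrix(v)
            for k, v in list(cohort.timeseries.items())[:4]
        }
        groups = dict(zip(cohort.manifest.subject_id, cohort.manifest.group))
        table, _, _ = mt.compute_metric_tables(
            conn, groups, thresholds=(0.05, 0.08), runs=3, seed=0
        )
        assert len(table) == 4 * (2 + 1)

    def test_single_threshold_mean_equals_row(self, small_cohort):
        from restnet.connectivity import correlation_matrix

        _, cohort = small_cohort
        conn = {("y01", 1): correlation_matrix(cohort.timeseries[("y01", 1)])}
        table, _, _ = mt.compute_metric_tables(
            conn, {"y01": "young"}, thresholds=(0.06,), runs=3, seed=1
        )
        single = table[table.density == 0.06].iloc[0]
        mean = table[table.density == "mean"].iloc[0]
        for col in ("Q", "Eglob", "Eloc_mean"):
            assert single[col] == pytest.approx(mean[col])


class TestMetricBounds:
    def test_q_below_one_and_efficiencies_in_unit_interval(self, rng):
        for _ in range(20):
            a = random_binary_graph(rng, 12, rng.uniform(0.15, 0.6))
            labels = rng.integers(0, 4, 12)
            assert mt.modularity(a, labels, 1.0) < 1.0
            assert 0.0 <= mt.global_efficiency(a) <= 1.0
            assert np.all((mt.local_efficiency(a) >= 0) & (mt.local_efficiency(a) <= 1))
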