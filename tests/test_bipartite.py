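"""Modularity closed forms, optimizer recovery, Rand index, permutation nulls."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, rand_score

from mips.bipartite import (
    BiclusterModel,
    BipartiteGraph,
    barber_modularity,
    rand_index,
    replication_test,
    rewire_preserving_degrees,
)
from mips.cohort import CohortSpec, generate_cohort

from conftest import all_set_partitions, partition_to_labels


def perfect_biclusters(k, n_per=3, d_per=2):
    A = np.zeros((k * n_per, k * d_per), dtype=int)
    for g in range(k):
        A[g * n_per : (g + 1) * n_per, g * d_per : (g + 1) * d_per] = 1
    graph = BipartiteGraph(
        [f"p{i}" for i in range(k * n_per)], [f"c{j}" for j in range(k * d_per)], A
    )
    gp = np.repeat(np.arange(1, k + 1), n_per)
    gc = np.repeat(np.arange(1, k + 1), d_per)
    return graph, gp, gc


class TestBarberModularity:
    def test_single_cluster_is_zero_on_any_graph(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A = (rng.random((6, 5)) < 0.5).astype(int)
            if A.sum() == 0:
                continue
            g = BipartiteGraph(list(range(6)), list("abcde"), A)
            q = barber_modularity(g, np.ones(6, int), np.ones(5, int))
            assert abs(q) < 1e-12

    def test_perfect_two_bicluster_toy(self):
        g = BipartiteGraph(["p1", "p2"], ["c1", "c2"], np.eye(2, dtype=int))
        assert barber_modularity(g, np.array([1, 2]), np.array([1, 2])) == pytest.approx(
            0.5, abs=1e-12
        )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_equal_perfect_biclusters_closed_form(self, k):
        graph, gp, gc = perfect_biclusters(k)
        assert barber_modularity(graph, gp, gc) == pytest.approx(1 - 1 / k, abs=1e-12)

    def test_matches_exhaustive_partition_oracle_on_small_graphs(self):
        """Q at every joint partition of <=9 nodes agrees with a direct
        double-sum oracle, and the optimizer attains the exhaustive max."""
        rng = np.random.default_rng(42)
        for trial in range(3):
            n, d = 4, 4
            A = (rng.random((n, d)) < 0.55).astype(int)
            A[A.sum(axis=1) == 0, rng.integers(0, d)] = 1
            g = BipartiteGraph(list(range(n)), [f"c{j}" for j in range(d)], A)
            k_i, d_j, m = g.patient_degrees, g.comorbidity_degrees, g.m

            def oracle_q(gp, gc):
                q = 0.0
                for i in range(n):
                    for j in range(d):
                        if gp[i] == gc[j]:
                            q += A[i, j] - k_i[i] * d_j[j] / m
                return q / m

            best = -np.inf
            for part in all_set_partitions(range(n + d)):
                labels = partition_to_labels(part, n + d)
                gp, gc = labels[:n], labels[n:]
                q_direct = oracle_q(gp, gc)
                assert barber_modularity(g, gp, gc) == pytest.approx(q_direct, abs=1e-12)
                best = max(best, q_direct)
            res = BiclusterModel(g).fit(restarts=30, seed=trial)
            assert res.q == pytest.approx(best, abs=1e-9)

    def test_q_within_unit_interval(self):
        rng = np.random.default_rng(3)
        A = (rng.random((8, 6)) < 0.4).astype(int)
        A[A.sum(axis=1) == 0, 0] = 1
        g = BipartiteGraph(list(range(8)), list(range(6)), A)
        for _ in range(20):
            gp = rng.integers(1, 4, size=8)
            gc = rng.integers(1, 4, size=6)
            assert -1.0 <= barber_modularity(g, gp, gc) <= 1.0


class TestMaximizeModularity:
    def test_noise_free_equal_blocks_hit_closed_form(self):
        # K=4 equal fully dense biclusters: optimum Q = 1 - 1/K = 0.75
        graph, gp, gc = perfect_biclusters(4, n_per=100, d_per=5)
        res = BiclusterModel(graph).fit(restarts=10, seed=1)
        assert res.q == pytest.approx(0.75, abs=1e-12)
        assert adjusted_rand_score(gc, res.partition.comorbidity_labels) == 1.0
        assert adjusted_rand_score(gp, res.partition.patient_labels) == 1.0

    def test_noise_free_planted_cohort_recovery(self):
        # generated cohort has random (unequal) subgroup sizes; recovery is
        # exact and the optimum can only exceed the planted labelling's Q
        spec = CohortSpec(
            n_cases=400,
            n_controls=50,
            n_comorbidities=20,
            n_subgroups=4,
            p_in=1.0,
            p_out=0.0,
            subgroup_risks=(0.2, 0.3, 0.4, 0.5),
            seed=9,
        )
        cases = generate_cohort(spec).cases()
        g = BipartiteGraph.from_cohort(cases)
        res = BiclusterModel(g).fit(restarts=10, seed=1)
        truth_c = np.array([spec.block_of(j) + 1 for j in range(20)])
        assert adjusted_rand_score(truth_c, res.partition.comorbidity_labels) == 1.0
        assert adjusted_rand_score(cases.true_subgroup, res.partition.patient_labels) == 1.0
        q_planted = barber_modularity(g, cases.true_subgroup, truth_c)
        assert res.q >= q_planted - 1e-12

    def test_optimizer_admissible_on_planted_graph(self):
        # never worse than the planted labelling itself
        spec = CohortSpec(n_cases=300, n_controls=50, seed=3)
        cases = generate_cohort(spec).cases()
        g = BipartiteGraph.from_cohort(cases)
        truth_p = cases.true_subgroup
        truth_c = np.array([spec.block_of(j) + 1 for j in range(spec.n_comorbidities)])
        q_planted = barber_modularity(g, truth_p, truth_c)
        res = BiclusterModel(g).fit(restarts=10, seed=0)
        assert res.q >= q_planted - 1e-12

    def test_complete_bipartite_has_no_structure(self):
        g = BipartiteGraph(list(range(12)), list(range(6)), np.ones((12, 6), dtype=int))
        res = BiclusterModel(g).fit(restarts=10, seed=0)
        assert res.q <= 0.05

    def test_deterministic_under_seed(self):
        spec = CohortSpec(n_cases=200, n_controls=50, seed=8)
        g = BipartiteGraph.from_cohort(generate_cohort(spec).cases())
        a = BiclusterModel(g).fit(restarts=5, seed=4)
        b = BiclusterModel(g).fit(restarts=5, seed=4)
        assert a.q == b.q
        assert np.array_equal(a.partition.patient_labels, b.partition.patient_labels)
        assert np.array_equal(a.partition.comorbidity_labels, b.partition.comorbidity_labels)


class TestRandIndex:
    def test_identical_partitions(self):
        assert rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_crossed_pairs_toy(self):
        # {12}{34} vs {13}{24}: only 2 of 6 pairs concordant
        assert rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(2 / 6)

    def test_all_singletons(self):
        assert rand_index(range(5), range(5)) == 1.0

    def test_symmetry_and_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for n in range(2, 9):
            for _ in range(10):
                a = rng.integers(0, 3, size=n)
                b = rng.integers(0, 3, size=n)
                agree = 0
                for i in range(n):
                    for j in range(i + 1, n):
                        agree += (a[i] == a[j]) == (b[i] == b[j])
                expected = agree / (n * (n - 1) / 2)
                assert rand_index(a, b) == pytest.approx(expected, abs=1e-12)
                assert rand_index(b, a) == pytest.approx(expected, abs=1e-12)
                assert rand_index(a, b) == pytest.approx(rand_score(a, b), abs=1e-12)

    def test_exhaustive_on_all_partitions_of_five(self):
        parts = [partition_to_labels(p, 5) for p in all_set_partitions(range(5))]
        for a in parts[::3]:
            for b in parts[::4]:
                agree = sum(
                    (a[i] == a[j]) == (b[i] == b[j])
                    for i in range(5)
                    for j in range(i + 1, 5)
                )
                assert rand_index(a, b) == pytest.approx(agree / 10, abs=1e-12)

    def test_rejects_tiny_or_mismatched(self):
        with pytest.raises(ValueError):
            rand_index([1], [1])
        with pytest.raises(ValueError):
            rand_index([1, 2], [1, 2, 3])


class TestPermutationNull:
    def test_rewire_preserves_both_degree_sequences(self):
        rng = np.random.default_rng(0)
        spec = CohortSpec(n_cases=150, n_controls=30, seed=2)
        g = BipartiteGraph.from_cohort(generate_cohort(spec).cases())
        g2 = rewire_preserving_degrees(g, rng)
        assert np.array_equal(g.patient_degrees, g2.patient_degrees)
        assert np.array_equal(g.comorbidity_degrees, g2.comorbidity_degrees)
        assert not np.array_equal(g.A, g2.A)  # something actually moved

    def test_significance_bookkeeping_and_floor(self):
        spec = CohortSpec(n_cases=120, n_controls=30, seed=6)
        g = BipartiteGraph.from_cohort(generate_cohort(spec).cases())
        res = BiclusterModel(g).fit(restarts=5, seed=0)
        sig = res.test_significance(n_perm=25, seed=1, restarts=2)
        assert len(sig.null_qs) == 25
        assert sig.p_empirical >= 1 / 26
        assert sig.z == pytest.approx((sig.q_obs - sig.null_mean) / sig.null_sd)

    def test_rejects_unstable_n_perm(self):
        spec = CohortSpec(n_cases=60, n_controls=20, seed=6)
        g = BipartiteGraph.from_cohort(generate_cohort(spec).cases())
        res = BiclusterModel(g).fit(restarts=2, seed=0)
        with pytest.raises(ValueError):
            res.test_significance(n_perm=5, seed=1)


class TestReplication:
    def test_identical_partitions_hit_p_floor(self):
        labels = np.array([1, 1, 2, 2, 3, 3, 1, 2, 3, 1])
        res = replication_test(labels, labels, n_perm=99, seed=0)
        assert res.ri == 1.0
        assert res.p_empirical == pytest.approx(1 / 100)

    def test_mismatched_comorbidity_sets_fail_loudly(self):
        with pytest.raises(ValueError):
            replication_test(
                [1, 2], [1, 2], comorbidity_ids_train=["a", "b"],
                comorbidity_ids_repl=["a", "c"], n_perm=30, seed=0,
            )

    def test_null_z_is_centred(self):
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(20):
            a = rng.integers(1, 4, size=24)
            b = rng.integers(1, 4, size=24)
            zs.append(replication_test(a, b, n_perm=200, seed=int(rng.integers(1e6))).z)
        inside = np.mean(np.abs(zs) <= 2)
        assert inside >= 0.9
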