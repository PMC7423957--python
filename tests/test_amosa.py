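import numpy as np
import pytest

from mvne import metrics
from mvne.amosa import (AmosaClustering, AnnealSchedule, Archive,
                        ClusterSolution, _dominates, anneal, assign_labels,
                        evaluate_centers, mutate, pbm_index, select_solution,
                        xb_index)


def oracle_xb(Y, centers, labels):
    """Double-loop Xie-Beni with crisp memberships, squared Euclidean."""
    n, K = Y.shape[0], centers.shape[0]
    num = 0.0
    for q in range(K):
        for r in range(n):
            if labels[r] == q:
                num += np.sum((Y[r] - centers[q]) ** 2)
    min_sep = min(np.sum((centers[l] - centers[m]) ** 2)
                  for l in range(K) for m in range(K) if l != m)
    return num / (n * min_sep)


def oracle_pbm(Y, centers, labels):
    """Double-loop PBM with Euclidean distances, as printed (no square)."""
    K = centers.shape[0]
    centroid = Y.mean(axis=0)
    e1 = sum(np.linalg.norm(y - centroid) for y in Y)
    ek = sum(np.linalg.norm(Y[r] - centers[labels[r]]) for r in range(len(Y)))
    dk = max(np.linalg.norm(centers[l] - centers[m])
             for l in range(K) for m in range(K)) if K > 1 else 0.0
    return (1.0 / K) * (e1 / ek) * dk


FOUR_POINTS = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
TWO_CENTERS = np.array([[0.0, 0.5], [10.0, 0.5]])


class TestValidityIndices:
    def test_xb_worked_example(self):
        # numerator 4 * 0.25 = 1; denominator 4 * 100; XB = 0.0025
        sol = ClusterSolution(centers=TWO_CENTERS,
                              labels=assign_labels(FOUR_POINTS, TWO_CENTERS))
        assert xb_index(FOUR_POINTS, sol) == pytest.approx(0.0025)

    def test_xb_decreases_with_tighter_clusters(self):
        wide = FOUR_POINTS.copy()
        tight = FOUR_POINTS.copy()
        tight[:, 1] = (tight[:, 1] - 0.5) * 0.1 + 0.5
        labels = assign_labels(FOUR_POINTS, TWO_CENTERS)
        sol = ClusterSolution(centers=TWO_CENTERS, labels=labels)
        assert xb_index(tight, sol) < xb_index(wide, sol)

    def test_xb_coincident_centers_sentinel(self):
        centers = np.zeros((2, 2))
        sol = ClusterSolution(centers=centers,
                              labels=np.array([0, 0, 1, 1]))
        assert xb_index(FOUR_POINTS, sol) == np.inf

    def test_pbm_single_cluster_zero(self):
        Y = FOUR_POINTS
        sol = ClusterSolution(centers=Y.mean(axis=0, keepdims=True),
                              labels=np.zeros(4, dtype=int))
        assert pbm_index(Y, sol) == 0.0

    def test_pbm_worked_example(self):
        labels = assign_labels(FOUR_POINTS, TWO_CENTERS)
        sol = ClusterSolution(centers=TWO_CENTERS, labels=labels)
        e1 = 4 * np.sqrt(5.0 ** 2 + 0.5 ** 2)
        expected = (1 / 2) * (e1 / 2.0) * 10.0
        assert pbm_index(FOUR_POINTS, sol) == pytest.approx(expected)

    @pytest.mark.parametrize("trial", range(50))
    def test_indices_match_bruteforce(self, trial):
        rng = np.random.default_rng(200 + trial)
        n = int(rng.integers(5, 11))
        K = int(rng.integers(2, 5))
        Y = rng.standard_normal((n, 3))
        centers = rng.standard_normal((K, 3))
        labels = assign_labels(Y, centers)
        if len(np.unique(labels)) < K:
            sol = evaluate_centers(Y, centers)   # repaired solution
            centers, labels = sol.centers, sol.labels
        sol = ClusterSolution(centers=centers, labels=labels)
        assert xb_index(Y, sol) == pytest.approx(
            oracle_xb(Y, centers, labels), abs=1e-12, rel=1e-12)
        assert pbm_index(Y, sol) == pytest.approx(
            oracle_pbm(Y, centers, labels), abs=1e-12, rel=1e-12)


class TestEvaluateAndMutate:
    def test_empty_cluster_repaired(self, rng):
        Y = rng.standard_normal((20, 2))
        centers = np.vstack([Y[:2], [100.0, 100.0]])  # third center empty
        sol = evaluate_centers(Y, centers)
        assert np.unique(sol.labels).size == 3
        assert np.isfinite(sol.xb) and np.isfinite(sol.pbm)

    def test_insert_keeps_old_centers(self, rng):
        Y = rng.standard_normal((30, 2))
        sol = evaluate_centers(Y, Y[:3])
        new = mutate(sol, Y, np.random.default_rng(0), kind="insert")
        assert new.n_clusters == 4
        np.testing.assert_array_equal(new.centers[:3], sol.centers)

    def test_delete_at_kmin_redrawn(self, rng):
        Y = rng.standard_normal((30, 2))
        sol = evaluate_centers(Y, Y[:2])
        for seed in range(10):
            new = mutate(sol, Y, np.random.default_rng(seed), kind="delete")
            assert new.n_clusters >= 2

    def test_insert_at_kmax_redrawn(self, rng):
        Y = rng.standard_normal((9, 2))  # k_max = 3
        sol = evaluate_centers(Y, Y[:3])
        for seed in range(10):
            new = mutate(sol, Y, np.random.default_rng(seed), kind="insert")
            assert new.n_clusters <= 3

    def test_normal_mutation_perturbs_one_center(self, rng):
        Y = rng.standard_normal((30, 2))
        sol = evaluate_centers(Y, Y[:3])
        new = mutate(sol, Y, np.random.default_rng(1), kind="normal")
        moved = [not np.allclose(new.centers[i], sol.centers[i])
                 for i in range(3)]
        assert sum(moved) == 1


class TestAnneal:
    def test_temperature_ladder_count(self):
        sched = AnnealSchedule(t_max=100, t_min=0.001, cooling=0.9)
        assert sched.n_levels == 110

    def test_archive_mutually_nondominated(self, rng):
        Y = rng.standard_normal((25, 2))
        arch = anneal(Y, AnnealSchedule(t_max=1.0, t_min=0.01,
                                        iters_per_temp=20, seed=2))
        sols = arch.solutions
        for a in sols:
            for b in sols:
                if a is not b:
                    assert not _dominates(a.objectives(), b.objectives())

    def test_recovers_four_separated_clusters(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        labels = rng.integers(0, 4, 80)
        Y = centers[labels] + rng.standard_normal((80, 2))
        arch = anneal(Y, AnnealSchedule(iters_per_temp=30, seed=3))
        sol = select_solution(arch, "best_pbm")
        assert sol.n_clusters == 4
        assert metrics.nmi(labels, sol.labels) >= 0.9

    def test_deterministic_given_seed(self, rng):
        Y = rng.standard_normal((20, 2))
        sched = AnnealSchedule(t_max=1.0, t_min=0.05, iters_per_temp=10, seed=9)
        a = anneal(Y, sched)
        b = anneal(Y, sched)
        assert len(a.solutions) == len(b.solutions)
        for s, t in zip(a.solutions, b.solutions):
            np.testing.assert_array_equal(s.centers, t.centers)

    def test_degenerate_data_warns(self):
        Y = np.zeros((10, 2))
        with pytest.warns(UserWarning):
            arch = anneal(Y, AnnealSchedule(t_max=1.0, t_min=0.5))
        assert arch.solutions


class TestSelectSolution:
    def _archive(self, Y):
        s1 = evaluate_centers(Y, Y[:2])
        s2 = evaluate_centers(Y, Y[:3])
        return Archive(solutions=[s1, s2])

    def test_single_solution_any_strategy(self, rng):
        Y = rng.standard_normal((10, 2))
        arch = Archive(solutions=[evaluate_centers(Y, Y[:2])])
        assert select_solution(arch, "best_pbm") is arch.solutions[0]
        assert select_solution(arch, "supervised_nmi",
                               labels=np.zeros(10)) is arch.solutions[0]

    def test_best_pbm_argmax(self, rng):
        Y = rng.standard_normal((12, 2))
        arch = self._archive(Y)
        best = max(arch.solutions, key=lambda s: s.pbm)
        assert select_solution(arch, "best_pbm") is best

    def test_supervised_nmi_picks_matching(self, rng):
        Y = rng.standard_normal((12, 2))
        arch = self._archive(Y)
        truth = arch.solutions[1].labels
        assert select_solution(arch, "supervised_nmi", labels=truth) \
            is arch.solutions[1]

    def test_empty_archive_error(self):
        with pytest.raises(ValueError):
            select_solution(Archive(solutions=[]))


def test_estimator_interface(rng):
    centers = np.array([[0, 0], [8, 8]], float)
    labels = rng.integers(0, 2, 40)
    Y = centers[labels] + rng.standard_normal((40, 2)) * 0.5
    est = AmosaClustering(t_max=1.0, t_min=0.01, iters_per_temp=20,
                          random_state=0)
    pred = est.fit_predict(Y)
    assert pred.shape == (40,)
    assert est.n_clusters_ == 2
    assert metrics.nmi(labels, pred) == pytest.approx(1.0)
    assert est.get_params()["cooling"] == 0.9
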