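"""Firefly optimizer contracts and firefly-driven cluster-count selection."""

import numpy as np
import pytest
from sklearn.metrics import davies_bouldin_score

from hsimap.firefly import (FireflyParams, ObjectiveSpec, firefly_optimize,
                            select_k)
from hsimap.phantom import PhantomSpec, generate_phantom
from hsimap.segment import KMeansParams, kmeans_segment


def sphere(x):
    return float(np.sum(x**2))


class TestOptimizer:
    def test_elitist_best_fitness_monotone(self):
        trace = firefly_optimize(
            ObjectiveSpec(sphere, "minimize"),
            FireflyParams(n_fireflies=10, max_generations=30,
                          bounds=((-5.0, 5.0), (-5.0, 5.0)), seed=3),
        )
        fits = np.array(trace.best_fitnesses)
        assert np.all(np.diff(fits) <= 0)

    def test_positions_stay_in_bounds(self):
        trace = firefly_optimize(
            ObjectiveSpec(sphere, "minimize"),
            FireflyParams(n_fireflies=8, max_generations=20, alpha=2.0,
                          bounds=((-1.0, 1.0), (0.0, 2.0)), seed=1),
            record_population=True,
        )
        for pop in trace.populations:
            assert np.all(pop[:, 0] >= -1.0) and np.all(pop[:, 0] <= 1.0)
            assert np.all(pop[:, 1] >= 0.0) and np.all(pop[:, 1] <= 2.0)

    def test_single_firefly_random_walk_monotone_elite(self):
        trace = firefly_optimize(
            ObjectiveSpec(sphere, "minimize"),
            FireflyParams(n_fireflies=1, max_generations=50,
                          bounds=((-5.0, 5.0),), seed=0),
        )
        fits = np.array(trace.best_fitnesses)
        assert np.all(np.diff(fits) <= 0)

    def test_sphere_minimum_found(self):
        """Swarm reaches the origin (< 1e-3) in at least 18 of 20 seeds."""
        wins = 0
        for seed in range(20):
            trace = firefly_optimize(
                ObjectiveSpec(sphere, "minimize"),
                FireflyParams(n_fireflies=25, max_generations=200,
                              bounds=((-5.0, 5.0), (-5.0, 5.0)), seed=seed),
            )
            wins += trace.best_fitness < 1e-3
        assert wins >= 18

    def test_frozen_swarm_when_gamma_infinite_and_alpha_zero(self):
        trace = firefly_optimize(
            ObjectiveSpec(sphere, "minimize"),
            FireflyParams(n_fireflies=6, max_generations=10, alpha=0.0,
                          gamma=1e12, bounds=((-5.0, 5.0), (-5.0, 5.0)),
                          seed=2),
            record_population=True,
        )
        first, last = trace.populations[0], trace.populations[-1]
        np.testing.assert_array_equal(first, last)

    def test_maximize_sense(self):
        trace = firefly_optimize(
            ObjectiveSpec(lambda x: -sphere(x), "maximize"),
            FireflyParams(n_fireflies=15, max_generations=50,
                          bounds=((-2.0, 2.0),), seed=5),
        )
        assert trace.best_fitness > -1e-2
        fits = np.array(trace.best_fitnesses)
        assert np.all(np.diff(fits) >= 0)  # non-worsening when maximizing

    def test_nan_fitness_raises_with_position(self):
        def bad(x):
            return float("nan") if x[0] > 0 else sphere(x)
        with pytest.raises(ValueError, match="non-finite"):
            firefly_optimize(
                ObjectiveSpec(bad, "minimize"),
                FireflyParams(n_fireflies=10, max_generations=5,
                              bounds=((-1.0, 1.0),), seed=0),
            )

    def test_deterministic_given_seed(self):
        params = FireflyParams(n_fireflies=10, max_generations=20,
                               bounds=((-3.0, 3.0), (-3.0, 3.0)), seed=9)
        a = firefly_optimize(ObjectiveSpec(sphere, "minimize"), params)
        b = firefly_optimize(ObjectiveSpec(sphere, "minimize"), params)
        assert a.best_fitnesses == b.best_fitnesses
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FireflyParams(n_fireflies=0).validate()
        with pytest.raises(ValueError):
            FireflyParams(bounds=((1.0, 0.0),)).validate()


class TestSelectK:
    def _phantom_features(self, seed, n_classes=3):
        p = generate_phantom(PhantomSpec(64, 64, 16, n_classes=n_classes,
                                         speckle_looks=4.0, seed=seed))
        return p.noisy_cube.reshape(-1, 16)

    def test_recovers_three_classes(self):
        """Three separated tissue classes -> k=3 in >= 90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            feats = self._phantom_features(seed)
            k, _, _ = select_k(feats, 2, 5,
                               FireflyParams(n_fireflies=15,
                                             max_generations=10, seed=seed))
            hits += k == 3
        assert hits >= 18

    def test_agrees_with_exhaustive_enumeration(self):
        """The metaheuristic answer equals the brute-force validity argmin."""
        for seed in range(5):
            feats = self._phantom_features(seed)
            k, _, cache = select_k(feats, 2, 5,
                                   FireflyParams(n_fireflies=15,
                                                 max_generations=10,
                                                 seed=seed))
            # independent enumeration over every integer candidate
            scores = {}
            for kk in range(2, 6):
                seg = kmeans_segment(
                    feats, KMeansParams(k=kk, seed=seed, n_restarts=2,
                                 min_cluster_frac=0.0))
                scores[kk] = davies_bouldin_score(feats, seg.labels)
            assert k == min(scores, key=lambda kk: (scores[kk], kk))

    def test_merged_blobs_select_boundary_k(self, rng):
        """One true cluster duplicated -> lowest allowed k=2 wins."""
        X = np.vstack([rng.normal(0, 0.2, size=(60, 2)),
                       rng.normal(0, 0.2, size=(60, 2))])
        k, _, cache = select_k(X, 2, 5,
                               FireflyParams(n_fireflies=15,
                                             max_generations=10, seed=0))
        assert k == min(cache, key=lambda kk: (cache[kk], kk))
        # exhaustive oracle over the validity index
        scores = {}
        for kk in range(2, 6):
            seg = kmeans_segment(X, KMeansParams(k=kk, seed=0, n_restarts=2,
                                          min_cluster_frac=0.0))
            scores[kk] = davies_bouldin_score(X, seg.labels)
        assert k == min(scores, key=lambda kk: (scores[kk], kk))

    def test_memoization_covers_every_candidate_once(self):
        feats = self._phantom_features(0)
        calls = []

        def counting_fitness(X, labels):
            k = len(np.unique(labels))
            calls.append(k)
            return davies_bouldin_score(X, labels)

        k, _, cache = select_k(feats, 2, 5,
                               FireflyParams(n_fireflies=15,
                                             max_generations=5, seed=0),
                               fitness=counting_fitness)
        assert sorted(cache) == [2, 3, 4, 5]
        assert len(calls) == len(set(calls))  # each integer scored once

    def test_too_few_distinct_points_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="distinct"):
            select_k(X, 2, 5)

    def test_kmin_below_two_rejected(self, blob_features):
        with pytest.raises(ValueError, match="kmin"):
            select_k(blob_features[0], 1, 5)
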