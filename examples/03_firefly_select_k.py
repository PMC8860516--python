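"""Select the cluster count with the firefly metaheuristic.

The swarm searches the box [2, 5]; each candidate position is rounded to an
integer k and scored by the Davies-Bouldin index of a seeded k-means run
(lower = better-separated clusters). Scores are memoized per integer.
"""

from hsimap import (PhantomSpec, generate_phantom, FireflyParams, select_k,
                    firefly_optimize, ObjectiveSpec)
import numpy as np

phantom = generate_phantom(
    PhantomSpec(height=64, width=64, n_bands=16, n_classes=3,
                speckle_looks=4.0, seed=0))
features = phantom.noisy_cube.reshape(-1, 16)

k, trace, cache = select_k(features, kmin=2, kmax=5,
                           ffp=FireflyParams(n_fireflies=15,
                                             max_generations=10, seed=0))
print(f"validity score per k : "
      f"{ {kk: round(v, 3) for kk, v in sorted(cache.items())} }")
print(f"selected k           : {k}  (true class count is 3)")

# The same optimizer is a generic bounded minimizer:
sphere = ObjectiveSpec(lambda x: float(np.sum(x**2)), "minimize", "sphere")
t = firefly_optimize(sphere, FireflyParams(n_fireflies=25,
                                           max_generations=200,
                                           bounds=((-5.0, 5.0), (-5.0, 5.0)),
                                           seed=0))
print(f"sphere best fitness  : {t.best_fitness:.2e}  (global optimum is 0)")
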