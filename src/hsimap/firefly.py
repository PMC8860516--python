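"""Firefly algorithm: bounded continuous metaheuristic, plus cluster-count
selection for k-means.

Each firefly holds a candidate position; dimmer fireflies move toward
brighter ones with attractiveness decaying as ``beta0 * exp(-gamma r^2)``
over Euclidean distance ``r``, plus a random step ``alpha * eps`` with
``eps`` uniform on [-0.5, 0.5] per dimension. Positions are clamped to the
bounding box after every move, and an elitist record of the best solution
seen so far is kept so the reported best-fitness trace never worsens.

For cluster-count selection the swarm searches a 1-D box (default [2, 5]);
positions are rounded to integers at evaluation time and the fitness — the
Davies-Bouldin index of a seeded k-means run at that k — is memoized per
integer, so the metaheuristic never pays for re-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import davies_bouldin_score

__all__ = ["FireflyParams", "ObjectiveSpec", "SwarmTrace", "firefly_optimize",
           "select_k"]


@dataclass
class FireflyParams:
    n_fireflies: int = 25
    max_generations: int = 100
    alpha: float = 0.2
    alpha_decay: float = 0.97
    beta0: float = 1.0
    gamma: float = 1.0
    bounds: tuple = ((-5.0, 5.0),)
    seed: int = 0

    def validate(self) -> None:
        if self.n_fireflies < 1:
            raise ValueError(f"n_fireflies must be >= 1; got {self.n_fireflies}")
        if self.max_generations < 1:
            raise ValueError(f"max_generations must be >= 1; got {self.max_generations}")
        for v, name in ((self.alpha, "alpha"), (self.beta0, "beta0"),
                        (self.gamma, "gamma")):
            if v < 0:
                raise ValueError(f"{name} must be >= 0; got {v}")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"bounds must satisfy lower < upper; got ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=float)


@dataclass
class ObjectiveSpec:
    """Scalar objective over the bounded box; ``sense`` picks the direction."""

    fn: Callable[[np.ndarray], float]
    sense: str = "minimize"
    name: str = "objective"

    def validate(self) -> None:
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"sense must be minimize|maximize; got {self.sense!r}")


@dataclass
class SwarmTrace:
    """Per-generation elitist record plus (optionally) population snapshots."""

    best_positions: list = field(default_factory=list)
    best_fitnesses: list = field(default_factory=list)
    populations: list | None = None

    @property
    def best_position(self) -> np.ndarray:
        return self.best_positions[-1]

    @property
    def best_fitness(self) -> float:
        return self.best_fitnesses[-1]


def _evaluate(obj: ObjectiveSpec, x: np.ndarray) -> float:
    val = float(obj.fn(np.asarray(x, dtype=float)))
    if not np.isfinite(val):
        raise ValueError(f"objective {obj.name!r} returned non-finite fitness "
                         f"{val} at position {np.asarray(x).tolist()}")
    return val


def firefly_optimize(obj: ObjectiveSpec, params: FireflyParams,
                     record_population: bool = False,
                     initial_positions: np.ndarray | None = None) -> SwarmTrace:
    """Run the firefly double loop and return the full elitist trace.

    Deterministic given ``params.seed``. ``initial_positions`` overrides the
    uniform-random initial swarm (it is clamped to the box).
    """
    params.validate()
    obj.validate()
    sign = 1.0 if obj.sense == "minimize" else -1.0
    rng = np.random.default_rng(params.seed)
    lo, hi = params.lower, params.upper
    dim = lo.size

    if initial_positions is not None:
        pos = np.clip(np.asarray(initial_positions, dtype=float), lo, hi)
        if pos.shape != (params.n_fireflies, dim):
            raise ValueError(
                f"initial_positions must be ({params.n_fireflies}, {dim}); "
                f"got {pos.shape}"
            )
        pos = pos.copy()
    else:
        pos = rng.uniform(lo, hi, size=(params.n_fireflies, dim))
    # Internal cost is sign-adjusted so lower is always brighter.
    cost = np.array([sign * _evaluate(obj, p) for p in pos])

    best_idx = int(np.argmin(cost))
    elite_pos, elite_cost = pos[best_idx].copy(), float(cost[best_idx])

    trace = SwarmTrace(populations=[] if record_population else None)
    alpha = params.alpha
    for _ in range(params.max_generations):
        for i in range(params.n_fireflies):
            for j in range(params.n_fireflies):
                if cost[j] < cost[i]:  # j is brighter: move i toward j
                    r2 = float(np.sum((pos[i] - pos[j]) ** 2))
                    beta = params.beta0 * np.exp(-params.gamma * r2)
                    eps = rng.uniform(-0.5, 0.5, size=dim)
                    pos[i] = pos[i] + beta * (pos[j] - pos[i]) + alpha * eps
                    pos[i] = np.clip(pos[i], lo, hi)
                    cost[i] = sign * _evaluate(obj, pos[i])
                    if cost[i] < elite_cost:
                        elite_cost, elite_pos = float(cost[i]), pos[i].copy()
        # Lone firefly: Table-style random walk keeps the search alive.
        if params.n_fireflies == 1:
            eps = rng.uniform(-0.5, 0.5, size=dim)
            pos[0] = np.clip(pos[0] + alpha * eps, lo, hi)
            cost[0] = sign * _evaluate(obj, pos[0])
            if cost[0] < elite_cost:
                elite_cost, elite_pos = float(cost[0]), pos[0].copy()
        alpha *= params.alpha_decay
        trace.best_positions.append(elite_pos.copy())
        trace.best_fitnesses.append(sign * elite_cost)
        if record_population:
            trace.populations.append(pos.copy())
    return trace


# ---------------------------------------------------------------------------
# Cluster-count selection


def select_k(features: np.ndarray, kmin: int = 2, kmax: int = 5,
             ffp: FireflyParams | None = None,
             fitness: Callable[[np.ndarray, np.ndarray], float] | None = None,
             kmeans_seed: int | None = None, n_restarts: int = 2
             ) -> tuple[int, SwarmTrace, dict]:
    """Pick the k-means cluster count via a 1-D firefly search.

    Fitness of a position x is the cluster-validity score (default
    Davies-Bouldin, lower better) of a seeded k-means run at k = round(x);
    scores are memoized per integer k. Returns ``(selected_k, trace, cache)``
    where ``cache`` maps each evaluated integer k to its score — so the
    selection can be audited against exhaustive enumeration.

    The initial swarm is stratified across the box (evenly spaced plus
    seeded jitter), which guarantees every integer candidate is scored when
    the swarm is at least as large as the candidate count.
    """
    from .segment import KMeansParams, kmeans_segment  # local: avoid cycle

    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError(f"features must be 2-D (n_pixels, n_features); "
                         f"got {features.shape}")
    if kmin < 2:
        raise ValueError(f"kmin must be >= 2 (validity indices are undefined "
                         f"for a single cluster); got {kmin}")
    if kmax < kmin:
        raise ValueError(f"kmax must be >= kmin; got kmin={kmin}, kmax={kmax}")
    n_distinct = np.unique(features, axis=0).shape[0]
    if n_distinct < kmin:
        raise ValueError(f"only {n_distinct} distinct feature vectors; "
                         f"cannot search k >= {kmin}")
    kmax = min(kmax, n_distinct)

    ffp = ffp or FireflyParams(n_fireflies=15, max_generations=20, seed=0)
    ffp = FireflyParams(**{**ffp.__dict__, "bounds": ((float(kmin), float(kmax)),)})
    km_seed = ffp.seed if kmeans_seed is None else kmeans_seed

    cache: dict[int, float] = {}

    def score_k(k: int) -> float:
        if k not in cache:
            # min_cluster_frac=0: score the raw k-way partition, so the
            # validity index always sees exactly k clusters.
            seg = kmeans_segment(
                features,
                KMeansParams(k=k, seed=km_seed, n_restarts=n_restarts,
                             min_cluster_frac=0.0),
            )
            if fitness is not None:
                cache[k] = float(fitness(features, seg.labels))
            else:
                cache[k] = float(davies_bouldin_score(features, seg.labels))
        return cache[k]

    def objective(x: np.ndarray) -> float:
        k = int(np.clip(round(float(x[0])), kmin, kmax))
        return score_k(k)

    rng = np.random.default_rng(ffp.seed)
    base = np.linspace(kmin, kmax, ffp.n_fireflies)
    jitter = rng.uniform(-0.5, 0.5, size=ffp.n_fireflies) * (kmax - kmin) / max(
        ffp.n_fireflies - 1, 1)
    init = np.clip(base + jitter, kmin, kmax)[:, None]

    trace = firefly_optimize(
        ObjectiveSpec(objective, sense="minimize", name="davies-bouldin"),
        ffp, initial_positions=init,
    )
    selected = min(cache, key=lambda k: (cache[k], k))
    return selected, trace, dict(cache)
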