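"""k-means segmentation of pixel spectra and KNN label refinement.

The k-means here is a plain Lloyd iteration with the stopping rule used
throughout the pipeline: stop when the largest centroid displacement drops
below ``min_error`` (default 1e-3) or after ``max_iter`` iterations
(default 50). Ties in the nearest-centroid assignment go to the lowest
centroid index; a cluster that empties is reseeded to the point farthest
from its former centroid; the best of ``n_restarts`` restarts (by final
inertia) is returned.

KNN refinement is a single-pass majority vote over each pixel's k nearest
neighbors, either in feature (spectral) space or over the spatial grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .cube import RGBImage

__all__ = ["KMeansParams", "SegmentationResult", "kmeans_segment",
           "knn_refine", "map_regions", "DEFAULT_PALETTE"]

#: Distinct label colors (RGB in [0,1]) for up to 8 regions.
DEFAULT_PALETTE = np.array([
    [0.894, 0.102, 0.110],
    [0.216, 0.494, 0.722],
    [0.302, 0.686, 0.290],
    [0.596, 0.306, 0.639],
    [1.000, 0.498, 0.000],
    [1.000, 1.000, 0.200],
    [0.651, 0.337, 0.157],
    [0.969, 0.506, 0.749],
])


@dataclass
class KMeansParams:
    k: int = 3
    max_iter: int = 50
    min_error: float = 1e-3
    init: str = "kmeans++"
    seed: int = 0
    n_restarts: int = 5
    min_cluster_frac: float = 0.005  # clusters below this share are merged

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1; got {self.k}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1; got {self.max_iter}")
        if not self.min_error > 0:
            raise ValueError(f"min_error must be > 0; got {self.min_error}")
        if self.init not in ("kmeans++", "random"):
            raise ValueError(f"init must be kmeans++|random; got {self.init!r}")
        if self.n_restarts < 1:
            raise ValueError(f"n_restarts must be >= 1; got {self.n_restarts}")


@dataclass
class SegmentationResult:
    labels: np.ndarray           # flat (n_pixels,) or (H, W) after reshape
    centroids: np.ndarray        # (k, F)
    inertia_trace: list          # within-cluster SSE per Lloyd iteration
    selected_k: int
    refined: bool = False

    @property
    def inertia(self) -> float:
        return self.inertia_trace[-1]

    def as_map(self, height: int, width: int) -> np.ndarray:
        return np.asarray(self.labels).reshape(height, width)


# ---------------------------------------------------------------------------


def _init_centroids(X: np.ndarray, k: int, method: str,
                    rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    if method == "random":
        idx = rng.choice(n, size=k, replace=False)
        return X[idx].copy()
    # kmeans++: D^2-weighted seeding
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total == 0:
            centroids[i] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centroids[i] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centroids[i]) ** 2, axis=1))
    return centroids


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels (ties -> lowest index) and squared distances."""
    d2 = cdist(X, centroids, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index
    return labels, d2


def _lloyd(X: np.ndarray, centroids: np.ndarray, p: KMeansParams
           ) -> tuple[np.ndarray, np.ndarray, list]:
    inertia_trace: list[float] = []
    labels, d2 = _assign(X, centroids)
    for _ in range(p.max_iter):
        inertia_trace.append(float(d2[np.arange(X.shape[0]), labels].sum()))
        new_centroids = centroids.copy()
        for c in range(p.k):
            members = labels == c
            if members.any():
                new_centroids[c] = X[members].mean(axis=0)
            else:
                # Reseed an empty cluster to the point farthest from it.
                far = int(np.argmax(np.sum((X - centroids[c]) ** 2, axis=1)))
                new_centroids[c] = X[far]
        shift = float(np.max(np.linalg.norm(new_centroids - centroids, axis=1)))
        centroids = new_centroids
        labels, d2 = _assign(X, centroids)
        if shift < p.min_error:
            break
    inertia_trace.append(float(d2[np.arange(X.shape[0]), labels].sum()))
    return labels, centroids, inertia_trace


def _merge_small_clusters(X, labels, centroids, frac):
    """Merge clusters below ``frac`` of pixels into the nearest centroid."""
    n = X.shape[0]
    counts = np.bincount(labels, minlength=centroids.shape[0])
    small = np.flatnonzero((counts > 0) & (counts < frac * n))
    if small.size == 0 or (counts > 0).sum() <= 1:
        return labels, centroids
    keep = np.flatnonzero(~np.isin(np.arange(centroids.shape[0]), small))
    for c in small:
        members = labels == c
        d2 = cdist(X[members], centroids[keep], metric="sqeuclidean")
        labels[members] = keep[np.argmin(d2, axis=1)]
    return labels, centroids


def kmeans_segment(features: np.ndarray, p: KMeansParams | None = None,
                   initial_centroids: np.ndarray | None = None
                   ) -> SegmentationResult:
    """Cluster pixel feature vectors; returns labels, centroids, inertia trace.

    Requires at least ``k`` distinct feature vectors. Deterministic given
    ``p.seed``; restart r uses seed ``p.seed + r`` and the restart with the
    lowest final inertia wins (tie -> lowest restart index). Passing
    ``initial_centroids`` pins the starting point (single run, no restarts).
    """
    p = p or KMeansParams()
    p.validate()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"features must be 2-D (n_pixels, n_features); got {X.shape}")
    n_distinct = np.unique(X, axis=0).shape[0]
    if p.k > n_distinct:
        raise ValueError(
            f"k={p.k} exceeds the {n_distinct} distinct feature vectors"
        )

    if p.k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        d2 = np.sum((X - centroid) ** 2, axis=1)
        return SegmentationResult(
            labels=np.zeros(X.shape[0], dtype=np.int64), centroids=centroid,
            inertia_trace=[float(d2.sum())], selected_k=1,
        )

    if initial_centroids is not None:
        c0 = np.asarray(initial_centroids, dtype=float)
        if c0.shape != (p.k, X.shape[1]):
            raise ValueError(
                f"initial_centroids must be ({p.k}, {X.shape[1]}); got {c0.shape}"
            )
        labels, centroids, trace = _lloyd(X, c0.copy(), p)
        if p.min_cluster_frac > 0:
            labels, centroids = _merge_small_clusters(
                X, labels.copy(), centroids, p.min_cluster_frac
            )
        return SegmentationResult(
            labels=labels.astype(np.int64), centroids=centroids,
            inertia_trace=trace, selected_k=p.k,
        )

    best = None
    for r in range(p.n_restarts):
        rng = np.random.default_rng(p.seed + r)
        centroids0 = _init_centroids(X, p.k, p.init, rng)
        labels, centroids, trace = _lloyd(X, centroids0, p)
        if best is None or trace[-1] < best[2][-1]:
            best = (labels, centroids, trace)
    labels, centroids, trace = best

    if p.min_cluster_frac > 0:
        labels, centroids = _merge_small_clusters(
            X, labels.copy(), centroids, p.min_cluster_frac
        )
    return SegmentationResult(
        labels=labels.astype(np.int64), centroids=centroids,
        inertia_trace=trace, selected_k=p.k,
    )


# ---------------------------------------------------------------------------
# KNN refinement


def _majority_or_keep(neigh_labels: np.ndarray, original: int, k: int) -> int:
    counts = np.bincount(neigh_labels, minlength=k)
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    if winners.size > 1:
        return original  # tie: keep the original label
    return int(winners[0])


def knn_refine(seg: SegmentationResult, features: np.ndarray,
               k_nn: int = 9, mode: str = "spatial",
               shape: tuple[int, int] | None = None) -> SegmentationResult:
    """Single-pass majority-vote relabeling over k nearest neighbors.

    ``mode='spectral'`` votes over the ``k_nn`` nearest pixels in feature
    space (including the pixel itself); ``mode='spatial'`` votes over the
    ``k_nn`` spatially nearest grid pixels (``shape`` required). Ties keep
    the original label. Never invents labels outside ``[0, k)``.
    """
    labels = np.asarray(seg.labels).ravel()
    n = labels.size
    if k_nn % 2 == 0:
        raise ValueError(f"k_nn must be odd; got {k_nn}")
    if k_nn >= n:
        raise ValueError(f"k_nn={k_nn} must be smaller than pixel count {n}")
    k = seg.centroids.shape[0]

    if mode == "spectral":
        X = np.asarray(features, dtype=float)
        nn = NearestNeighbors(n_neighbors=k_nn).fit(X)
        idx = nn.kneighbors(X, return_distance=False)
        new = np.array([
            _majority_or_keep(labels[idx[i]], labels[i], k) for i in range(n)
        ])
    elif mode == "spatial":
        if shape is None:
            raise ValueError("spatial mode requires the (height, width) shape")
        H, W = shape
        if H * W != n:
            raise ValueError(f"shape {shape} does not match {n} pixels")
        lab2d = labels.reshape(H, W)
        yy, xx = np.mgrid[0:H, 0:W]
        coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        nn = NearestNeighbors(n_neighbors=k_nn).fit(coords)
        idx = nn.kneighbors(coords, return_distance=False)
        new = np.array([
            _majority_or_keep(labels[idx[i]], labels[i], k) for i in range(n)
        ])
    else:
        raise ValueError(f"mode must be spectral|spatial; got {mode!r}")

    return SegmentationResult(
        labels=new.astype(np.int64), centroids=seg.centroids,
        inertia_trace=list(seg.inertia_trace), selected_k=seg.selected_k,
        refined=True,
    )


def map_regions(seg: SegmentationResult, shape: tuple[int, int],
                palette: np.ndarray | None = None) -> RGBImage:
    """Render a label map to colors; deterministic given the palette."""
    palette = DEFAULT_PALETTE if palette is None else np.asarray(palette, dtype=float)
    lab = seg.as_map(*shape)
    k = int(lab.max()) + 1
    if palette.shape[0] < k:
        raise ValueError(
            f"palette has {palette.shape[0]} colors but {k} labels are present"
        )
    return RGBImage(palette[lab], provenance="label palette rendering")
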