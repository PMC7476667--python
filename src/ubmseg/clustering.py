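"""Baseline intensity-clustering segmenters: hard K-means and fuzzy C-means.

Both cluster pixel intensities alone (a 1-D feature), minimising

    K-means:  E = sum_j sum_{i in cluster j} |I(x_i) - c_j|^2
    FCM:      E = sum_j sum_i u_ij^m |I(x_i) - c_j|^2,   sum_j u_ij = 1

by Lloyd-style alternation / alternating membership-centroid updates.  They
are the reference points against which the bias-field-aware level-set
segmenter is compared: on images with pronounced intensity inhomogeneity
pure intensity clustering mixes tissue classes, which is exactly the failure
mode these baselines are meant to exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "ClusteringConfig",
    "LabelMask",
    "FuzzyResult",
    "kmeans_segment",
    "fcm_segment",
    "harden_memberships",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Shared configuration for the clustering segmenters.

    ``init`` selects centroid initialisation: ``"quantile"`` places the K
    centroids at evenly spaced intensity quantiles (deterministic),
    ``"random"`` samples K distinct pixel intensities with ``seed``, and
    ``"exhaustive"`` (K-means only, small inputs) tries every contiguous
    split of the sorted intensities — for 1-D data the globally optimal
    clusters are contiguous in sorted order, so this attains the global
    minimum.
    """

    n_clusters: int = 3
    fuzzifier: float = 2.0
    max_iter: int = 100
    tol: float = 1e-6
    init: str = "quantile"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.fuzzifier <= 1.0:
            raise ValueError(f"fuzzifier must be > 1, got {self.fuzzifier}")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.init not in ("quantile", "random", "exhaustive"):
            raise ValueError(f"unknown init strategy {self.init!r}")


@dataclass(frozen=True)
class LabelMask:
    """Hard partition of the image domain with its clustering diagnostics."""

    labels: np.ndarray          # (H, W) int in 0..K-1
    centroids: np.ndarray       # (K,) intensity per cluster, ascending
    objective: float
    trace: tuple[float, ...] = field(default_factory=tuple)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class FuzzyResult:
    """Soft partition: per-pixel membership vectors plus centroids."""

    memberships: np.ndarray     # (H, W, K), rows sum to 1
    centroids: np.ndarray       # (K,), ascending
    objective: float
    trace: tuple[float, ...] = field(default_factory=tuple)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    return image


def _init_centroids(values: np.ndarray, config: ClusteringConfig) -> np.ndarray:
    k = config.n_clusters
    if config.init == "quantile":
        q = (2 * np.arange(k) + 1) / (2 * k)
        return np.quantile(values, q)
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        uniq = np.unique(values)
        if len(uniq) < k:
            raise ValueError(
                f"cannot place {k} distinct centroids on {len(uniq)} distinct intensities"
            )
        return np.sort(rng.choice(uniq, size=k, replace=False))
    raise ValueError(f"init strategy {config.init!r} not valid here")


def _lloyd(values: np.ndarray, centroids: np.ndarray, config: ClusteringConfig):
    """Lloyd alternation on 1-D intensities; returns (labels, centroids, trace)."""
    trace: list[float] = []
    labels = None
    for _ in range(config.max_iter):
        d2 = (values[:, None] - centroids[None, :]) ** 2
        labels = np.argmin(d2, axis=1)  # ties -> lower index
        # Empty-cluster handling: re-seed to the intensity farthest from its
        # assigned centroid, then re-assign.
        for j in range(len(centroids)):
            if not (labels == j).any():
                worst = int(np.argmax(d2[np.arange(len(values)), labels]))
                centroids = centroids.copy()
                centroids[j] = values[worst]
                d2 = (values[:, None] - centroids[None, :]) ** 2
                labels = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(len(values)), labels].sum())
        trace.append(obj)
        new_centroids = centroids.copy()
        for j in range(len(centroids)):
            members = values[labels == j]
            if members.size:
                new_centroids[j] = members.mean()
        if np.array_equal(new_centroids, centroids):
            break
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) <= config.tol * max(
            abs(trace[-2]), 1.0
        ):
            centroids = new_centroids
            break
        centroids = new_centroids
    # Final assignment against the final centroids.
    d2 = (values[:, None] - centroids[None, :]) ** 2
    labels = np.argmin(d2, axis=1)
    obj = float(d2[np.arange(len(values)), labels].sum())
    if not trace or obj < trace[-1]:
        trace.append(obj)
    return labels, centroids, trace


def _sort_clusters(labels: np.ndarray, centroids: np.ndarray):
    order = np.argsort(centroids, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return remap[labels], centroids[order]


def kmeans_segment(image: np.ndarray, config: ClusteringConfig | None = None) -> LabelMask:
    """Segment an image by K-means clustering of its pixel intensities.

    Returns a :class:`LabelMask` whose objective is a local minimum of the
    within-cluster sum of squares (the global minimum under
    ``init="exhaustive"``).  Clusters are relabelled so centroids ascend;
    label 0 is always the darkest cluster.
    """
    config = config or ClusteringConfig()
    image = _check_image(image)
    values = image.ravel()
    k = config.n_clusters
    uniq = np.unique(values)
    if k > len(uniq):
        raise ValueError(
            f"K={k} exceeds the number of distinct intensities ({len(uniq)})"
        )

    if config.init == "exhaustive":
        labels, centroids, trace = _exhaustive_kmeans(values, config)
    else:
        centroids = _init_centroids(values, config)
        labels, centroids, trace = _lloyd(values, centroids, config)

    labels, centroids = _sort_clusters(labels, centroids)
    return LabelMask(
        labels=labels.reshape(image.shape),
        centroids=centroids,
        objective=trace[-1],
        trace=tuple(trace),
    )


def _exhaustive_kmeans(values: np.ndarray, config: ClusteringConfig):
    """Global 1-D K-means: Lloyd polishing from every contiguous sorted split."""
    k = config.n_clusters
    n = len(values)
    if n > 4096:
        raise ValueError("exhaustive init is intended for small images")
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    best = None
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        centroids = np.array(
            [sorted_vals[bounds[j] : bounds[j + 1]].mean() for j in range(k)]
        )
        if len(np.unique(centroids)) < k:
            continue
        labels, cents, trace = _lloyd(values, centroids, config)
        if best is None or trace[-1] < best[2][-1]:
            best = (labels, cents, trace)
    if best is None:
        raise ValueError("no valid contiguous split found")
    return best


def fcm_segment(image: np.ndarray, config: ClusteringConfig | None = None) -> FuzzyResult:
    """Segment an image by fuzzy C-means clustering of pixel intensities.

    Alternates the closed-form membership update

        u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1))

    with the weighted-mean centroid update until the objective changes by
    less than ``tol`` (relative) or ``max_iter`` is reached.  A pixel that
    coincides exactly with one or more centroids receives membership 1 on
    the first coincident centroid and 0 elsewhere.
    """
    config = config or ClusteringConfig()
    image = _check_image(image)
    values = image.ravel()
    k = config.n_clusters
    m = config.fuzzifier

    if config.init == "exhaustive":
        raise ValueError("exhaustive init applies to kmeans_segment only")
    centroids = _init_centroids(values, config)

    trace: list[float] = []
    u = _fcm_memberships(values, centroids, m)
    for _ in range(config.max_iter):
        obj = _fcm_objective(values, centroids, u, m)
        trace.append(obj)
        um = u**m
        denom = um.sum(axis=0)
        # A cluster with no mass keeps its centroid (cannot move).
        new_centroids = np.where(denom > 0, (um * values[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), centroids)
        u = _fcm_memberships(values, new_centroids, m)
        centroids = new_centroids
        new_obj = _fcm_objective(values, centroids, u, m)
        if abs(obj - new_obj) <= config.tol * max(abs(obj), 1.0):
            trace.append(new_obj)
            break
    else:
        trace.append(_fcm_objective(values, centroids, u, m))

    order = np.argsort(centroids, kind="stable")
    centroids = centroids[order]
    u = u[:, order]
    return FuzzyResult(
        memberships=u.reshape(*image.shape, k),
        centroids=centroids,
        objective=trace[-1],
        trace=tuple(trace),
    )


def _fcm_memberships(values: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d2 = (values[:, None] - centroids[None, :]) ** 2
    zero = d2 == 0.0
    u = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():
        first = np.argmax(zero[hit], axis=1)
        u[np.nonzero(hit)[0], first] = 1.0
    ok = ~hit
    if ok.any():
        # u_ij = 1 / sum_l (d_ij / d_il)^(1/(m-1)); dividing by the row
        # minimum first keeps the powers <= 1 (no overflow at small m).
        p = -1.0 / (m - 1.0)
        d = d2[ok]
        w = (d / d.min(axis=1, keepdims=True)) ** p
        u[ok] = w / w.sum(axis=1, keepdims=True)
    return u


def _fcm_objective(values: np.ndarray, centroids: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = (values[:, None] - centroids[None, :]) ** 2
    return float((u**m * d2).sum())


def harden_memberships(result: FuzzyResult) -> LabelMask:
    """Collapse fuzzy memberships to a hard label mask by per-pixel argmax.

    Ties go to the lower cluster index; centroids and the FCM objective are
    carried over unchanged so the hardened mask stays traceable to its run.
    """
    labels = np.argmax(result.memberships, axis=-1)
    return LabelMask(
        labels=labels,
        centroids=result.centroids,
        objective=result.objective,
        trace=result.trace,
    )
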