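"""Sketch-initialized k-means.

Standard k-means initialization (random or k-means++) concentrates initial
centers inside large groups when cluster sizes are highly imbalanced. Here
the data are first reduced to a small *skeleton* of weighted points by
iterative locality-sensitive hashing: points falling in the same hash
bucket are merged into their weighted centroid. Large groups shrink far
more than small ones, so weighted k-means++ on the skeleton yields initial
centers that cover small clusters too. The final pass is plain Lloyd on
the full data from those centers.

The hash is the p-stable random-projection family
``h(v) = floor((a.v + b) / w)`` with ``a ~ N(0, I)`` and ``b ~ U[0, w)``;
``l`` such functions are concatenated into a composite code, and two
points share a bucket iff their codes are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "HashFamily",
    "Skeleton",
    "SketchConfig",
    "ClusterResult",
    "sample_hash_family",
    "hash_point",
    "hash_points",
    "split_bucket_radius",
    "filter_buckets_size",
    "reduce_points_once",
    "build_skeleton",
    "weighted_kmeanspp_init",
    "weighted_kmeans",
    "sketch_kmeans",
    "estimate_k_weighted_bic",
]


@dataclass
class HashFamily:
    """Composite random-projection hash: l functions over R^d."""

    a: np.ndarray  # (l, d) standard-normal projection directions
    b: np.ndarray  # (l,) offsets, uniform on [0, w)
    w: float  # quantization step

    def __post_init__(self) -> None:
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.w <= 0:
            raise ValueError("quantization step w must be positive")
        if self.a.shape[0] != self.b.shape[0]:
            raise ValueError("a and b disagree on the number of hash functions")

    @property
    def l(self) -> int:
        return self.a.shape[0]

    @property
    def d(self) -> int:
        return self.a.shape[1]


@dataclass
class Skeleton:
    """Weighted representative points; weights sum to the original count."""

    points: np.ndarray  # (S, d)
    weights: np.ndarray  # (S,)
    provenance: np.ndarray  # (N,) original index -> skeleton index

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("skeleton weights must be positive")
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points/weights length mismatch")

    @property
    def size(self) -> int:
        return self.points.shape[0]


@dataclass
class SketchConfig:
    """Knobs for skeleton construction and the clustering passes.

    The reduction scale ``s`` starts at ``w_scale`` times the median
    nearest-neighbor distance of a subsample and grows by ``w_growth``
    every iteration until the skeleton is small enough; the hash step is
    ``s * sqrt(d)`` (projections onto unnormalized Gaussian directions
    stretch lengths by about sqrt(d)) and the radius correction operates
    at ``radius_scale * s`` in the original space.
    """

    l: int = 5
    w_scale: float = 1.0
    w_growth: float = 1.2
    radius_scale: float = 1.5
    skeleton_target: int | None = None  # resolved to max(50, 10k) when clustering
    max_reduce_iters: int = 100
    correction: str = "radius"  # none | radius | size
    radius: float | None = None  # fixed radius override
    size_threshold: float | None = None  # default: 95th pct of bucket weights
    n_init: int = 1
    seeding_restarts: int = 10
    seeding_candidates: int = 8
    max_lloyd_iters: int = 300
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correction not in ("none", "radius", "size"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.l < 1:
            raise ValueError("l must be at least 1")
        if self.w_growth <= 1.0:
            raise ValueError("w_growth must exceed 1")


@dataclass
class ClusterResult:
    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    k: int
    n_reseeds: int = 0
    extras: dict = field(default_factory=dict)


def sample_hash_family(
    d: int, l: int, w: float, rng: np.random.Generator
) -> HashFamily:
    if d < 1 or l < 1:
        raise ValueError("d and l must be at least 1")
    if w <= 0:
        raise ValueError("quantization step w must be positive")
    a = rng.standard_normal((l, d))
    b = rng.uniform(0.0, w, size=l)
    return HashFamily(a=a, b=b, w=float(w))


def hash_point(f: HashFamily, v: np.ndarray) -> np.ndarray:
    """Composite integer code of a single point."""
    v = np.asarray(v, dtype=float)
    if v.shape != (f.d,):
        raise ValueError(f"point has dimension {v.shape} but the family expects ({f.d},)")
    return np.floor((f.a @ v + f.b) / f.w).astype(np.int64)


def hash_points(f: HashFamily, points: np.ndarray) -> np.ndarray:
    """(n, l) integer codes for a stack of points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != f.d:
        raise ValueError(
            f"points have dimension {points.shape[1]} but the family expects {f.d}"
        )
    return np.floor((points @ f.a.T + f.b) / f.w).astype(np.int64)


def split_bucket_radius(
    points: np.ndarray, weights: np.ndarray, r: float
) -> list[np.ndarray]:
    """Split one bucket into sub-buckets by a sequential radius rule.

    Points are scanned in order; a point joins the nearest existing
    sub-center if within ``r`` of it, otherwise it founds a new sub-bucket
    whose center is the point itself. Returns index arrays into the bucket.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    points = np.atleast_2d(points)
    centers: list[np.ndarray] = []
    members: list[list[int]] = []
    for idx, p in enumerate(points):
        if centers:
            dists = np.linalg.norm(np.asarray(centers) - p, axis=1)
            j = int(np.argmin(dists))
            if dists[j] <= r:
                members[j].append(idx)
                continue
        centers.append(p)
        members.append([idx])
    return [np.asarray(m, dtype=int) for m in members]


def filter_buckets_size(
    buckets: list[np.ndarray], weights: np.ndarray, size_threshold: float
) -> tuple[list[np.ndarray], np.ndarray]:
    """Partition buckets into (small enough to merge, member indices passed through).

    A bucket is merged only if its summed weight is at or below the
    threshold; members of heavier buckets continue to the next iteration
    as individual points.
    """
    if size_threshold < 1:
        raise ValueError("size_threshold must be at least 1")
    weights = np.asarray(weights, dtype=float)
    small: list[np.ndarray] = []
    passed: list[np.ndarray] = []
    for idx in buckets:
        if weights[idx].sum() <= size_threshold:
            small.append(idx)
        else:
            passed.append(idx)
    passthrough = (
        np.concatenate(passed) if passed else np.empty(0, dtype=int)
    )
    return small, passthrough


def _group_codes(codes: np.ndarray) -> list[np.ndarray]:
    """Bucket membership (index arrays) from composite codes."""
    _, inverse = np.unique(codes, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    bounds = np.flatnonzero(np.diff(inverse[order])) + 1
    return np.split(order, bounds)


def reduce_points_once(
    points: np.ndarray,
    weights: np.ndarray,
    f: HashFamily,
    correction: str = "none",
    radius: float | None = None,
    size_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One LSH reduction pass: merge same-bucket points into weighted centroids.

    Returns (new points, new weights, merge map) where ``merge_map[i]`` is
    the output index that input point ``i`` contributed to. Total weight is
    conserved exactly.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    n = points.shape[0]
    if weights.shape != (n,):
        raise ValueError("weights must be one per point")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    buckets = _group_codes(hash_points(f, points))

    if correction == "radius":
        r = float(radius) if radius is not None else f.w
        refined: list[np.ndarray] = []
        for idx in buckets:
            for sub in split_bucket_radius(points[idx], weights[idx], r):
                refined.append(idx[sub])
        buckets = refined
    elif correction == "size":
        if size_threshold is None:
            sums = np.array([weights[idx].sum() for idx in buckets])
            size_threshold = float(np.percentile(sums, 95))
        buckets, passthrough = filter_buckets_size(buckets, weights, max(size_threshold, 1.0))
        buckets = buckets + [np.array([i]) for i in passthrough]
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    out_points = np.empty((len(buckets), points.shape[1]))
    out_weights = np.empty(len(buckets))
    merge_map = np.empty(n, dtype=int)
    for out_idx, idx in enumerate(buckets):
        wsum = weights[idx].sum()
        out_points[out_idx] = (weights[idx][:, None] * points[idx]).sum(axis=0) / wsum
        out_weights[out_idx] = wsum
        merge_map[idx] = out_idx
    return out_points, out_weights, merge_map


def _local_scale(
    points: np.ndarray, rng: np.random.Generator, max_sample: int = 500
) -> float:
    """Median nearest-neighbor distance of a subsample (the merge scale)."""
    n = points.shape[0]
    sub = points
    if n > max_sample:
        sub = points[rng.choice(n, max_sample, replace=False)]
    if sub.shape[0] < 2:
        return 1.0
    dist = cdist(sub, sub)
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    scale = float(np.percentile(nn[np.isfinite(nn)], 50))
    return scale if scale > 0 else 1.0


def _weight_cover(weights: np.ndarray, frac: float = 0.995) -> int:
    """How many of the heaviest points cover ``frac`` of the total weight."""
    s = np.sort(weights)[::-1]
    return int(np.searchsorted(np.cumsum(s), frac * s.sum()) + 1)


def build_skeleton(
    points: np.ndarray,
    cfg: SketchConfig,
    rng: np.random.Generator,
    target: int | None = None,
) -> Skeleton:
    """Iteratively LSH-reduce points into a small weighted skeleton.

    Reduction stops once either the point count, or the number of heavy
    points carrying 99.5% of the weight, drops to ``target`` (light
    stragglers should not keep the merge scale growing past the
    cluster-separation scale).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = points.shape
    if target is None:
        target = cfg.skeleton_target if cfg.skeleton_target is not None else 50
    if target < 1:
        raise ValueError("skeleton target must be at least 1")

    cur_points = points
    cur_weights = np.ones(n)
    provenance = np.arange(n)
    scale = cfg.w_scale * _local_scale(points, rng)
    for _ in range(cfg.max_reduce_iters):
        if cur_points.shape[0] <= target or _weight_cover(cur_weights) <= target:
            break
        fam = sample_hash_family(d, cfg.l, scale * np.sqrt(d), rng)
        radius = cfg.radius if cfg.radius is not None else cfg.radius_scale * scale
        cur_points, cur_weights, merge_map = reduce_points_once(
            cur_points,
            cur_weights,
            fam,
            correction=cfg.correction,
            radius=radius,
            size_threshold=cfg.size_threshold,
        )
        provenance = merge_map[provenance]
        scale *= cfg.w_growth
    return Skeleton(points=cur_points, weights=cur_weights, provenance=provenance)


def weighted_kmeanspp_init(
    points: np.ndarray,
    weights: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_candidates: int = 1,
) -> np.ndarray:
    """k-means++ seeding where selection mass is weight x squared distance.

    The first center is sampled with probability proportional to weight;
    each later center is sampled proportional to weight times squared
    distance to the nearest chosen center. With ``n_candidates > 1``,
    that many candidates are drawn per step and the one minimizing the
    resulting weighted potential is kept (greedy k-means++).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    n = points.shape[0]
    if n < k:
        raise ValueError(f"cannot place {k} centers on {n} points")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    centers = np.empty((k, points.shape[1]))
    probs = weights / weights.sum()
    first = rng.choice(n, p=probs)
    centers[0] = points[first]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for c in range(1, k):
        mass = weights * d2
        total = mass.sum()
        if total <= 0:  # all remaining points coincide with chosen centers
            idx = rng.choice(n, p=probs)
        elif n_candidates <= 1:
            idx = rng.choice(n, p=mass / total)
        else:
            cand = rng.choice(n, size=min(n_candidates, n), p=mass / total)
            potentials = [
                float(np.sum(weights * np.minimum(
                    d2, np.sum((points - points[i]) ** 2, axis=1)
                )))
                for i in cand
            ]
            idx = cand[int(np.argmin(potentials))]
        centers[c] = points[idx]
        d2 = np.minimum(d2, np.sum((points - centers[c]) ** 2, axis=1))
    return centers


def weighted_kmeans(
    points: np.ndarray,
    weights: np.ndarray,
    k: int,
    init_centers: np.ndarray,
    max_iters: int = 300,
    tol: float = 1e-4,
) -> ClusterResult:
    """Lloyd iterations with per-point masses.

    Assignment is nearest-center (ties to the lowest center index, which is
    what argmin gives); the update step is the weighted mean. An emptied
    cluster is re-seeded at the point with the largest weighted squared
    distance to its current center.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    centers = np.array(init_centers, dtype=float, copy=True)
    if centers.shape != (k, points.shape[1]):
        raise ValueError("init_centers must be k x d")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    n_reseeds = 0
    labels = np.zeros(points.shape[0], dtype=int)
    inertia_history: list[float] = []
    for _ in range(max_iters):
        d2 = cdist(points, centers, "sqeuclidean")
        labels = np.argmin(d2, axis=1)
        inertia_history.append(
            float(np.sum(weights * d2[np.arange(len(labels)), labels]))
        )
        new_centers = centers.copy()
        for c in range(k):
            mask = labels == c
            if not mask.any():
                far = int(np.argmax(weights * d2[np.arange(len(labels)), labels]))
                new_centers[c] = points[far]
                labels[far] = c
                n_reseeds += 1
            else:
                wc = weights[mask]
                new_centers[c] = (wc[:, None] * points[mask]).sum(axis=0) / wc.sum()
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            break

    d2 = cdist(points, centers, "sqeuclidean")
    labels = np.argmin(d2, axis=1)
    inertia = float(np.sum(weights * d2[np.arange(len(labels)), labels]))
    return ClusterResult(
        labels=labels, centers=centers, inertia=inertia, k=k, n_reseeds=n_reseeds,
        extras={"inertia_history": inertia_history},
    )


def sketch_kmeans(
    points: np.ndarray,
    k: int,
    cfg: SketchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Full pipeline: skeleton -> weighted k-means seeding -> Lloyd on all points.

    Runs ``cfg.n_init`` independent restarts and keeps the result with the
    lowest final inertia. Deterministic given the generator (or ``cfg.seed``).
    """
    cfg = cfg or SketchConfig()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} points")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    target = cfg.skeleton_target if cfg.skeleton_target is not None else max(50, 10 * k)

    best: ClusterResult | None = None
    for _ in range(max(1, cfg.n_init)):
        skel = build_skeleton(points, cfg, rng, target=target)
        if skel.size < k:  # over-reduced: fall back to the raw points
            skel = Skeleton(points, np.ones(n), np.arange(n))
        # seeding on the skeleton is cheap: restart it several times and
        # keep the centers with the lowest full-data potential (the
        # skeleton objective can be misled by weight lost in reduction)
        best_centers = None
        best_potential = np.inf
        for _ in range(max(1, cfg.seeding_restarts)):
            init = weighted_kmeanspp_init(
                skel.points, skel.weights, k, rng,
                n_candidates=cfg.seeding_candidates,
            )
            trial = weighted_kmeans(
                skel.points, skel.weights, k, init,
                max_iters=cfg.max_lloyd_iters, tol=cfg.tol,
            )
            potential = float(
                cdist(points, trial.centers, "sqeuclidean").min(axis=1).sum()
            )
            if potential < best_potential:
                best_potential = potential
                best_centers = trial.centers
        final = weighted_kmeans(
            points, np.ones(n), k, best_centers,
            max_iters=cfg.max_lloyd_iters, tol=cfg.tol,
        )
        final.extras["skeleton_size"] = skel.size
        if best is None or final.inertia < best.inertia:
            best = final
    assert best is not None
    return best


def _weighted_bic(
    points: np.ndarray, weights: np.ndarray, result: ClusterResult
) -> float:
    """Spherical-Gaussian BIC over weighted points with hard assignments.

    A single pooled variance is shared by all clusters (x-means style);
    per-cluster variances let near-singleton clusters blow up the
    likelihood and systematically overestimate k on reduced skeletons.
    Mixing proportions enter both the likelihood and the parameter count.
    """
    d = points.shape[1]
    total_w = weights.sum()
    ssq_total = 0.0
    mixing = 0.0
    for c in range(result.k):
        mask = result.labels == c
        if not mask.any():
            continue
        wc = weights[mask]
        mu = result.centers[c]
        ssq_total += float(np.sum(wc * np.sum((points[mask] - mu) ** 2, axis=1)))
        mixing += wc.sum() * np.log(wc.sum() / total_w)
    sigma2 = max(ssq_total / (d * total_w), 1e-12)
    ll = (
        -0.5 * total_w * d * np.log(2 * np.pi * sigma2)
        - ssq_total / (2 * sigma2)
        + mixing
    )
    n_params = result.k * d + 1 + (result.k - 1)
    return float(ll - 0.5 * n_params * np.log(total_w))


def estimate_k_weighted_bic(
    skeleton: Skeleton,
    k_range,
    rng: np.random.Generator | None = None,
    cfg: SketchConfig | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick k by maximizing a weighted spherical-Gaussian BIC on the skeleton."""
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    if ks[-1] > skeleton.size:
        raise ValueError(
            f"max k ({ks[-1]}) exceeds the skeleton size ({skeleton.size})"
        )
    cfg = cfg or SketchConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scores: dict[int, float] = {}
    for k in ks:
        res = None
        for _ in range(max(1, cfg.seeding_restarts)):
            init = weighted_kmeanspp_init(
                skeleton.points, skeleton.weights, k, rng,
                n_candidates=cfg.seeding_candidates,
            )
            trial = weighted_kmeans(
                skeleton.points, skeleton.weights, k, init,
                max_iters=cfg.max_lloyd_iters, tol=cfg.tol,
            )
            if res is None or trial.inertia < res.inertia:
                res = trial
        scores[k] = _weighted_bic(skeleton.points, skeleton.weights, res)
    k_star = max(scores, key=lambda k: (scores[k], -k))
    return k_star, scores
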