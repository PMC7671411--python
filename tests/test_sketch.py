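import numpy as np
import pytest

from scsketch.sketch import (
    ClusterResult,
    HashFamily,
    SketchConfig,
    build_skeleton,
    estimate_k_weighted_bic,
    filter_buckets_size,
    hash_point,
    hash_points,
    reduce_points_once,
    sample_hash_family,
    sketch_kmeans,
    split_bucket_radius,
    weighted_kmeans,
    weighted_kmeanspp_init,
)


class TestHashFamily:
    def test_code_length(self, rng):
        f = sample_hash_family(4, 3, 1.0, rng)
        assert hash_point(f, np.zeros(4)).shape == (3,)

    def test_deterministic(self):
        f1 = sample_hash_family(5, 2, 0.5, np.random.default_rng(3))
        f2 = sample_hash_family(5, 2, 0.5, np.random.default_rng(3))
        np.testing.assert_array_equal(f1.a, f2.a)
        np.testing.assert_array_equal(f1.b, f2.b)

    def test_gaussian_moments(self, rng):
        f = sample_hash_family(1000, 100, 1.0, rng)  # 1e5 entries
        entries = f.a.ravel()
        n = entries.size
        assert abs(entries.mean()) < 3 / np.sqrt(n)
        assert abs(entries.var() - 1.0) < 3 * np.sqrt(2 / n)

    def test_offsets_in_range(self, rng):
        f = sample_hash_family(2, 50, 2.5, rng)
        assert np.all((f.b >= 0) & (f.b < 2.5))

    def test_invalid_w(self, rng):
        with pytest.raises(ValueError):
            sample_hash_family(2, 1, 0.0, rng)


class TestHashPoint:
    def test_arithmetic(self):
        f = HashFamily(a=np.array([[1.0, 0.0]]), b=np.array([0.5]), w=1.0)
        assert hash_point(f, np.array([1.0, 0.0]))[0] == 1  # floor(1.5)

    def test_identical_points_same_code(self, rng):
        f = sample_hash_family(6, 4, 0.7, rng)
        v = rng.normal(size=6)
        np.testing.assert_array_equal(hash_point(f, v), hash_point(f, v.copy()))

    def test_huge_w_single_bucket(self, rng):
        pts = rng.normal(size=(50, 3))
        f = sample_hash_family(3, 2, 1e9, rng)
        codes = hash_points(f, pts)
        assert np.unique(codes, axis=0).shape[0] == 1

    def test_dimension_mismatch(self, rng):
        f = sample_hash_family(3, 1, 1.0, rng)
        with pytest.raises(ValueError):
            hash_point(f, np.zeros(4))

    def test_collision_probability_decreases_with_distance(self, rng):
        # l=1, fixed w; empirical collision rate strictly decreasing
        w = 1.0
        base = np.zeros(2)
        rates = []
        for dist in (0.1, 0.5, 2.0):
            other = np.array([dist, 0.0])
            hits = 0
            for _ in range(2000):
                f = sample_hash_family(2, 1, w, rng)
                hits += hash_point(f, base)[0] == hash_point(f, other)[0]
            rates.append(hits / 2000)
        assert rates[0] > rates[1] > rates[2]


class TestReduceOnce:
    def test_all_identical(self, rng):
        pts = np.ones((10, 3))
        f = sample_hash_family(3, 2, 1.0, rng)
        out, w, mm = reduce_points_once(pts, np.ones(10), f)
        assert out.shape == (1, 3)
        assert w[0] == 10
        assert np.all(mm == 0)

    def test_no_collisions_identity(self, rng):
        pts = np.arange(8, dtype=float).reshape(-1, 1) * 100
        f = sample_hash_family(1, 1, 1e-3, rng)
        out, w, mm = reduce_points_once(pts, np.ones(8), f)
        assert out.shape[0] == 8
        np.testing.assert_allclose(np.sort(out.ravel()), pts.ravel())
        assert w.sum() == 8

    def test_weighted_centroid(self, rng):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 100.0]])
        wts = np.array([1.0, 3.0, 1.0])
        f = sample_hash_family(2, 3, 1.0, rng)
        out, w, _ = reduce_points_once(pts, wts, f)
        assert out.shape[0] == 2
        merged = out[np.argmax(w)]
        np.testing.assert_allclose(merged, [0.0, 0.0])
        assert w.max() == 4.0

    def test_weight_conservation(self, rng):
        pts = rng.normal(size=(200, 4))
        wts = rng.integers(1, 5, 200).astype(float)
        f = sample_hash_family(4, 1, 1.0, rng)
        for corr in ("none", "radius", "size"):
            _, w, _ = reduce_points_once(pts, wts, f, correction=corr, radius=1.0)
            assert w.sum() == wts.sum()


class TestBucketCorrections:
    def test_radius_all_within(self):
        pts = np.array([[0.0], [0.1], [0.2]])
        subs = split_bucket_radius(pts, np.ones(3), r=1.0)
        assert len(subs) == 1

    def test_radius_two_far_points(self):
        pts = np.array([[0.0], [10.0]])
        subs = split_bucket_radius(pts, np.ones(2), r=1.0)
        assert len(subs) == 2

    def test_radius_hand_trace(self):
        # sequential rule: 0 founds; 0.4 joins (<=1); 5.0 founds new
        pts = np.array([[0.0], [0.4], [5.0]])
        subs = split_bucket_radius(pts, np.ones(3), r=1.0)
        assert [s.tolist() for s in subs] == [[0, 1], [2]]

    def test_size_filter_partition(self, rng):
        weights = np.array([1.0, 1.0, 4.0, 4.0, 4.0])
        buckets = [np.array([0, 1]), np.array([2, 3, 4])]
        small, passed = filter_buckets_size(buckets, weights, size_threshold=5)
        assert len(small) == 1 and small[0].tolist() == [0, 1]
        assert sorted(passed.tolist()) == [2, 3, 4]

    def test_size_filter_all_singletons(self):
        buckets = [np.array([i]) for i in range(4)]
        small, passed = filter_buckets_size(buckets, np.ones(4), 1)
        assert len(small) == 4 and passed.size == 0


class TestBuildSkeleton:
    def test_small_input_untouched(self, rng):
        pts = rng.normal(size=(20, 3))
        skel = build_skeleton(pts, SketchConfig(), rng, target=50)
        assert skel.size == 20
        np.testing.assert_array_equal(skel.weights, np.ones(20))
        np.testing.assert_array_equal(skel.provenance, np.arange(20))

    def test_identical_points_collapse(self, rng):
        pts = np.ones((30, 2))
        skel = build_skeleton(pts, SketchConfig(), rng, target=5)
        assert skel.size == 1
        assert skel.weights[0] == 30

    def test_weight_conservation_multi_seed(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(300, 5))
            skel = build_skeleton(pts, SketchConfig(seed=seed), rng, target=30)
            assert skel.weights.sum() == 300

    def test_provenance_consistent(self, rng):
        pts = rng.normal(size=(100, 3))
        skel = build_skeleton(pts, SketchConfig(), rng, target=10)
        assert skel.provenance.shape == (100,)
        assert skel.provenance.max() < skel.size
        # per-skeleton-point provenance weight equals its weight
        counts = np.bincount(skel.provenance, minlength=skel.size)
        np.testing.assert_allclose(counts, skel.weights)

    def test_invalid_target(self, rng):
        with pytest.raises(ValueError):
            build_skeleton(np.ones((5, 2)), SketchConfig(), rng, target=0)


class TestWeightedKmeansPP:
    def test_k_equals_points(self, rng):
        pts = np.array([[0.0], [5.0], [10.0]])
        centers = weighted_kmeanspp_init(pts, np.ones(3), 3, rng)
        np.testing.assert_allclose(np.sort(centers.ravel()), [0, 5, 10])

    def test_first_pick_proportional_to_weight(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        wts = np.array([1.0, 2.0, 7.0])
        counts = np.zeros(3)
        n_draws = 10_000
        for seed in range(n_draws):
            rng = np.random.default_rng(seed)
            c = weighted_kmeanspp_init(pts, wts, 1, rng)
            counts[int(c[0, 0])] += 1
        freqs = counts / n_draws
        for i, p in enumerate([0.1, 0.2, 0.7]):
            sigma = np.sqrt(p * (1 - p) / n_draws)
            assert abs(freqs[i] - p) < 4 * sigma

    def test_negligible_weight_rarely_first(self):
        pts = np.array([[0.0], [1.0]])
        wts = np.array([1e-9, 1.0])
        picks = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            c = weighted_kmeanspp_init(pts, wts, 1, rng)
            picks += c[0, 0] == 0.0
        assert picks == 0

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            weighted_kmeanspp_init(np.ones((2, 2)), np.ones(2), 3, rng)


class TestWeightedKmeans:
    def test_k1_weighted_mean(self):
        pts = np.array([[0.0], [1.0]])
        res = weighted_kmeans(pts, np.array([9.0, 1.0]), 1, np.array([[0.5]]))
        assert res.centers[0, 0] == pytest.approx(0.1)

    def test_equal_weights_match_plain_lloyd(self, rng):
        pts = rng.normal(size=(60, 2))
        init = pts[:3].copy()

        def plain_lloyd(points, centers):
            centers = centers.copy()
            for _ in range(300):
                d2 = ((points[:, None] - centers[None]) ** 2).sum(-1)
                labels = d2.argmin(1)
                new = np.stack(
                    [
                        points[labels == c].mean(0) if (labels == c).any() else centers[c]
                        for c in range(3)
                    ]
                )
                if np.abs(new - centers).max() < 1e-4:
                    centers = new
                    break
                centers = new
            d2 = ((points[:, None] - centers[None]) ** 2).sum(-1)
            return d2.argmin(1)

        res = weighted_kmeans(pts, np.ones(60), 3, init)
        np.testing.assert_array_equal(res.labels, plain_lloyd(pts, init))

    def test_inertia_non_increasing(self, rng):
        pts = rng.normal(size=(100, 3))
        init = pts[rng.choice(100, 4, replace=False)]
        res = weighted_kmeans(pts, np.ones(100), 4, init)
        hist = res.extras["inertia_history"]
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_empty_cluster_reseeded(self):
        pts = np.array([[0.0], [0.1], [10.0]])
        init = np.array([[0.0], [100.0]])  # second center attracts nothing
        res = weighted_kmeans(pts, np.ones(3), 2, init)
        assert set(res.labels) == {0, 1}
        assert res.n_reseeds >= 1


class TestSketchKmeans:
    def test_singleton_clusters(self, rng):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        res = sketch_kmeans(pts, 3, SketchConfig(seed=0))
        assert res.inertia == pytest.approx(0.0)
        assert len(set(res.labels)) == 3

    def test_deterministic(self, rng):
        pts = np.random.default_rng(5).normal(size=(200, 4))
        r1 = sketch_kmeans(pts, 3, SketchConfig(seed=9))
        r2 = sketch_kmeans(pts, 3, SketchConfig(seed=9))
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.inertia == r2.inertia

    def test_n_less_than_k(self):
        with pytest.raises(ValueError):
            sketch_kmeans(np.ones((2, 2)), 3, SketchConfig())


class TestEstimateK:
    def test_singleton_range(self, rng):
        pts = rng.normal(size=(100, 3))
        skel = build_skeleton(pts, SketchConfig(), rng, target=50)
        k, scores = estimate_k_weighted_bic(skel, [3], rng)
        assert k == 3 and set(scores) == {3}

    def test_empty_range(self, rng):
        pts = rng.normal(size=(50, 2))
        skel = build_skeleton(pts, SketchConfig(), rng, target=30)
        with pytest.raises(ValueError):
            estimate_k_weighted_bic(skel, [], rng)

    def test_k_exceeds_skeleton(self, rng):
        pts = np.ones((10, 2))
        skel = build_skeleton(pts, SketchConfig(), rng, target=5)
        with pytest.raises(ValueError):
            estimate_k_weighted_bic(skel, range(2, 50), rng)
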