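import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from fundusseg.preprocess import (
    ResizeSpec,
    SplitConfig,
    ThresholdParams,
    alpha_composite,
    compose_ground_truth,
    contour_threshold,
    fill_polygon,
    minmax_normalize,
    resize,
    rgba_to_rgb,
    split_dataset,
)


class TestContourThreshold:
    def test_zero_variance(self):
        img = np.full((4, 4), 100.0)
        assert contour_threshold(img, ThresholdParams(k=1)).sum() == 0

    def test_hand_computed_threshold(self):
        # mean 25, population std 43.301 -> threshold 68.301
        img = np.array([[0.0, 0.0], [0.0, 100.0]])
        mask = contour_threshold(img, ThresholdParams(k=1))
        assert np.array_equal(mask, [[0, 0], [0, 1]])

    def test_large_k_empties_mask(self, rng):
        img = rng.random((10, 10))
        assert contour_threshold(img, ThresholdParams(k=1e6)).sum() == 0

    def test_monotone_in_k(self, rng):
        img = rng.random((16, 16))
        prev = contour_threshold(img, ThresholdParams(k=0.0))
        for k in (0.5, 1.0, 2.0, 3.0):
            cur = contour_threshold(img, ThresholdParams(k=k))
            assert np.all(cur <= prev)
            prev = cur

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contour_threshold(np.empty((0, 0)), ThresholdParams())


class TestFillPolygon:
    def test_square_covers_nine_pixels(self):
        verts = [(0.5, 0.5), (3.5, 0.5), (3.5, 3.5), (0.5, 3.5)]
        mask = fill_polygon(verts, (5, 5))
        assert mask.sum() == 9
        assert mask[1:4, 1:4].all()

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fill_polygon([(0, 0), (1, 1)], (5, 5))

    def test_mirror_symmetry(self):
        tri = [(0.2, 0.2), (6.7, 0.4), (1.3, 6.6)]
        mirrored = [(9 - x, y) for x, y in tri]
        a = fill_polygon(tri, (10, 10))
        b = fill_polygon(mirrored, (10, 10))
        assert np.array_equal(a, b[:, ::-1])

    def test_against_shapely_oracle(self, rng):
        for _ in range(5):
            verts = [(rng.uniform(0.1, 11.9), rng.uniform(0.1, 11.9))
                     for _ in range(3)]
            poly = Polygon(verts)
            expected = np.array(
                [[poly.contains(Point(x, y)) for x in range(12)]
                 for y in range(12)], dtype=np.uint8)
            assert np.array_equal(fill_polygon(verts, (12, 12)), expected)


class TestCompositing:
    def test_alpha_identities(self, rng):
        src = rng.random((5, 5)) * 255
        dst = rng.random((5, 5)) * 255
        assert np.allclose(alpha_composite(src, dst, 1.0), src)
        assert np.allclose(alpha_composite(src, dst, 0.0), dst)

    def test_convex_combination_value(self):
        out = alpha_composite(np.full((2, 2), 200.0), np.full((2, 2), 100.0), 0.25)
        assert np.allclose(out, 125.0)

    def test_linear_and_bounded(self, rng):
        src, dst = rng.random((6, 6)), rng.random((6, 6))
        a_half = alpha_composite(src, dst, 0.5)
        a_quarter = alpha_composite(src, dst, 0.25)
        assert np.allclose(a_quarter, 0.5 * (a_half + dst))
        lo = np.minimum(src, dst) - 1e-12
        hi = np.maximum(src, dst) + 1e-12
        assert np.all(a_half >= lo) and np.all(a_half <= hi)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            alpha_composite(np.ones((2, 2)), np.ones((2, 2)), 1.5)

    def test_rgba_identities(self, rng):
        rgba = rng.integers(0, 256, (4, 4, 4)).astype(np.uint8)
        rgba[..., 3] = 255
        assert np.array_equal(rgba_to_rgb(rgba), rgba[..., :3])
        rgba[..., 3] = 0
        assert rgba_to_rgb(rgba, background=(0, 0, 0)).sum() == 0

    def test_rgba_half_blend(self):
        img = np.zeros((1, 1, 4))
        img[0, 0] = (200, 0, 0, 0.5)
        out = rgba_to_rgb(img, background=(100, 100, 100))
        assert np.allclose(out[0, 0], (150, 50, 50))

    def test_wrong_channels(self):
        with pytest.raises(ValueError):
            rgba_to_rgb(np.zeros((3, 3, 3)))


class TestResizeNormalize:
    def test_identity_resize(self, rng):
        img = rng.random((8, 8))
        out = resize(img, ResizeSpec(target_size=(8, 8), order=1))
        assert np.allclose(out, img)

    def test_nearest_mask_upsample(self):
        mask = np.array([[1, 1], [2, 2]], dtype=np.int64)
        out = resize(mask, ResizeSpec(target_size=(4, 4), order=0))
        assert np.array_equal(out[:2], np.ones((2, 4)))
        assert np.array_equal(out[2:], np.full((2, 4), 2))

    def test_integer_mask_with_linear_order_rejected(self):
        with pytest.raises(TypeError):
            resize(np.ones((4, 4), dtype=np.int64), ResizeSpec((8, 8), order=1))

    def test_constant_preserved(self):
        out = resize(np.full((5, 5), 3.3), ResizeSpec((13, 7), order=1))
        assert np.allclose(out, 3.3)

    def test_minmax_endpoints_and_constant(self):
        out = minmax_normalize(np.array([[0.0, 255.0]]))
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.all(minmax_normalize(np.full((3, 3), 9.0)) == 0.0)

    def test_minmax_values(self):
        out = minmax_normalize(np.array([[10.0, 20.0, 30.0]]))
        assert np.allclose(out, [[0.0, 0.5, 1.0]])


class TestComposeGroundTruth:
    def test_all_empty(self):
        z = np.zeros((3, 3), dtype=bool)
        assert compose_ground_truth(z, z, z, z, z).sum() == 0

    def test_disc_only(self):
        z = np.zeros((3, 3), dtype=bool)
        d = z.copy()
        d[1, 1] = True
        out = compose_ground_truth(d, z, z, z, z)
        assert set(np.unique(out)) == {0, 1}

    def test_precedence_brute_force(self):
        # every overlap pattern of the five masks on one pixel
        order = [2, 3, 1, 4, 5]  # cup > vessels > disc > beta > alpha
        for bits in range(32):
            masks = [np.array([[bool(bits >> i & 1)]]) for i in range(5)]
            disc, cup, vessels, beta, alpha = masks
            out = compose_ground_truth(disc, cup, vessels, beta, alpha)[0, 0]
            present = {1: disc, 2: cup, 3: vessels, 4: beta, 5: alpha}
            expected = next((c for c in order if present[c][0, 0]), 0)
            assert out == expected

    def test_idempotent_on_own_decomposition(self, small_sample):
        mask = small_sample.mask
        parts = [mask == c for c in (1, 2, 3, 4, 5)]
        out = compose_ground_truth(parts[0], parts[1], parts[2], parts[3],
                                   parts[4])
        assert np.array_equal(out, mask)

    def test_counts_never_exceed_inputs(self, rng):
        masks = [rng.random((8, 8)) > 0.6 for _ in range(5)]
        out = compose_ground_truth(*masks)
        for cid, m in zip((1, 2, 3, 4, 5), masks):
            assert (out == cid).sum() <= m.sum()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compose_ground_truth(np.zeros((2, 2)), np.zeros((3, 3)),
                                 np.zeros((2, 2)), np.zeros((2, 2)),
                                 np.zeros((2, 2)))


class TestSplit:
    def test_counts(self):
        tr, te = split_dataset(10, SplitConfig(test_fraction=0.2))
        assert len(tr) == 8 and len(te) == 2
        tr, te = split_dataset(45, SplitConfig(test_fraction=0.2))
        assert len(tr) == 36 and len(te) == 9

    def test_deterministic_partition(self):
        a = split_dataset(20, SplitConfig(seed=42))
        b = split_dataset(20, SplitConfig(seed=42))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert sorted(np.concatenate(a)) == list(range(20))

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_dataset(1)
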