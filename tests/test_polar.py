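import math

import numpy as np
import pytest

from fundusseg.polar import (
    PolarGrid,
    PolarImage,
    cart_to_polar,
    estimate_disc_center,
    from_polar,
    polar_to_cart,
    to_polar,
)


class TestPointTransforms:
    def test_axis_cases(self):
        assert polar_to_cart(5, 0.0) == (5.0, 0.0)
        x, y = polar_to_cart(0, 1.234)
        assert (x, y) == (0.0, 0.0)
        r, t = cart_to_polar(-1.0, 0.0)
        assert r == 1.0 and t == pytest.approx(math.pi)

    def test_origin_convention(self):
        assert cart_to_polar(0.0, 0.0) == (0.0, 0.0)

    def test_345_triangle(self):
        x, y = polar_to_cart(5.0, math.atan2(4, 3))
        assert x == pytest.approx(3.0, abs=1e-12)
        assert y == pytest.approx(4.0, abs=1e-12)

    def test_roundtrip_1000_points(self, rng):
        pts = rng.normal(0, 10, (1000, 2))
        r, t = cart_to_polar(pts[:, 0], pts[:, 1])
        x, y = polar_to_cart(r, t)
        assert np.allclose(np.stack([x, y], axis=1), pts, atol=1e-12)
        assert np.all(t > -np.pi) and np.all(t <= np.pi)


def _disk(h, w, center, radius):
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    return (np.hypot(xs - center[0], ys - center[1]) <= radius).astype(float)


class TestImageTransforms:
    def test_constant_image(self):
        grid = PolarGrid(center=(32, 32), radius=20, angular_bins=64,
                         radial_samples=32)
        out = to_polar(np.full((64, 64), 3.5), grid)
        assert np.allclose(out.data, 3.5)

    def test_radial_image_constant_rows(self):
        h = w = 65
        ys, xs = np.mgrid[0:h, 0:w].astype(float)
        dist = np.hypot(xs - 32, ys - 32)
        grid = PolarGrid(center=(32, 32), radius=20, angular_bins=40,
                         radial_samples=21)
        out = to_polar(dist, grid, order=1).data
        # constant along the angular axis (up to bilinear interpolation
        # error, largest near the center kink of the distance function),
        # increasing along the radial axis
        dev = np.abs(out - out.mean(axis=0)[None, :])
        assert dev.max() < 0.1
        assert dev[:, 5:].max() < 0.02
        assert np.all(np.diff(out.mean(axis=0)) > 0)

    def test_disk_membership_analytic(self):
        grid = PolarGrid(center=(40, 40), radius=20, angular_bins=36,
                         radial_samples=41)
        img = _disk(81, 81, (40, 40), 10.0)
        out = to_polar(img, grid, order=0).data
        r_s = grid.radius * np.arange(41) / 40.0
        expected = (r_s <= 10.0).astype(float)
        # nearest-neighbour pixel snapping can flip samples right at the
        # disk rim; membership must be exact away from it
        off_rim = np.abs(r_s - 10.0) > 0.9
        assert np.array_equal(out[:, off_rim],
                              np.tile(expected[off_rim], (36, 1)))
        assert np.abs(out - expected[None, :]).sum(axis=1).max() <= 2

    def test_center_outside_rejected(self):
        grid = PolarGrid(center=(100, 100), radius=5)
        with pytest.raises(ValueError):
            to_polar(np.zeros((10, 10)), grid)

    def test_roundtrip_constant_inside_rmax(self):
        grid = PolarGrid(center=(32, 32), radius=25, angular_bins=100,
                         radial_samples=50)
        polar_img = to_polar(np.full((64, 64), 2.0), grid)
        back = from_polar(polar_img, (64, 64), fill=-1.0)
        ys, xs = np.mgrid[0:64, 0:64].astype(float)
        inside = np.hypot(xs - 32, ys - 32) <= 25
        assert np.allclose(back[inside], 2.0)
        assert np.allclose(back[~inside], -1.0)

    def test_disk_roundtrip_jaccard(self):
        h = w = 128
        grid = PolarGrid(center=(64, 64), radius=40, angular_bins=400,
                         radial_samples=400)
        img = _disk(h, w, (64, 64), 20.0)
        back = from_polar(to_polar(img, grid, order=1), (h, w), order=1)
        ys, xs = np.mgrid[0:h, 0:w].astype(float)
        inside = np.hypot(xs - 64, ys - 64) <= 40
        a = img[inside] > 0.5
        b = back[inside] > 0.5
        jaccard = (a & b).sum() / (a | b).sum()
        assert jaccard >= 0.98

    def test_nearest_roundtrip_preserves_ids(self, small_sample):
        mask = small_sample.mask
        grid = PolarGrid(center=(32, 32), radius=28, angular_bins=200,
                         radial_samples=100)
        back = from_polar(to_polar(mask, grid, order=0), mask.shape, order=0,
                          fill=0)
        assert set(np.unique(back)) <= set(np.unique(mask))

    def test_error_shrinks_with_resolution(self):
        h = w = 96
        ys, xs = np.mgrid[0:h, 0:w].astype(float)
        smooth = np.sin(xs / 9.0) + np.cos(ys / 7.0)
        errs = []
        for bins in (100, 400):
            grid = PolarGrid(center=(48, 48), radius=30, angular_bins=bins,
                             radial_samples=bins)
            back = from_polar(to_polar(smooth, grid, order=1), (h, w), order=1)
            inside = np.hypot(xs - 48, ys - 48) <= 29
            errs.append(np.abs(back - smooth)[inside].mean())
        assert errs[1] < errs[0]

    def test_rotation_equivariance_cyclic_shift(self):
        # wedge image whose value depends only on the angular sector: a
        # rotation by k angular bins must cyclically shift the polar rows
        h = w = 101
        bins = 40
        u0 = v0 = 50
        ys, xs = np.mgrid[0:h, 0:w].astype(float)

        def wedge_image(offset_bins):
            theta = np.arctan2(ys - v0, xs - u0)
            rot = math.radians(-90.0)
            # half-bin offset keeps sampled angles away from sector edges
            shifted = (theta - rot - (2 * offset_bins + 1) * np.pi / bins) \
                % (2 * np.pi)
            return np.floor(shifted / (2 * np.pi / 8))  # 8 sectors

        grid = PolarGrid(center=(u0, v0), radius=30, angular_bins=bins,
                         radial_samples=16)
        # drop inner radii where pixel-center snapping perturbs the angle
        # by more than the half-bin safety margin
        base = to_polar(wedge_image(0), grid, order=0).data[:, 7:]
        for k in (5, 10, 25):
            rotated = to_polar(wedge_image(k), grid, order=0).data[:, 7:]
            assert np.array_equal(np.roll(base, k, axis=0), rotated)

    def test_polar_image_requires_matching_grid(self):
        grid = PolarGrid(center=(5, 5), radius=3, angular_bins=8,
                         radial_samples=4)
        with pytest.raises(ValueError):
            PolarImage(data=np.zeros((9, 4)), grid=grid)


class TestCenterFallback:
    def test_bright_blob_centroid(self):
        img = np.zeros((50, 50))
        img[18:25, 30:37] = 100.0
        u, v = estimate_disc_center(img, k=2.0)
        assert u == pytest.approx(33.0, abs=0.6)
        assert v == pytest.approx(21.0, abs=0.6)

    def test_flat_image_falls_back_to_middle(self):
        u, v = estimate_disc_center(np.zeros((21, 31)))
        assert (u, v) == (15.0, 10.0)
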