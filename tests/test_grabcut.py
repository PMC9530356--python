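"""GrabCut segmentation: GMM fitting, smoothness term, min-cut, contours."""

import numpy as np
import pytest

from woundmetry.geometry import BoundingBox, polygon_area, polygon_perimeter
from woundmetry.grabcut import (
    EmptyRegionError,
    GrabcutParams,
    InvalidBoxError,
    NoBackgroundError,
    TrimapLabel,
    assign_components,
    extract_contours,
    grabcut_segment,
    init_trimap,
    learn_gmm,
    smoothness_beta,
)


def two_color_disk_scene(radius=20, size=60, fg=(150, 40, 40), bg=(200, 170, 150),
                         noise_sd=0.0, seed=0):
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (xx - size // 2) ** 2 + (yy - size // 2) ** 2 <= radius**2
    img = np.zeros((size, size, 3), float)
    img[...] = bg
    img[disk] = fg
    if noise_sd:
        img += np.random.default_rng(seed).normal(0, noise_sd, img.shape)
        img = np.clip(img, 0, 255)
    return img, disk


class TestTrimap:
    def test_interior_count(self):
        t = init_trimap((10, 10), BoundingBox(2, 2, 8, 8))
        assert (t == TrimapLabel.PROBABLE_FOREGROUND).sum() == 36
        assert (t == TrimapLabel.DEFINITE_BACKGROUND).sum() == 64

    def test_full_box_leaves_no_background(self):
        t = init_trimap((5, 5), BoundingBox(0, 0, 5, 5))
        assert (t == TrimapLabel.DEFINITE_BACKGROUND).sum() == 0

    def test_single_pixel_box(self):
        t = init_trimap((4, 4), BoundingBox(0, 0, 1, 1))
        assert (t == TrimapLabel.PROBABLE_FOREGROUND).sum() == 1

    def test_box_outside_image_rejected(self):
        with pytest.raises(InvalidBoxError):
            init_trimap((5, 5), BoundingBox(10, 10, 12, 12))


class TestGmm:
    def test_single_color_component(self):
        px = np.tile([10.0, 20.0, 30.0], (50, 1))
        model = learn_gmm(px, np.zeros(50, int), K=1, cov_reg=1e-6)
        np.testing.assert_allclose(model.means[0], [10, 20, 30])
        np.testing.assert_allclose(model.covariances[0], 1e-6 * np.eye(3))

    def test_two_separated_colors(self):
        px = np.vstack([np.tile([0.0, 0, 0], (30, 1)), np.tile([200.0, 0, 0], (70, 1))])
        a = np.r_[np.zeros(30, int), np.ones(70, int)]
        model = learn_gmm(px, a, K=2)
        np.testing.assert_allclose(model.means[0], [0, 0, 0])
        np.testing.assert_allclose(model.means[1], [200, 0, 0])
        np.testing.assert_allclose(model.weights, [0.3, 0.7])

    def test_parameter_recovery_from_simulated_mixture(self):
        # oracle: known 2-component generator, hard labels known
        rng = np.random.default_rng(42)
        true_means = np.array([[60.0, 90.0, 120.0], [180.0, 40.0, 70.0]])
        n = 10_000
        z = rng.random(n) < 0.4
        px = np.where(z[:, None],
                      rng.multivariate_normal(true_means[0], 25 * np.eye(3), n),
                      rng.multivariate_normal(true_means[1], 25 * np.eye(3), n))
        model = learn_gmm(px, (~z).astype(int), K=2)
        # label 0 <-> first true component
        assert np.abs(model.means[0] - true_means[0]).max() / true_means[0].min() < 0.02
        assert np.abs(model.means[1] - true_means[1]).max() / true_means[1].min() < 0.02

    def test_empty_pixels_rejected(self):
        with pytest.raises(EmptyRegionError):
            learn_gmm(np.empty((0, 3)), np.empty(0, int), K=2)

    def test_assignment_matches_bruteforce_density_argmax(self):
        rng = np.random.default_rng(7)
        px = rng.uniform(0, 255, (100, 3))
        labels = rng.integers(0, 3, 100)
        fg = learn_gmm(rng.uniform(0, 255, (300, 3)), rng.integers(0, 3, 300), K=3)
        bg = learn_gmm(rng.uniform(0, 255, (300, 3)), rng.integers(0, 3, 300), K=3)
        mask = rng.random(100) < 0.5
        got = assign_components(px, fg, bg, mask)
        # oracle: per-component weighted normal density evaluated directly
        from scipy.stats import multivariate_normal

        for i in range(100):
            model = fg if mask[i] else bg
            dens = [
                model.weights[k] * multivariate_normal.pdf(
                    px[i], model.means[k], model.covariances[k])
                for k in range(model.K)
            ]
            assert got[i] == int(np.argmax(dens))

    def test_tie_breaks_to_lowest_index(self):
        px = np.array([[100.0, 0.0, 0.0]])
        dup = learn_gmm(
            np.vstack([np.tile([90.0, 0, 0], (10, 1)), np.tile([110.0, 0, 0], (10, 1))]),
            np.r_[np.zeros(10, int), np.ones(10, int)], K=2)
        got = assign_components(px, dup, dup, np.array([True]))
        assert got[0] == 0


class TestSmoothnessBeta:
    def test_constant_image_gives_zero(self):
        assert smoothness_beta(np.full((8, 8, 3), 42.0)) == 0.0

    def test_single_pair(self):
        img = np.zeros((1, 2, 3))
        img[0, 1, 0] = 10.0
        assert smoothness_beta(img) == pytest.approx(1.0 / 200.0)

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, (8, 8, 3))
        sq = []
        for r in range(8):
            for c in range(8):
                for dr, dc in [(0, 1), (1, -1), (1, 0), (1, 1)]:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 8 and 0 <= cc < 8:
                        sq.append(np.sum((img[r, c] - img[rr, cc]) ** 2))
        assert smoothness_beta(img) == pytest.approx(1.0 / (2.0 * np.mean(sq)), rel=1e-12)


class TestGrabcutSegment:
    def test_two_color_disk_iou(self):
        img, disk = two_color_disk_scene()
        res = grabcut_segment(img, BoundingBox(5, 5, 55, 55))
        iou = (res.mask & disk).sum() / (res.mask | disk).sum()
        assert iou >= 0.99

    @pytest.mark.parametrize("gamma", [10.0, 50.0, 100.0])
    def test_exact_color_partition_across_gamma(self, gamma):
        img, disk = two_color_disk_scene()
        res = grabcut_segment(img, BoundingBox(5, 5, 55, 55),
                              GrabcutParams(gamma=gamma))
        assert np.array_equal(res.mask, disk)

    def test_energy_trace_non_increasing(self):
        img, _ = two_color_disk_scene(noise_sd=10, seed=1)
        res = grabcut_segment(img, BoundingBox(5, 5, 55, 55))
        e = np.asarray(res.energy_trace)
        assert np.all(np.diff(e) <= 1e-6 * abs(e[0]))

    def test_hard_background_constraint(self):
        img, _ = two_color_disk_scene(noise_sd=10, seed=2)
        box = BoundingBox(8, 8, 52, 52)
        res = grabcut_segment(img, box)
        outside = np.ones_like(res.mask)
        outside[box.ymin:box.ymax, box.xmin:box.xmax] = False
        assert not np.any(res.mask & outside)

    def test_deterministic_masks_per_seed(self):
        img, _ = two_color_disk_scene(noise_sd=12, seed=3)
        a = grabcut_segment(img, BoundingBox(5, 5, 55, 55), GrabcutParams(seed=9))
        b = grabcut_segment(img, BoundingBox(5, 5, 55, 55), GrabcutParams(seed=9))
        assert np.array_equal(a.mask, b.mask)
        assert a.energy_trace == b.energy_trace

    def test_full_image_box_rejected(self):
        img, _ = two_color_disk_scene()
        with pytest.raises(NoBackgroundError):
            grabcut_segment(img, BoundingBox(0, 0, 60, 60))


class TestExtractContours:
    def test_filled_square_pixel_boundary(self):
        m = np.zeros((10, 10), bool)
        m[0:5, 0:5] = True
        (c,) = extract_contours(m, min_area=1)
        assert len(c) == 4  # collinear vertices merged
        assert polygon_area(c) == 25.0
        assert polygon_perimeter(c) == 20.0

    def test_two_disjoint_squares(self):
        m = np.zeros((20, 20), bool)
        m[1:6, 1:6] = True
        m[10:18, 10:18] = True
        cs = extract_contours(m, min_area=1)
        assert len(cs) == 2
        assert sorted(polygon_area(c) for c in cs) == [25.0, 64.0]

    def test_disk_area_matches_pixel_count(self):
        yy, xx = np.mgrid[0:50, 0:50]
        disk = (xx - 25) ** 2 + (yy - 25) ** 2 <= 20**2
        (c,) = extract_contours(disk)
        assert polygon_area(c) == pytest.approx(disk.sum(), rel=1e-12)
        assert polygon_area(c) == pytest.approx(np.pi * 400, rel=0.02)

    def test_min_area_suppression(self):
        m = np.zeros((20, 20), bool)
        m[0:2, 0:2] = True       # 4 px, below default threshold
        m[5:15, 5:15] = True     # 100 px
        cs = extract_contours(m)  # default min_area=16
        assert len(cs) == 1
        assert polygon_area(cs[0]) == 100.0

    def test_diagonally_touching_pixels_form_one_component(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = m[1, 1] = True
        cs = extract_contours(m, min_area=0)
        assert len(cs) == 1
        assert polygon_area(cs[0]) == 2.0

    def test_empty_mask(self):
        assert extract_contours(np.zeros((5, 5), bool)) == []

    def test_contours_counter_clockwise(self):
        from woundmetry.geometry import signed_polygon_area

        m = np.zeros((10, 10), bool)
        m[2:8, 2:8] = True
        (c,) = extract_contours(m, min_area=1)
        assert signed_polygon_area(c.vertices) > 0
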