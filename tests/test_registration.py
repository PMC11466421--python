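"""Downsampling, color segmentation, Canny edges, ECC alignment and warping."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.transform import ProjectiveTransform, warp as sk_warp

from msinmf import (
    ColorStats,
    align_ecc,
    apply_warp,
    best_alignment,
    detect_edges,
    downsample_to,
    roi_color_stats,
    segment_by_color,
)
from msinmf.synthetic import PhantomConfig, make_ground_truth


def _planted_homography(width, height, frac, rng):
    corners = np.array([[0.0, 0.0], [width - 1.0, 0.0], [width - 1.0, height - 1.0], [0.0, height - 1.0]])
    pert = corners + rng.uniform(-frac, frac, (4, 2)) * width
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src=pert, dst=corners)
    else:  # pragma: no cover - older scikit-image
        tf = ProjectiveTransform()
        tf.estimate(src=pert, dst=corners)
    return tf.params / tf.params[2, 2], corners


def _corner_error(warp, truth, corners):
    ch = np.c_[corners, np.ones(4)].T

    def ap(H):
        q = H @ ch
        return (q[:2] / q[2]).T

    return float(np.linalg.norm(ap(warp) - ap(truth), axis=1).max())


class TestDownsample:
    def test_exact_target_shape(self):
        img = np.random.default_rng(0).integers(0, 255, (200, 200, 3), dtype=np.uint8)
        out = downsample_to(img, (20, 20))
        assert out.shape == (20, 20, 3)
        assert out.dtype == np.uint8

    def test_constant_image_stays_constant(self):
        img = np.full((64, 48, 3), 133, np.uint8)
        out = downsample_to(img, (16, 12))
        assert np.all(out == 133)

    def test_checkerboard_averages_to_midgray(self):
        tile = np.array([[0, 255], [255, 0]], dtype=float)
        img = np.tile(tile, (16, 16))
        out = downsample_to(img, (16, 16))  # block size = checker period
        assert np.allclose(out, 127.5)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample_to(np.zeros((10, 10)), (20, 20))


class TestRoiColorStats:
    def test_uniform_roi(self):
        img = np.zeros((16, 16, 3))
        img[:] = (100.0, 50.0, 200.0)
        stats = roi_color_stats(img, (8, 8), roi_size=8)
        assert np.allclose(stats.mean, (100, 50, 200))
        assert np.allclose(stats.sd, 0.0)

    def test_outlier_pixel_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(120.0, 3.0, (8, 8, 3))
        img = base.copy()
        img[4, 4] = (255.0, 0.0, 255.0)  # lone extreme pixel
        full = np.zeros((16, 16, 3))
        full[4:12, 4:12] = img
        clean = np.zeros((16, 16, 3))
        clean[4:12, 4:12] = base
        with_outlier = roi_color_stats(full, (8, 8), roi_size=8)
        # statistics computed without the outlier are nearly reproduced
        reference = base.reshape(-1, 3)
        keep = np.ones(64, bool)
        keep[4 * 8 + 4] = False
        assert np.allclose(with_outlier.mean, reference[keep].mean(axis=0), atol=0.5)
        assert np.allclose(with_outlier.sd, reference[keep].std(axis=0), atol=0.5)

    def test_roi_outside_bounds_rejected(self):
        img = np.zeros((16, 16, 3))
        with pytest.raises(ValueError):
            roi_color_stats(img, (2, 2), roi_size=8)


class TestSegmentByColor:
    def test_pixel_at_mean_is_inside(self):
        stats = ColorStats(mean=np.array([10.0, 20.0, 30.0]), sd=np.array([2.0, 2.0, 2.0]))
        img = np.zeros((1, 1, 3))
        img[0, 0] = (10, 20, 30)
        assert segment_by_color(img, stats)[0, 0]

    def test_pixel_beyond_two_sigma_excluded(self):
        stats = ColorStats(mean=np.array([10.0, 20.0, 30.0]), sd=np.array([2.0, 2.0, 2.0]))
        img = np.zeros((1, 1, 3))
        img[0, 0] = (10 + 3 * 2.0, 20, 30)
        assert not segment_by_color(img, stats)[0, 0]

    def test_uniform_image_fully_selected(self):
        img = np.full((12, 12, 3), 77.0)
        stats = roi_color_stats(img, (6, 6), roi_size=8)
        assert segment_by_color(img, stats).all()

    def test_two_region_image_recovered(self):
        rng = np.random.default_rng(1)
        img = np.empty((40, 40, 3))
        img[:, :20] = (200.0, 80.0, 90.0)
        img[:, 20:] = (60.0, 150.0, 210.0)
        # bounded noise: every region pixel stays within mean +- 2 sd
        img += rng.uniform(-4.0, 4.0, img.shape)
        stats = roi_color_stats(img, (10, 20), roi_size=8)
        mask = segment_by_color(img, stats)
        truth = np.zeros((40, 40), bool)
        truth[:, :20] = True
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard > 0.95


class TestDetectEdges:
    def test_constant_image_has_no_edges(self):
        assert not detect_edges(np.full((30, 30), 90.0)).any()

    def test_rectangle_boundary_traced(self):
        img = np.zeros((40, 40))
        img[10:30, 12:28] = 200.0
        edges = detect_edges(img)
        ys, xs = np.nonzero(edges)
        assert len(ys) > 0
        # every edge pixel is within 1.5 px of the rectangle outline
        border_y = (np.abs(ys - 9.5) <= 1.5) | (np.abs(ys - 29.5) <= 1.5)
        border_x = (np.abs(xs - 11.5) <= 1.5) | (np.abs(xs - 27.5) <= 1.5)
        assert np.all(border_y | border_x)

    def test_annulus_has_two_closed_contours(self):
        from skimage.measure import label

        yy, xx = np.mgrid[0:60, 0:60]
        r = np.hypot(xx - 29.5, yy - 29.5)
        img = ((r > 10) & (r < 20)).astype(float)
        n_contours = label(detect_edges(img), connectivity=2).max()
        assert n_contours == 2

    def test_rgb_input_rejected(self):
        with pytest.raises(ValueError):
            detect_edges(np.zeros((8, 8, 3)))


@pytest.fixture(scope="module")
def structure_map():
    gt = make_ground_truth(PhantomConfig(seed=3))
    return gt.z["ds0"][:, :, [1, 3, 5]].sum(axis=2)


class TestAlignECC:
    def test_self_alignment_is_identity(self, structure_map):
        edges = detect_edges(structure_map)
        res = align_ecc(edges, edges)
        assert res.ecc == pytest.approx(1.0, abs=1e-6)
        assert np.abs(res.warp - np.eye(3)).max() < 1e-6

    def test_planted_warp_recovered_subpixel(self, structure_map):
        h, w = structure_map.shape
        rng = np.random.default_rng(0)
        for _ in range(3):
            T, corners = _planted_homography(w, h, 0.05, rng)
            moving = sk_warp(structure_map, inverse_map=ProjectiveTransform(matrix=T), order=1)
            res = align_ecc(structure_map, moving)
            assert res.ecc > 0.98
            assert _corner_error(res.warp, T, corners) < 1.0

    def test_unstructured_noise_is_flagged_low(self, structure_map):
        rng = np.random.default_rng(1)
        noise = rng.uniform(size=structure_map.shape)
        res = align_ecc(structure_map, noise)
        assert res.ecc < 0.5

    def test_ecc_invariant_to_affine_intensity_rescale(self, structure_map):
        h, w = structure_map.shape
        rng = np.random.default_rng(2)
        T, _ = _planted_homography(w, h, 0.03, rng)
        moving = sk_warp(structure_map, inverse_map=ProjectiveTransform(matrix=T), order=1)
        base = align_ecc(structure_map, moving)
        scaled = align_ecc(structure_map * 7.5, moving * 0.2 + 0.05)
        assert scaled.ecc == pytest.approx(base.ecc, abs=5e-3)

    def test_unknown_motion_rejected(self, structure_map):
        with pytest.raises(ValueError):
            align_ecc(structure_map, structure_map, motion="rigid")


class TestBestAlignment:
    def test_single_pair_returned(self, structure_map):
        res = best_alignment([structure_map], [structure_map > structure_map.mean()])
        assert res.fixed_id == 0 and res.moving_id == 0

    def test_matching_pair_selected(self):
        gt = make_ground_truth(PhantomConfig(seed=3))
        z = gt.z["ds0"]
        maps = [z[:, :, 1], z[:, :, 8]]  # a ring and a blob
        segments = [m > 0.3 * m.max() for m in maps]
        res = best_alignment(maps, segments)
        assert res.fixed_id == res.moving_id

    def test_empty_inputs_rejected(self, structure_map):
        with pytest.raises(ValueError):
            best_alignment([], [structure_map > 0])


class TestApplyWarp:
    def test_identity_warp_is_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (30, 30, 3), dtype=np.uint8)
        assert np.array_equal(apply_warp(img, np.eye(3)), img)

    def test_warp_then_inverse_recovers_image(self):
        # smooth image: interpolation error scales with curvature
        yy, xx = np.mgrid[0:60, 0:60]
        smooth = 255.0 * np.exp(-((xx - 30) ** 2 + (yy - 25) ** 2) / (2 * 12.0**2))
        img = smooth.astype(np.uint8)
        rng = np.random.default_rng(3)
        T, _ = _planted_homography(60, 60, 0.03, rng)
        once = apply_warp(img, T)
        back = apply_warp(once, np.linalg.inv(T))
        interior = np.s_[6:-6, 6:-6]
        assert np.abs(back[interior].astype(float) - img[interior].astype(float)).mean() < 2.0

    def test_singular_warp_rejected(self):
        bad = np.zeros((3, 3))
        with pytest.raises(ValueError):
            apply_warp(np.zeros((8, 8)), bad)
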