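"""Rasterizer tests: blending semantics, tiled/untiled equivalence,
single-splat closed forms, EWA consistency and anti-aliasing."""

import numpy as np
import pytest

from endosplat.scene import Camera, GaussianCloud, InvalidParameterError
from endosplat.projection import Splat2D, apply_low_pass_filter
from endosplat.rasterizer import (alpha_blend_pixel, make_splats, render,
                                  render_bruteforce,
                                  render_supersampled_reference, sort_and_bin,
                                  render_training)
from endosplat.experiments import random_cloud, tiled_vs_bruteforce
from endosplat._kernels import STOP_T


def _splat(uv, depth, color, opacity, cov=None, pf=1.0):
    return Splat2D(uv=np.asarray(uv, float),
                   cov2d=np.eye(2) if cov is None else np.asarray(cov, float),
                   depth=depth, color=np.asarray(color, float),
                   opacity=opacity, filter_prefactor=pf)


class TestSortAndBin:
    def test_depth_ordering_in_shared_tiles(self):
        s = [_splat([8, 8], 2.0, [1, 0, 0], 0.5),
             _splat([8, 8], 1.0, [0, 1, 0], 0.5)]
        grid = sort_and_bin(s, (16, 16), tile=16)
        assert grid[0][0] == [1, 0]

    def test_small_splat_in_exactly_one_tile(self):
        s = [_splat([8, 8], 1.0, [1, 1, 1], 0.5, cov=0.25 * np.eye(2))]
        grid = sort_and_bin(s, (32, 32), tile=16)
        counts = sum(len(grid[i][j]) for i in range(2) for j in range(2))
        assert counts == 1 and grid[0][0] == [0]

    def test_matches_bruteforce_overlap_oracle(self):
        rng = np.random.default_rng(5)
        splats = []
        for _ in range(200):
            L = rng.normal(0, 2, (2, 2))
            cov = L @ L.T + 0.1 * np.eye(2)
            splats.append(_splat(rng.uniform(-10, 74, 2), rng.uniform(0.5, 5),
                                 [1, 1, 1], 0.5, cov=cov))
        tile = 16
        H = W = 64
        grid = sort_and_bin(splats, (H, W), tile=tile)
        from endosplat.projection import splat_extent
        for ty in range((H + tile - 1) // tile):
            for tx in range((W + tile - 1) // tile):
                x0, x1 = tx * tile, (tx + 1) * tile
                y0, y1 = ty * tile, (ty + 1) * tile
                expected = [i for i in sorted(
                    range(200), key=lambda i: (splats[i].depth, i))
                    if (splats[i].uv[0] + splat_extent(splats[i].cov2d) >= x0
                        and splats[i].uv[0] - splat_extent(splats[i].cov2d) < x1
                        and splats[i].uv[1] + splat_extent(splats[i].cov2d) >= y0
                        and splats[i].uv[1] - splat_extent(splats[i].cov2d) < y1)]
                assert grid[ty][tx] == expected


class TestAlphaBlendPixel:
    def test_single_splat_at_pixel(self):
        # one splat exactly at p, exponent 0: pixel = 0.8 c + 0.2 bg
        c = np.array([0.9, 0.5, 0.1])
        bg = np.array([0.0, 0.2, 0.4])
        rgb = alpha_blend_pixel([4.5, 4.5],
                                [_splat([4.5, 4.5], 1.0, c, 0.8)], bg)
        np.testing.assert_allclose(rgb, 0.8 * c + 0.2 * bg, rtol=1e-12)

    def test_two_half_transparent_white_splats(self):
        s = [_splat([2.5, 2.5], 1.0, [1, 1, 1], 0.5),
             _splat([2.5, 2.5], 2.0, [1, 1, 1], 0.5)]
        rgb = alpha_blend_pixel([2.5, 2.5], s)
        np.testing.assert_allclose(rgb, 0.75, rtol=1e-12)

    def test_alpha_cap_limits_back_contribution(self):
        # front splat requests alpha 1.0, capped at 0.99
        s = [_splat([2.5, 2.5], 1.0, [0, 0, 0], 1.0 - 1e-12),
             _splat([2.5, 2.5], 2.0, [1, 1, 1], 1.0 - 1e-12)]
        rgb = alpha_blend_pixel([2.5, 2.5], s)
        assert np.all(rgb <= 0.01 + 1e-9)
        assert np.all(rgb > 0)

    def test_weight_conservation_and_monotone_transmittance(self):
        rng = np.random.default_rng(2)
        splats = [_splat(rng.uniform(0, 5, 2), d, rng.uniform(0, 1, 3),
                         rng.uniform(0.1, 0.9),
                         cov=np.eye(2) * rng.uniform(0.5, 4))
                  for d in sorted(rng.uniform(0.5, 5, 30))]
        rgb, weights, T = alpha_blend_pixel([2.5, 2.5], splats,
                                            return_details=True)
        assert abs(weights.sum() + T - 1.0) < 1e-12
        # transmittance non-increasing along the list
        trans = np.concatenate([[1.0], 1.0 - np.cumsum(weights) ])
        assert np.all(np.diff(trans) <= 1e-15)

    def test_nonpd_covariance_skipped_with_warning(self):
        bad = _splat([2.5, 2.5], 1.0, [1, 1, 1], 0.9,
                     cov=np.array([[1.0, 2.0], [2.0, 1.0]]))  # det < 0
        with pytest.warns(UserWarning):
            rgb = alpha_blend_pixel([2.5, 2.5], [bad], (0.3, 0.3, 0.3))
        np.testing.assert_allclose(rgb, 0.3)


class TestRender:
    def test_empty_cloud_is_background(self, small_camera):
        cloud = GaussianCloud(np.zeros((0, 3)), np.zeros((0, 4)),
                              np.zeros((0, 3)), np.zeros(0),
                              np.zeros((0, 1, 3)), sh_degree=0)
        out = render(cloud, small_camera, background=(0.1, 0.2, 0.3))
        np.testing.assert_allclose(
            out.pixels, np.broadcast_to([0.1, 0.2, 0.3], out.pixels.shape))
        np.testing.assert_array_equal(out.final_transmittance, 1.0)

    def test_single_splat_matches_closed_form(self, single_splat_cloud,
                                              small_camera):
        # analytic alpha-map oracle for one isotropic Gaussian
        s_filter = 0.3
        out = render(single_splat_cloud, small_camera,
                     filter_scale=s_filter, background=(0.0, 0.0, 0.0))
        act = single_splat_cloud.activated()
        z = act.means[0, 2]
        sigma2 = act.scales[0, 0] ** 2
        proj_var = (small_camera.fx ** 2 * sigma2) / z ** 2
        cov2d = proj_var * np.eye(2)
        filt, pf = apply_low_pass_filter(cov2d, s_filter)
        color = np.clip(act.sh_coeffs[0, 0] * 0.28209479177387814 + 0.5, 0, None)
        ys, xs = np.mgrid[0:64, 0:64]
        d2 = ((xs + 0.5 - 32.0) ** 2 + (ys + 0.5 - 32.0) ** 2) / filt[0, 0]
        alpha = np.where(d2 <= 9.0,
                         np.minimum(0.99,
                                    act.opacities[0] * pf * np.exp(-0.5 * d2)),
                         0.0)
        expected = alpha[:, :, None] * color
        assert np.abs(out.pixels - expected).max() < 1e-5

    def test_deterministic(self, small_cloud, small_camera):
        a = render(small_cloud, small_camera).pixels
        b = render(small_cloud, small_camera).pixels
        np.testing.assert_array_equal(a, b)

    def test_zero_size_camera_rejected(self, small_cloud):
        with pytest.raises(InvalidParameterError):
            Camera(fx=10, fy=10, cx=0, cy=0, width=0, height=5)

    def test_pixel_range_and_transmittance(self, small_cloud, small_camera):
        out = render(small_cloud, small_camera, background=(0.2, 0.2, 0.2))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        assert (out.final_transmittance.min() >= 0.0
                and out.final_transmittance.max() <= 1.0)

    def test_filter_limit_s_to_zero(self, small_cloud, small_camera):
        # as s -> 0 the filtered render converges to the unfiltered one
        base = render(small_cloud, small_camera, filter_scale=0.0).pixels
        near = render(small_cloud, small_camera, filter_scale=1e-8).pixels
        assert np.abs(base - near).max() < 1e-4

    def test_render_matches_pixel_oracle(self, small_cloud, small_camera):
        # cross-check the kernel against the pure-python splat list path
        out = render(small_cloud, small_camera, background=(0.1, 0.0, 0.3))
        splats = make_splats(small_cloud, small_camera)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = int(rng.integers(0, 64))
            j = int(rng.integers(0, 64))
            rgb = alpha_blend_pixel([j + 0.5, i + 0.5], splats, (0.1, 0.0, 0.3))
            np.testing.assert_allclose(out.pixels[i, j], np.clip(rgb, 0, 1),
                                       atol=1e-12)


class TestTiledVsBruteforce:
    def test_equivalence_on_random_scenes(self):
        res = tiled_vs_bruteforce(n_scenes=8, seed=42)
        assert res["max_diff_no_termination"] < 1e-5
        assert res["max_diff_all"] < STOP_T + 1e-5

    def test_empty_cloud(self, small_camera):
        cloud = GaussianCloud(np.zeros((0, 3)), np.zeros((0, 4)),
                              np.zeros((0, 3)), np.zeros(0),
                              np.zeros((0, 1, 3)), sh_degree=0)
        out = render_bruteforce(cloud, small_camera, background=(0.5, 0.5, 0.5))
        np.testing.assert_allclose(out.pixels, 0.5)

    def test_single_opaque_splat_matches_render(self, single_splat_cloud,
                                                small_camera):
        a = render(single_splat_cloud, small_camera).pixels
        b = render_bruteforce(single_splat_cloud, small_camera).pixels
        np.testing.assert_array_equal(a, b)


class TestEWAConsistency:
    def test_fitted_2d_gaussian_recovers_projection(self):
        # render one well-resolved splat and fit a 2D Gaussian to the image
        cloud = GaussianCloud(
            means=np.array([[0.05, -0.02, 2.0]]),
            rot_quats=np.array([[0.9, 0.1, -0.2, 0.3]]),
            log_scales=np.log([[0.20, 0.16, 0.18]]),  # >= 10 px projected std
            opacity_logits=np.array([2.0]),
            sh_coeffs=((np.array([[0.8, 0.8, 0.8]]) - 0.5)
                       / 0.28209479177387814)[:, None, :],
            sh_degree=0)
        cam = Camera(fx=120.0, fy=120.0, cx=64.0, cy=64.0, width=128,
                     height=128, znear=0.1)
        s_filter = 0.3
        out = render(cloud, cam, filter_scale=s_filter).pixels[:, :, 0]
        w = out / out.sum()
        ys, xs = np.mgrid[0:128, 0:128]
        xc = (xs + 0.5)
        yc = (ys + 0.5)
        mx = (w * xc).sum()
        my = (w * yc).sum()
        cxx = (w * (xc - mx) ** 2).sum()
        cyy = (w * (yc - my) ** 2).sum()
        cxy = (w * (xc - mx) * (yc - my)).sum()

        from endosplat.projection import project_gaussian
        act = cloud.activated()
        uv, cov2d, _ = project_gaussian(act.means[0], act.covariances()[0], cam)
        filt, _ = apply_low_pass_filter(cov2d, s_filter)
        assert np.hypot(*(np.array([mx, my]) - uv)) < 0.1
        fitted = np.array([[cxx, cxy], [cxy, cyy]])
        # the splat kernel is truncated at Mahalanobis radius 3; for an
        # elliptically truncated Gaussian each principal second moment is
        # shrunk by the closed-form factor below, which the oracle undoes
        shrink = 1.0 - 4.5 * np.exp(-4.5) / (1.0 - np.exp(-4.5))
        recovered = fitted / shrink
        assert np.abs(recovered - filt).max() / np.abs(filt).max() < 0.05


class TestSupersampledReference:
    def test_factor_one_equals_plain_render(self, small_cloud, small_camera):
        a = render_supersampled_reference(small_cloud, small_camera,
                                          filter_scale=0.0, factor=1).pixels
        b = render(small_cloud, small_camera, filter_scale=0.0).pixels
        np.testing.assert_array_equal(a, b)

    def test_constant_scene_stays_constant(self, small_camera):
        cloud = GaussianCloud(np.zeros((0, 3)), np.zeros((0, 4)),
                              np.zeros((0, 3)), np.zeros(0),
                              np.zeros((0, 1, 3)), sh_degree=0)
        out = render_supersampled_reference(cloud, small_camera, factor=4,
                                            background=(0.3, 0.6, 0.9))
        np.testing.assert_allclose(
            out.pixels, np.broadcast_to([0.3, 0.6, 0.9], out.pixels.shape))


class TestTransmittanceConservation:
    def test_blend_weights_plus_final_transmittance(self, small_cloud,
                                                    small_camera):
        # per-pixel: sum of blend weights + final T = 1
        out, ctx = render_training(small_cloud, small_camera,
                                   background=(0.0, 0.0, 0.0))
        splats = make_splats(small_cloud, small_camera)
        rng = np.random.default_rng(3)
        for _ in range(30):
            i = int(rng.integers(0, 64))
            j = int(rng.integers(0, 64))
            _, weights, T = alpha_blend_pixel([j + 0.5, i + 0.5], splats,
                                              return_details=True)
            assert abs(weights.sum() + T - 1.0) < 1e-12
            np.testing.assert_allclose(ctx["trans"][i, j], T, atol=1e-12)
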