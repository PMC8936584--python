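"""Spatial transformer: grids, sampler, theta derivation, inverse remap."""

import numpy as np
import pytest

from tanet import nn
from tanet.nn import Tensor
from tanet.stn import (AffineTheta, LocalizationNet, MissingRegionError,
                       ThetaSet, bilinear_sample, coarse_to_input,
                       inverse_remap, make_sampling_grid,
                       sample_labels_nearest, theta_gt_from_mask)

from _utils import numeric_grad

rng = np.random.default_rng(11)

IDENTITY = AffineTheta(1.0, 1.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# grid generator

class TestSamplingGrid:
    def test_identity_theta_gives_target_grid(self):
        g = make_sampling_grid(IDENTITY, 5, 7)
        xt = np.linspace(-1, 1, 7)
        yt = np.linspace(-1, 1, 5)
        assert np.allclose(g.source_coords[..., 0], xt[None, :])
        assert np.allclose(g.source_coords[..., 1], yt[:, None])

    def test_pure_translation_shifts_x_only(self):
        g0 = make_sampling_grid(IDENTITY, 4, 4).source_coords
        g1 = make_sampling_grid(AffineTheta(1, 1, 0.5, 0), 4, 4).source_coords
        assert np.allclose(g1[..., 0] - g0[..., 0], 0.5)
        assert np.allclose(g1[..., 1], g0[..., 1])

    def test_matches_per_point_matrix_multiply_oracle(self):
        theta = AffineTheta(*rng.uniform(-1, 1, 4))
        g = make_sampling_grid(theta, 7, 5).source_coords
        m = theta.matrix()
        xt = np.linspace(-1, 1, 5)
        yt = np.linspace(-1, 1, 7)
        for i in range(7):
            for j in range(5):
                expect = m @ np.array([xt[j], yt[i], 1.0])
                assert np.abs(g[i, j] - expect).max() <= 1e-12

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ValueError):
            AffineTheta(np.nan, 1, 0, 0)


# ---------------------------------------------------------------------------
# bilinear sampler

def _naive_bilinear(image, coords):
    """Direct truncated-kernel double loop: the sampler's defining sum."""
    C, H, W = image.shape
    Ho, Wo = coords.shape[:2]
    out = np.zeros((C, Ho, Wo))
    for i in range(Ho):
        for j in range(Wo):
            xs = (coords[i, j, 0] + 1) / 2 * (W - 1)
            ys = (coords[i, j, 1] + 1) / 2 * (H - 1)
            for n in range(H):
                for m in range(W):
                    w = max(0, 1 - abs(xs - m)) * max(0, 1 - abs(ys - n))
                    if w:
                        out[:, i, j] += image[:, n, m] * w
    return out


class TestBilinearSampler:
    def test_identity_grid_reproduces_input_exactly(self):
        img = rng.random((2, 6, 6))
        crop = bilinear_sample(img, make_sampling_grid(IDENTITY, 6, 6))
        assert np.array_equal(crop.values, img)

    def test_matches_bruteforce_kernel_sum(self):
        img = rng.random((1, 8, 8))
        theta = AffineTheta(*(rng.uniform(0.3, 1.0, 2).tolist()
                              + rng.uniform(-0.5, 0.5, 2).tolist()))
        grid = make_sampling_grid(theta, 8, 8)
        got = bilinear_sample(img, grid).values
        want = _naive_bilinear(img, grid.source_coords)
        assert np.abs(got - want).max() <= 1e-6

    def test_grid_fully_outside_gives_zeros(self):
        img = rng.random((1, 5, 5))
        grid = make_sampling_grid(AffineTheta(1, 1, 5.0, 5.0), 4, 4)
        assert np.all(bilinear_sample(img, grid).values == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linearity_in_the_input(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.random((1, 6, 6)), r.random((1, 6, 6))
        a, b = r.uniform(-2, 2, 2)
        grid = make_sampling_grid(AffineTheta(0.7, 0.8, 0.1, -0.2), 5, 5)
        lhs = bilinear_sample(a * x + b * y, grid).values
        rhs = (a * bilinear_sample(x, grid).values
               + b * bilinear_sample(y, grid).values)
        assert np.abs(lhs - rhs).max() < 1e-12

    def test_unit_interval_preserved(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            img = r.random((1, 7, 7))
            theta = AffineTheta(*(r.uniform(0.2, 1.4, 2).tolist()
                                  + r.uniform(-1, 1, 2).tolist()))
            out = bilinear_sample(img, make_sampling_grid(theta, 6, 6)).values
            assert out.min() >= -1e-12 and out.max() <= 1 + 1e-12

    def test_channel_mismatch_rejected(self):
        img = Tensor(rng.random((1, 2, 5, 5)))
        bad_grid = Tensor(rng.random((2, 4, 4, 2)))
        with pytest.raises(ValueError):
            nn.grid_sample(img, bad_grid)

    def test_theta_gradient_matches_finite_differences(self):
        img = Tensor(rng.standard_normal((1, 1, 8, 8)))
        c = Tensor(rng.standard_normal((1, 1, 6, 6)))
        theta = Tensor(np.array([[0.71237, 0.6123, 0.1117, -0.0713]]),
                       requires_grad=True)

        def f(th=theta):
            return nn.tsum(nn.mul(nn.grid_sample(img, nn.affine_grid(th, 6, 6)), c))

        f().backward()
        analytic = theta.grad.copy()
        numeric = numeric_grad(f, theta)
        assert np.abs(analytic - numeric).max() <= 1e-4


# ---------------------------------------------------------------------------
# ground-truth theta

class TestThetaGT:
    def test_full_frame_region_is_identity(self):
        mask = np.ones((16, 16), dtype=int)
        t = theta_gt_from_mask(mask, 1, margin=0.0)
        assert t.as_vector() == pytest.approx([1, 1, 0, 0], abs=1e-12)

    def test_left_half_rectangle(self):
        W = 64
        mask = np.zeros((W, W), dtype=int)
        mask[:, : W // 2] = 1
        t = theta_gt_from_mask(mask, 1, margin=0.0)
        tol = 2.0 / (W - 1)  # pixel-centre convention: exact to one pixel
        assert t.s_x == pytest.approx(0.5, abs=tol)
        assert t.s_y == pytest.approx(1.0, abs=tol)
        assert t.t_x == pytest.approx(-0.5, abs=tol)
        assert t.t_y == pytest.approx(0.0, abs=tol)
        # functional check: the crop contains exactly the rectangle
        crop = bilinear_sample(mask[None].astype(float),
                               make_sampling_grid(t, W, W)).values
        assert crop.min() > 0.99

    def test_margin_grows_the_crop(self):
        mask = np.zeros((32, 32), dtype=int)
        mask[10:20, 8:25] = 1
        t0 = theta_gt_from_mask(mask, 1, margin=0.0)
        t1 = theta_gt_from_mask(mask, 1, margin=0.1)
        crop0 = sample_labels_nearest(mask, t0, 32, 32)
        crop1 = sample_labels_nearest(mask, t1, 32, 32)
        assert crop1.sum() * (t1.s_x * t1.s_y) >= crop0.sum() * (t0.s_x * t0.s_y) - 1e-9
        assert t1.s_x > t0.s_x and t1.s_y > t0.s_y

    def test_crop_concentrates_the_region(self):
        mask = np.zeros((40, 40), dtype=int)
        mask[5:15, 20:33] = 2
        t = theta_gt_from_mask(mask, 2, margin=0.1)
        crop = sample_labels_nearest(mask, t, 40, 40)
        assert (crop == 2).mean() >= (mask == 2).mean()
        assert 0 < t.s_x <= 1 and 0 < t.s_y <= 1

    def test_absent_region_raises(self):
        with pytest.raises(MissingRegionError):
            theta_gt_from_mask(np.zeros((8, 8), dtype=int), 3)


# ---------------------------------------------------------------------------
# inverse remap

class TestInverseRemap:
    def test_identity_round_trip(self):
        crop = rng.integers(0, 2, (12, 12))
        thetas = ThetaSet([IDENTITY], [1])
        out = inverse_remap([crop], thetas, 12, 12)
        assert np.array_equal(out, crop * 1)

    def test_crop_then_remap_recovers_blob(self):
        mask = np.zeros((128, 128), dtype=int)
        yy, xx = np.mgrid[:128, :128]
        mask[((yy - 70) / 25) ** 2 + ((xx - 50) / 18) ** 2 <= 1] = 1
        t = theta_gt_from_mask(mask, 1, margin=0.1)
        crop = sample_labels_nearest(mask, t, 128, 128)
        back = inverse_remap([crop], ThetaSet([t], [1]), 128, 128)
        inter = ((back == 1) & (mask == 1)).sum()
        union = ((back == 1) | (mask == 1)).sum()
        assert inter / union >= 0.98

    def test_disjoint_crops_union(self):
        left = np.zeros((8, 8), dtype=int)
        left[:, :4] = 1
        right = np.zeros((8, 8), dtype=int)
        right[:, 4:] = 2
        out = inverse_remap([left, right], ThetaSet([IDENTITY, IDENTITY], [1, 2]), 8, 8)
        assert np.array_equal(out, left + right)

    def test_singular_theta_rejected(self):
        with pytest.raises(ValueError):
            inverse_remap([np.ones((4, 4), dtype=int)],
                          ThetaSet([AffineTheta(0.0, 1.0, 0, 0)], [1]), 4, 4)

    def test_conflict_goes_to_nearest_crop_centre(self):
        # both regions claim the whole frame; region 2's transform centres
        # the frame in its crop, so region 2 wins everywhere except where
        # region 1 is closer to its own centre
        full1 = np.ones((16, 16), dtype=int)
        full2 = np.full((16, 16), 2)
        t1 = AffineTheta(1.0, 1.0, 0.9, 0.9)   # frame far from crop centre
        t2 = IDENTITY                            # frame centred in crop
        out = inverse_remap([full1, full2], ThetaSet([t1, t2], [1, 2]), 16, 16)
        centre = out[6:10, 6:10]
        assert np.all(centre == 2)


# ---------------------------------------------------------------------------
# localization network

class TestLocalizationNet:
    @pytest.mark.parametrize("n_regions", [1, 5])
    def test_theta_set_length_matches_configuration(self, n_regions):
        net = LocalizationNet(n_regions)
        labels = np.zeros((64, 64), dtype=int)
        labels[20:40, 20:40] = 1
        ts = net.predict_theta(labels)
        assert len(ts) == n_regions
        assert ts.stack().shape == (n_regions, 2, 3)

    def test_untrained_predicts_finite_near_identity_zero_shear(self):
        net = LocalizationNet(2, rng=np.random.default_rng(3))
        labels = np.zeros((64, 64), dtype=int)
        labels[5:30, 5:30] = 1
        labels[40:60, 40:60] = 2
        stack = net.predict_theta(labels).stack()
        assert np.all(np.isfinite(stack))
        assert np.all(stack[:, 0, 1] == 0) and np.all(stack[:, 1, 0] == 0)
        ident = np.array([[1, 0, 0], [0, 1, 0]], dtype=float)
        assert np.abs(stack - ident).max() < 0.05

    def test_region_count_mismatch_is_config_error(self):
        net = LocalizationNet(3)
        z = coarse_to_input(np.zeros((64, 64), dtype=int), 1)
        with pytest.raises(ValueError):
            net(Tensor(z[None].astype(np.float32)))

    def test_scales_clamped_into_valid_range(self):
        net = LocalizationNet(1, scale_clip=(0.05, 1.5))
        net.head.bias.data[:] = np.array([9.0, -9.0, 0.0, 0.0], dtype=np.float32)
        z = coarse_to_input(np.zeros((64, 64), dtype=int), 1)
        theta = net(Tensor(z[None].astype(np.float32))).data[0, 0]
        assert theta[0] <= 1.5 and theta[1] >= 0.05


def test_theta_set_validation():
    with pytest.raises(ValueError):
        ThetaSet([IDENTITY, IDENTITY], [2, 1])     # unsorted
    with pytest.raises(ValueError):
        ThetaSet([IDENTITY], [0])                  # non-positive id
    with pytest.raises(ValueError):
        ThetaSet([IDENTITY, IDENTITY], [1, 1])     # duplicate
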