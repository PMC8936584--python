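"""Pathways: spatial, LBP-encoded handcrafted, context, fusion, head."""

import numpy as np
import pytest

from tanet import nn
from tanet.nn import Tensor
from tanet.pathways import (ContextPath, FusionModule, HandcraftedPath,
                            LBCBlockSpec, SegmentationHead, SpatialPath,
                            count_learnable_params, lbc_block_forward,
                            make_anchors, make_lbc_spec, reweight)

rng = np.random.default_rng(77)


# ---------------------------------------------------------------------------
# parameter counting

class TestParamCounts:
    @pytest.mark.parametrize("k", [1, 3, 5, 7, 9, 11, 13])
    def test_ratio_is_k_squared_when_m_equals_cin(self, k):
        q = 16
        std = count_learnable_params("standard", k, q, q)
        lbc = count_learnable_params("lbc", k, q, q, m=q)
        assert std // lbc == k * k and std % lbc == 0

    def test_formulas(self):
        assert count_learnable_params("standard", 3, 4, 8) == 9 * 4 * 8
        assert count_learnable_params("lbc", 3, 4, 8, m=6) == 6 * 8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            count_learnable_params("standard", 2, 4, 4)
        with pytest.raises(ValueError):
            count_learnable_params("gabor", 3, 4, 4)

    def test_spatial_path_matches_closed_form(self):
        sp = SpatialPath(1, (64, 64, 128))
        total = sum(p.size for p in sp.parameters())
        expect = 0
        for c_in, c_out in ((1, 64), (64, 64), (64, 128)):
            expect += 9 * c_in * c_out + 2 * c_out  # conv (no bias) + BN
        assert total == expect

    def test_handcrafted_path_learns_fewer_params_than_spatial(self):
        hp = HandcraftedPath(1, (64, 64, 128))
        sp = SpatialPath(1, (64, 64, 128))
        assert (sum(p.size for p in hp.parameters())
                < sum(p.size for p in sp.parameters()))


# ---------------------------------------------------------------------------
# LBC blocks

class TestLBC:
    def test_anchor_sparsity_and_signs(self):
        for sparsity in (0.2, 0.5, 0.9):
            anchors = make_anchors(6, 3, 3, sparsity, np.random.default_rng(1))
            want = int(np.ceil(sparsity * 9 * 3))
            for a in anchors:
                nz = a[a != 0]
                assert nz.size == want
                assert set(np.unique(nz)) <= {-1.0, 1.0}

    def test_zero_recombination_gives_zero_output(self):
        spec = make_lbc_spec(2, 5, rng=np.random.default_rng(2))
        spec.recombination[:] = 0.0
        x = rng.random((1, 2, 8, 8))
        assert np.all(lbc_block_forward(x, spec) == 0)

    def test_identity_anchor_passthrough(self):
        anchors = np.zeros((1, 1, 3, 3), dtype=np.float32)
        anchors[0, 0, 1, 1] = 1.0
        spec = LBCBlockSpec(m=1, kernel_size=3, sparsity=1 / 9, anchors=anchors,
                            recombination=np.ones((1, 1), dtype=np.float32))
        x = rng.random((1, 1, 6, 6))  # non-negative: ReLU passes through
        out = lbc_block_forward(x, spec)
        assert np.allclose(out[0, 0], x[0, 0], atol=1e-6)

    def test_matches_two_step_oracle(self):
        spec = make_lbc_spec(2, 3, rng=np.random.default_rng(4))
        x = rng.standard_normal((1, 2, 6, 6))
        got = lbc_block_forward(x, spec)
        # oracle: explicit correlation loop, ReLU, weighted channel sum
        xp = np.pad(x[0], ((0, 0), (1, 1), (1, 1)))
        maps = np.zeros((spec.m, 6, 6))
        for f in range(spec.m):
            for i in range(6):
                for j in range(6):
                    maps[f, i, j] = (spec.anchors[f] * xp[:, i:i + 3, j:j + 3]).sum()
        maps = np.maximum(maps, 0)
        want = np.einsum("om,mij->oij", spec.recombination, maps)
        assert np.abs(got[0] - want).max() <= 1e-5

    def test_channel_mismatch_rejected(self):
        spec = make_lbc_spec(2, 3, rng=np.random.default_rng(5))
        with pytest.raises(ValueError):
            lbc_block_forward(rng.random((1, 3, 6, 6)), spec)

    def test_anchors_frozen_through_an_optimizer_step(self):
        hp = HandcraftedPath(1, (8, 8, 16), anchor_seed=1)
        before = [b.anchors.data.copy() for b in hp.blocks]
        opt = nn.Adam(hp.parameters(), lr=1e-2)
        x = Tensor(rng.random((2, 1, 16, 16)).astype(np.float32))
        loss = nn.tsum(nn.mul(hp(x), hp(x)))
        opt.zero_grad()
        loss.backward()
        opt.step()
        for b, a0 in zip(hp.blocks, before):
            assert np.array_equal(b.anchors.data, a0)  # bitwise

    def test_gradient_flows_through_anchors_to_input(self):
        hp = HandcraftedPath(1, (8, 8, 16), anchor_seed=2)
        x = Tensor(rng.random((1, 1, 16, 16)).astype(np.float32),
                   requires_grad=True)
        nn.tsum(hp(x)).backward()
        assert x.grad is not None and np.any(x.grad != 0)


# ---------------------------------------------------------------------------
# pathway geometry

class TestPathwayShapes:
    @pytest.mark.parametrize("size,out", [(128, 16), (64, 8)])
    def test_spatial_path_is_one_eighth(self, size, out):
        sp = SpatialPath(1)
        y = sp(Tensor(rng.random((1, 1, size, size)).astype(np.float32)))
        assert y.shape == (1, 128, out, out)

    def test_spatial_path_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            SpatialPath(1)(Tensor(np.zeros((1, 1, 20, 20), dtype=np.float32)))

    def test_handcrafted_path_mirrors_spatial_resolution(self):
        hp = HandcraftedPath(1)
        y = hp(Tensor(rng.random((1, 1, 128, 128)).astype(np.float32)))
        assert y.shape == (1, 128, 16, 16)

    def test_context_path_contract(self):
        cp = ContextPath(n_classes=6)
        x = Tensor(rng.random((2, 1, 64, 64)).astype(np.float32))
        ctx, aux1, aux2 = cp(x)
        assert ctx.shape == (2, cp.out_channels, 8, 8)   # matches SP dims
        assert aux1.shape == (2, 6, 4, 4)                # 1/16 tap
        assert aux2.shape == (2, 6, 2, 2)                # 1/32 tap
        with pytest.raises(ValueError):
            cp(Tensor(np.zeros((1, 1, 48, 48), dtype=np.float32)))

    def test_context_map_constant_for_constant_input(self):
        # a constant image gives a constant interior context map; only the
        # zero-padding boundary (receptive field ~63 px) may deviate
        cp = ContextPath(n_classes=2, rng=np.random.default_rng(8)).eval()
        x = Tensor(np.full((1, 1, 256, 256), 0.5, dtype=np.float32))
        ctx, _, _ = cp(x)
        interior = ctx.data[0, :, 12:20, 12:20]
        spread = interior.max(axis=(1, 2)) - interior.min(axis=(1, 2))
        scale = np.abs(interior).max() + 1e-6
        assert spread.max() / scale < 0.05


# ---------------------------------------------------------------------------
# fusion and head

class TestFusion:
    def _maps(self, b=2, s=8):
        return (Tensor(rng.random((b, 16, s, s)).astype(np.float32)),
                Tensor(rng.random((b, 16, s, s)).astype(np.float32)),
                Tensor(rng.random((b, 8, s, s)).astype(np.float32)))

    def test_forced_weights_zero_and_one(self):
        v = Tensor(rng.random((1, 4, 3, 3)))
        assert np.allclose(reweight(v, Tensor(np.zeros((1, 4, 1, 1)))).data, v.data)
        assert np.allclose(reweight(v, Tensor(np.ones((1, 4, 1, 1)))).data, 2 * v.data)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_bounded_between_v_and_2v(self, seed):
        fm = FusionModule((16, 16, 8), rng=np.random.default_rng(seed))
        fm.eval()
        sp, hp, cp = self._maps()
        out, w = fm(sp, hp, cp)
        v = fm.bn(nn.concat([sp, hp, cp], axis=1)).data
        nonneg = np.maximum(v, 0)  # bound holds where v_concat >= 0
        m = v >= 0
        assert np.all(out.data[m] >= nonneg[m] - 1e-5)
        assert np.all(out.data[m] <= 2 * nonneg[m] + 1e-5)
        assert np.all((w.data > 0) & (w.data < 1))

    def test_spatial_mismatch_rejected(self):
        fm = FusionModule((16, 16, 8))
        sp, hp, cp = self._maps()
        bad = Tensor(rng.random((2, 8, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError):
            fm(sp, hp, bad)

    def test_deterministic_given_fixed_weights(self):
        fm = FusionModule((16, 16, 8), rng=np.random.default_rng(3)).eval()
        sp, hp, cp = self._maps()
        a, _ = fm(sp, hp, cp)
        b, _ = fm(sp, hp, cp)
        assert np.array_equal(a.data, b.data)


class TestHead:
    def test_shape_and_range(self):
        head = SegmentationHead(256, 2)
        x = Tensor(rng.random((1, 256, 16, 16)).astype(np.float32))
        logits = head(x, 128)
        assert logits.shape == (1, 2, 128, 128)
        assert set(np.unique(logits.data.argmax(axis=1))) <= {0, 1}

    def test_class_count_appears_only_in_head_downstream_of_fusion(self):
        # two heads over the same fusion trunk differ only in the projection
        fm2 = FusionModule((16, 16, 8), rng=np.random.default_rng(0))
        fm6 = FusionModule((16, 16, 8), rng=np.random.default_rng(0))
        shapes2 = [p.shape for p in fm2.parameters()]
        shapes6 = [p.shape for p in fm6.parameters()]
        assert shapes2 == shapes6  # fusion is class-count independent
        h2 = SegmentationHead(fm2.out_channels, 2)
        h6 = SegmentationHead(fm6.out_channels, 6)
        assert h2.proj.weight.shape != h6.proj.weight.shape

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            SegmentationHead(8, 1)
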