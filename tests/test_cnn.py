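"""Dense U-Net components: cropping arithmetic, seeded construction, the
composite loss against hand calculations, gradient correctness, and the
training-sample schedule."""

import numpy as np
import pytest

from flowunwrap import nn
from flowunwrap.aliasing import WrapSpec, wrap_velocity
from flowunwrap.cnn import (
    CnnConfig,
    build_model,
    center_crop,
    composite_loss,
    load_model,
    predict,
    save_model,
    uncrop,
    _loss_and_grad,
)
from flowunwrap.phantom import PhantomSpec, generate_phantom


class TestCenterCrop:
    @pytest.mark.parametrize(
        "in_shape, crop, out_shape, offsets, pad",
        [
            ((160, 120, 30), (128, 96), (128, 96, 30), (16, 12), (0, 0)),
            ((128, 96, 22), (128, 96), (128, 96, 22), (0, 0), (0, 0)),
            ((100, 80, 25), (128, 96), (128, 96, 25), (0, 0), (14, 8)),
            ((130, 90, 10), (128, 96), (128, 96, 10), (1, 0), (0, 3)),
        ],
    )
    def test_shapes_offsets_and_padding(self, in_shape, crop, out_shape, offsets, pad):
        vol = np.random.default_rng(0).normal(size=in_shape)
        out, info = center_crop(vol, crop)
        assert out.shape == out_shape
        assert info.offsets == offsets
        assert info.pad == pad

    def test_uncrop_inverts_exactly(self):
        rng = np.random.default_rng(1)
        for in_shape in [(160, 120, 5), (100, 80, 5), (100, 120, 5)]:
            vol = rng.normal(size=in_shape)
            out, info = center_crop(vol, (128, 96))
            back = uncrop(out, info)
            assert back.shape == vol.shape
            # the crop-retained region is restored exactly; removed regions are 0
            ox, oy = info.offsets
            nx = min(in_shape[0], 128)
            ny = min(in_shape[1], 96)
            np.testing.assert_array_equal(back[ox : ox + nx, oy : oy + ny], vol[ox : ox + nx, oy : oy + ny])


class TestModelConstruction:
    def test_seeded_builds_are_identical(self):
        cfg = CnnConfig.tiny(seed=7)
        assert build_model(cfg).checksum() == build_model(cfg).checksum()

    def test_different_seeds_differ(self):
        assert (
            build_model(CnnConfig.tiny(seed=1)).checksum()
            != build_model(CnnConfig.tiny(seed=2)).checksum()
        )

    def test_forward_is_voxelwise_softmax_normalized(self):
        m = build_model(CnnConfig.tiny(seed=0))
        logits = m.forward(np.zeros((48, 32, 6)))
        assert logits.shape == (48, 32, 6, 2)
        p = nn.softmax(logits)
        np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-6)

    def test_growth_rate_increases_parameter_count(self):
        n = [
            build_model(CnnConfig.tiny(growth=g, seed=0)).num_parameters()
            for g in (2, 4, 8)
        ]
        assert n[0] < n[1] < n[2]

    def test_crop_divisibility_enforced(self):
        with pytest.raises(ValueError):
            CnnConfig(crop_xy=(130, 96), levels=4)

    def test_untrained_model_predicts_background(self):
        m = build_model(CnnConfig.tiny(seed=3))
        rng = np.random.default_rng(0)
        vol = rng.normal(0.0, 0.3, size=(48, 32, 5)).astype(np.float32)
        assert not m.predict_volume(vol).any()


class TestCompositeLoss:
    def test_perfect_prediction_limit(self):
        y = np.zeros((4, 4, 2), bool)
        y[1:3, 1:3, :] = True
        p = y.astype(float)
        assert composite_loss(p, y) == pytest.approx(0.0, abs=1e-6)

    def test_empty_truth_all_background_is_minimal(self):
        y = np.zeros((4, 4, 2), bool)
        base = composite_loss(np.zeros((4, 4, 2)), y)
        assert np.isfinite(base)
        rng = np.random.default_rng(0)
        for _ in range(10):
            other = rng.random((4, 4, 2))
            assert composite_loss(other, y) >= base - 1e-12

    def test_hand_computed_toy(self):
        # 2x2x1 volume: p1 = [[0.9, 0.2], [0.6, 0.1]], truth = [[1, 0], [0, 0]]
        from flowunwrap.cnn import DICE_SMOOTH

        p = np.array([[0.9, 0.2], [0.6, 0.1]])[..., None]
        y = np.array([[True, False], [False, False]])[..., None]
        ce = -(np.log(0.9) + np.log(0.8) + np.log(0.4) + np.log(0.9)) / 4.0
        soft_dice = (2 * 0.9 + DICE_SMOOTH) / (1.8 + 1.0 + DICE_SMOOTH)
        assert composite_loss(p, y) == pytest.approx(ce + 1.0 - soft_dice, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=(3, 3, 2, 2)).astype(np.float64)
        y = rng.random((3, 3, 2)) < 0.4
        ce, dl, dlogits, _ = _loss_and_grad(logits, y)
        eps = 1e-5
        for idx in [(0, 0, 0, 0), (1, 2, 1, 1), (2, 1, 0, 1)]:
            up = logits.copy()
            up[idx] += eps
            dn = logits.copy()
            dn[idx] -= eps
            num = (sum(_loss_and_grad(up, y)[:2]) - sum(_loss_and_grad(dn, y)[:2])) / (2 * eps)
            assert dlogits[idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestTrainingSchedule:
    def test_samples_per_epoch_counting(self):
        # 2 phantoms x 4 wraps x 10 frames x 3 directions = 240 samples
        from flowunwrap.cnn import _volume_samples

        spec = PhantomSpec(grid_shape=(16, 16, 4), n_frames=10, vessel="straight",
                           vessel_radius=8.0, snr=np.inf, seed=0)
        field, _, _ = generate_phantom(spec)
        aliased, truth = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        per_wrap = sum(1 for _ in _volume_samples(aliased, truth, (16, 16)))
        assert per_wrap == 10 * 3
        assert 2 * 4 * per_wrap == 240

    def test_normalization_invariance_of_prediction(self):
        m = build_model(CnnConfig.tiny(seed=9))
        # give the head nonzero weights so predictions are nontrivial
        rng = np.random.default_rng(0)
        m.head.w.value[...] = rng.normal(0, 0.5, m.head.w.value.shape).astype(np.float32)
        spec = PhantomSpec(grid_shape=(48, 32, 6), n_frames=3, vessel="straight",
                           vessel_radius=10.0, snr=np.inf, seed=1)
        field, _, _ = generate_phantom(spec)
        aliased, _ = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        scaled = aliased.with_values(aliased.values * 2.0, venc=aliased.venc * 2.0)
        np.testing.assert_array_equal(predict(m, aliased), predict(m, scaled))

    def test_predict_mask_shape_matches_field(self):
        m = build_model(CnnConfig.tiny(seed=0))
        spec = PhantomSpec(grid_shape=(40, 28, 5), n_frames=2, vessel="straight",
                           vessel_radius=10.0, snr=np.inf, seed=2)
        field, _, _ = generate_phantom(spec)
        assert predict(m, field).shape == field.shape

    def test_empty_training_set_rejected(self):
        from flowunwrap.cnn import train

        m = build_model(CnnConfig.tiny(seed=0))
        with pytest.raises(ValueError):
            train(m, [])

    def test_checkpoint_round_trip(self, tmp_path):
        m = build_model(CnnConfig.tiny(seed=4))
        p = tmp_path / "w.npz"
        save_model(p, m)
        back = load_model(p)
        assert back.checksum() == m.checksum()
        assert back.config == m.config


class TestEngine:
    def test_conv_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv3d(2, 3, (3, 3, 3), rng)
        x = rng.normal(size=(5, 4, 3, 2)).astype(np.float32)
        out = conv.forward(x)
        # direct evaluation at an interior voxel
        i, j, k = 2, 2, 1
        patch = x[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2, :]
        expect = np.tensordot(patch, conv.w.value, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        np.testing.assert_allclose(out[i, j, k], expect + conv.b.value, rtol=1e-5)

    def test_pool_then_upsample_shapes(self):
        pool, up = nn.MaxPool2x2(), nn.Upsample2x2()
        x = np.random.default_rng(0).normal(size=(8, 6, 3, 2)).astype(np.float32)
        y = pool.forward(x, train=True)
        assert y.shape == (4, 3, 3, 2)
        z = up.forward(y)
        assert z.shape == x.shape
        # pooling gradient routes to exactly one voxel per window
        g = pool.backward(np.ones_like(y))
        assert g.sum() == y.size

    def test_dense_block_output_channels(self):
        rng = np.random.default_rng(0)
        blk = nn.DenseBlock(4, n_layers=3, growth=5, kernel=(3, 3, 1), dropout=0.0, rng=rng)
        x = rng.normal(size=(6, 6, 2, 4)).astype(np.float32)
        assert blk.forward(x).shape[-1] == 4 + 3 * 5 == blk.c_out

    def test_model_gradient_check_end_to_end(self):
        cfg = CnnConfig(crop_xy=(8, 8), levels=2, dense_layers=1, growth=2,
                        init_channels=2, width=3, dropout=0.0, seed=3)
        m = build_model(cfg)
        rng = np.random.default_rng(0)
        m.head.w.value[...] = rng.normal(0, 0.5, m.head.w.value.shape).astype(np.float32)
        x = rng.normal(size=(8, 8, 3)).astype(np.float32)
        y = rng.random((8, 8, 3)) < 0.3
        logits = m.forward(x, train=True)
        _, _, dlog, _ = _loss_and_grad(logits, y)
        m.backward(dlog)
        params = m.params()
        checked = 0
        for p in params[:4] + params[-4:]:
            flat = p.value.ravel()
            k = flat.size // 2
            eps, old = 1e-2, flat[k]
            flat[k] = old + eps
            l1 = sum(_loss_and_grad(m.forward(x), y)[:2])
            flat[k] = old - eps
            l2 = sum(_loss_and_grad(m.forward(x), y)[:2])
            flat[k] = old
            num = (l1 - l2) / (2 * eps)
            ana = p.grad.ravel()[k]
            assert ana == pytest.approx(num, rel=0.1, abs=2e-3)
            checked += 1
        assert checked == 8
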