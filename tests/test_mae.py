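"""Masked autoencoder: masking, reconstruction loss locality, transfer."""

import numpy as np
import pytest

from hemafuse import (BackboneConfig, MAEConfig, MaskedAutoencoder,
                      ViTClassifier, patchify, random_mask,
                      reconstruction_loss, render_reconstruction,
                      toy_backbone_config, transfer_weights)
from hemafuse.autodiff import Tensor


def _toy_mae(rng, **cfg_kw):
    cfg = toy_backbone_config(pos_embed="sincos", **cfg_kw)
    mae_cfg = MAEConfig(decoder_dim=32, decoder_depth=1, decoder_heads=4)
    return MaskedAutoencoder(cfg, mae_cfg, rng), cfg


class TestRandomMask:
    def test_default_ratio_on_base_grid(self, rng):
        plan = random_mask(196, 0.75, rng)
        assert plan.masked_idx.size == 147
        assert plan.visible_idx.size == 49

    def test_half_ratio_small_grid(self, rng):
        plan = random_mask(4, 0.5, rng)
        assert plan.masked_idx.size == 2 and plan.visible_idx.size == 2
        assert sorted(np.concatenate([plan.visible_idx, plan.masked_idx])) \
            == [0, 1, 2, 3]

    @pytest.mark.parametrize("ratio", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_ratios_rejected(self, rng, ratio):
        with pytest.raises(ValueError):
            random_mask(196, ratio, rng)

    def test_masking_is_uniform_over_positions(self, rng):
        n, draws, ratio = 196, 10_000, 0.75
        hits = np.zeros(n)
        for _ in range(draws):
            hits[random_mask(n, ratio, rng).masked_idx] += 1
        freq = hits / draws
        # 5-sigma binomial band around 0.75
        tol = 5 * np.sqrt(ratio * (1 - ratio) / draws)
        assert np.all(np.abs(freq - ratio) < tol)


class TestForwardAndLoss:
    def test_output_covers_all_patches(self, rng):
        mae, cfg = _toy_mae(rng)
        patches = patchify(rng.normal(size=(2, 32, 32, 3)), cfg.patch_size)
        for ratio in (0.25, 0.75):
            plan = random_mask(cfg.num_patches, ratio, rng)
            pred = mae(patches, plan)
            assert pred.shape == patches.shape

    def test_forward_deterministic_given_weights(self, rng):
        mae, cfg = _toy_mae(rng)
        patches = patchify(rng.normal(size=(1, 32, 32, 3)), cfg.patch_size)
        plan = random_mask(cfg.num_patches, 0.75, rng)
        a = mae(patches, plan).data
        b = mae(patches, plan).data
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_plan_mismatch_raises(self, rng):
        mae, cfg = _toy_mae(rng)
        patches = patchify(rng.normal(size=(1, 32, 32, 3)), cfg.patch_size)
        bad_plan = random_mask(99, 0.5, rng)
        with pytest.raises(ValueError):
            mae(patches, bad_plan)

    def test_loss_ignores_visible_patches(self, rng):
        n, p = 6, 12
        plan = random_mask(n, 0.5, rng)
        target = rng.normal(size=(1, n, p))
        pred = target.copy()
        pred[0, plan.visible_idx] = 999.0  # garbage where loss must not look
        assert reconstruction_loss(Tensor(pred), target, plan).item() == 0.0
        target2 = target.copy()
        target2[0, plan.visible_idx] += rng.normal(size=(plan.visible_idx.size, p))
        base = reconstruction_loss(Tensor(pred), target, plan).item()
        assert reconstruction_loss(Tensor(pred), target2, plan).item() == base

    def test_allones_error_on_single_masked_patch_gives_unit_mse(self):
        plan = random_mask(2, 0.5, np.random.default_rng(0))
        target = np.zeros((1, 2, 5))
        pred = target.copy()
        pred[0, plan.masked_idx] = 1.0
        assert reconstruction_loss(Tensor(pred), target, plan).item() \
            == pytest.approx(1.0)

    def test_loss_gradient_exactly_zero_at_visible_positions(self, rng):
        mae, cfg = _toy_mae(rng)
        n = cfg.num_patches
        plan = random_mask(n, 0.75, rng)
        pred = Tensor(rng.normal(size=(1, n, cfg.patch_dim)),
                      requires_grad=True)
        reconstruction_loss(pred, rng.normal(size=(1, n, cfg.patch_dim)),
                            plan).backward()
        assert np.all(pred.grad[0, plan.visible_idx] == 0.0)
        assert np.any(pred.grad[0, plan.masked_idx] != 0.0)

    def test_empty_mask_rejected(self, rng):
        plan = random_mask(4, 0.5, rng)
        plan.masked_idx = np.array([], dtype=int)
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((1, 4, 3)), np.zeros((1, 4, 3)), plan)


class TestTransfer:
    def test_encoder_outputs_identical_after_transfer(self, rng):
        mae, cfg = _toy_mae(rng)
        clf = ViTClassifier(cfg, 4, np.random.default_rng(123), fusion=True,
                            head="arcface")
        transfer_weights(mae.state_dict(), clf)
        img = rng.normal(size=(2, 32, 32, 3))
        ours = clf.encoder(img)
        theirs = mae.encoder(img)
        for a, b in zip(ours, theirs):
            assert np.allclose(a.data, b.data, atol=1e-5)

    def test_report_partitions_keys(self, rng):
        mae, cfg = _toy_mae(rng)
        clf = ViTClassifier(cfg, 4, rng, fusion=True, head="arcface")
        report = transfer_weights(mae.state_dict(), clf)
        assert all(k.startswith(("decoder", "mask_token"))
                   for k in report.ignored)
        assert any(k.startswith("encoder.blocks") for k in report.copied)
        assert any(k.startswith(("se.", "arcface.")) for k in report.initialized)
        assert not set(report.copied) & set(report.initialized)

    def test_depth_mismatch_raises_with_key_name(self, rng):
        mae, _ = _toy_mae(rng, depth=4)
        shallow_cfg = toy_backbone_config(depth=2, pos_embed="sincos")
        clf = ViTClassifier(shallow_cfg, 4, rng)
        with pytest.raises(KeyError, match="encoder.blocks"):
            transfer_weights(mae.state_dict(), clf)

    def test_width_mismatch_raises(self, rng):
        mae, _ = _toy_mae(rng)
        wide_cfg = toy_backbone_config(dim=64, heads=4, pos_embed="sincos")
        clf = ViTClassifier(wide_cfg, 4, rng)
        with pytest.raises(ValueError, match="shape mismatch"):
            transfer_weights(mae.state_dict(), clf)

    def test_cls_token_version_rejected_for_pretraining(self, rng):
        cfg = BackboneConfig(image_size=32, patch_size=8, depth=1, dim=32,
                             heads=4, use_cls_token=True)
        with pytest.raises(ValueError):
            MaskedAutoencoder(cfg, MAEConfig(), rng)


class TestRendering:
    def test_four_panel_composite_geometry(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        plan = random_mask(16, 0.75, rng)
        pred = rng.uniform(0, 255, size=(16, 8 * 8 * 3))
        panel = render_reconstruction(img, plan, pred, patch_size=8)
        assert panel.shape == (32, 4 * 32, 3)
        original, masked = panel[:, :32], panel[:, 32:64]
        paste = panel[:, 96:]
        assert np.array_equal(original, img)
        # masked panel: constant fill at masked patches
        gy, gx = divmod(int(plan.masked_idx[0]), 4)
        assert np.all(masked[gy * 8:(gy + 1) * 8, gx * 8:(gx + 1) * 8] == 127)
        # paste panel equals the original at visible patches
        gy, gx = divmod(int(plan.visible_idx[0]), 4)
        sl = np.s_[gy * 8:(gy + 1) * 8, gx * 8:(gx + 1) * 8]
        assert np.array_equal(paste[sl], img[sl])
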