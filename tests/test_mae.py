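"""Masking plans, schedule/EMA closed forms, encode/decode contracts,
gradient-accumulation equivalence, and a brief pretraining run."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budcall._nn import AdamW
from budcall.errors import ValidationError
from budcall.mae import (
    MaskedAutoencoder,
    ema_update,
    load_mae_checkpoint,
    lr_at_step,
    mae_decode,
    mae_encode,
    make_masking_plan,
    pretrain,
    reconstruction_loss,
    save_mae_checkpoint,
)
from conftest import tiny_mae_config


class TestMaskingPlan:
    def test_default_ratio_counts(self):
        plan = make_masking_plan(64, 0.75, seed=0)
        assert len(plan.masked_indices) == 48
        assert len(plan.visible_indices) == 16

    def test_deterministic_per_seed(self):
        assert make_masking_plan(64, 0.75, 3) == make_masking_plan(64, 0.75, 3)
        assert make_masking_plan(64, 0.75, 3) != make_masking_plan(64, 0.75, 4)

    @given(st.integers(4, 128), st.floats(0.1, 0.9), st.integers(0, 10 ** 6))
    @settings(max_examples=200, deadline=None)
    def test_partition_invariant_fuzz(self, n_tokens, ratio, seed):
        n_masked = int(round(ratio * n_tokens))
        if not 1 <= n_masked <= n_tokens - 1:
            return
        plan = make_masking_plan(n_tokens, ratio, seed)
        vis, mask = set(plan.visible_indices), set(plan.masked_indices)
        assert vis.isdisjoint(mask)
        assert vis | mask == set(range(n_tokens))
        assert len(mask) == n_masked

    def test_degenerate_ratio_raises(self):
        with pytest.raises(ValidationError):
            make_masking_plan(4, 0.01, 0)  # would mask zero tokens


class TestLrSchedule:
    def test_warmup_endpoints(self):
        assert lr_at_step(0, 1e-3, 10, 100) == 0.0
        assert lr_at_step(10, 1e-3, 10, 100) == pytest.approx(1e-3)

    def test_cosine_midpoint_closed_form(self):
        base = 2e-3
        lr = lr_at_step(10 + 50, base, 10, 100)
        assert lr == pytest.approx(base * 0.5 * (1 + math.cos(math.pi / 2)))
        assert lr == pytest.approx(base / 2)

    def test_restart_resets(self):
        base = 1e-3
        assert lr_at_step(10 + 100, base, 10, 100) == pytest.approx(base)
        # just before the restart the rate has almost fully decayed
        assert lr_at_step(10 + 99, base, 10, 100) < 0.01 * base

    def test_continuous_within_period(self):
        vals = [lr_at_step(s, 1.0, 5, 50) for s in range(5, 55)]
        diffs = np.abs(np.diff(vals))
        assert diffs.max() < 0.1  # smooth cosine, no jumps inside a period


class TestEma:
    def test_decay_extremes(self):
        shadow = {"w": np.ones(3)}
        live = {"w": np.full(3, 2.0)}
        assert ema_update(shadow, live, 1.0)["w"] == pytest.approx([1, 1, 1])
        assert ema_update(shadow, live, 0.0)["w"] == pytest.approx([2, 2, 2])
        assert ema_update({"w": np.zeros(1)}, {"w": np.full(1, 2.0)}, 0.5)[
            "w"
        ] == pytest.approx([1.0])

    def test_geometric_convergence_to_constant_live(self):
        rng = np.random.default_rng(0)
        shadow = {"w": rng.standard_normal(5)}
        live = {"w": rng.standard_normal(5)}
        decay = 0.9
        gaps = []
        for _ in range(20):
            shadow = ema_update(shadow, live, decay)
            gaps.append(np.linalg.norm(shadow["w"] - live["w"]))
        ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
        np.testing.assert_allclose(ratios, decay, atol=1e-10)


@pytest.fixture(scope="module")
def model():
    return MaskedAutoencoder(tiny_mae_config())


@pytest.fixture(scope="module")
def image():
    return np.random.default_rng(1).random((64, 64)).astype(np.float32)


class TestEncodeDecode:
    def test_encode_shape_one_latent_per_visible(self, model, image):
        plan = make_masking_plan(16, 0.75, 0)
        latents = mae_encode(model, image, plan)
        assert latents.shape == (4, 32)

    def test_encode_deterministic(self, model, image):
        plan = make_masking_plan(16, 0.75, 0)
        a = mae_encode(model, image, plan)
        b = mae_encode(model, image, plan)
        np.testing.assert_array_equal(a, b)

    def test_decode_full_image_shape(self, model, image):
        plan = make_masking_plan(16, 0.75, 0)
        recon = mae_decode(model, mae_encode(model, image, plan), plan)
        assert recon.shape == (64, 64)

    def test_nearly_all_masked_still_full_image(self, model, image):
        plan = make_masking_plan(16, 15 / 16, 0)  # one visible token
        assert len(plan.visible_indices) == 1
        recon = model.reconstruct(image, plan)
        assert recon.shape == (64, 64)
        assert np.isfinite(recon).all()

    def test_latent_plan_mismatch_raises(self, model, image):
        plan = make_masking_plan(16, 0.75, 0)
        latents = mae_encode(model, image, plan)
        with pytest.raises(ValidationError, match="visible"):
            mae_decode(model, latents[:2], plan)

    def test_permutation_equivariance(self):
        """Permuting visible tokens together with their positions permutes
        the latents identically (transformers are set functions)."""
        cfg = tiny_mae_config()
        model = MaskedAutoencoder(cfg)
        rng = np.random.default_rng(2)
        tokens = rng.random((1, 6, cfg.patch_size_px ** 2)).astype(np.float32)
        ids = np.array([[0, 3, 5, 7, 9, 11]])
        out = model._encode_tokens(tokens, ids).data[0]
        perm = np.array([4, 2, 0, 5, 1, 3])
        out_p = model._encode_tokens(tokens[:, perm], ids[:, perm]).data[0]
        np.testing.assert_allclose(out_p, out[perm], atol=1e-5)


class TestReconstructionLoss:
    def test_zero_for_identity(self):
        img = np.random.default_rng(0).random((32, 32))
        plan = make_masking_plan(4, 0.5, 0)
        assert reconstruction_loss(img, img, plan, 16) == 0.0

    def test_constant_offset_closed_form(self):
        """Adding c to every masked patch gives masked-only MSE = c^2."""
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        plan = make_masking_plan(4, 0.5, 1)
        recon = img.copy()
        g = 2
        c = 0.7
        for t in plan.masked_indices:
            r, col = divmod(t, g)
            recon[r * 16:(r + 1) * 16, col * 16:(col + 1) * 16] += c
        assert reconstruction_loss(recon, img, plan, 16) == pytest.approx(c ** 2)
        # untouched visible patches: all-patches loss dilutes by the ratio
        assert reconstruction_loss(
            recon, img, plan, 16, loss_on="all_patches"
        ) == pytest.approx(c ** 2 * len(plan.masked_indices) / 4)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValidationError, match="shape"):
            reconstruction_loss(np.zeros((32, 32)), np.zeros((16, 16)),
                                make_masking_plan(4, 0.5, 0), 16)


class TestGradientAccumulation:
    def test_accumulated_update_matches_large_batch(self):
        """k micro-batches with grad accumulation produce the same optimizer
        step as the pooled batch, to float32 tolerance."""
        cfg = tiny_mae_config()
        rng = np.random.default_rng(0)
        images = rng.random((8, 64, 64)).astype(np.float32)
        ids = np.stack([rng.permutation(16) for _ in range(8)])

        def one_step(accum_chunks):
            model = MaskedAutoencoder(cfg, np.random.default_rng(123))
            opt = AdamW(list(model.named_parameters()), lr=1e-3,
                        weight_decay=0.01)
            opt.zero_grad()
            for sel in accum_chunks:
                loss = model.batch_loss(images[sel], ids[sel],
                                        loss_scale=len(sel) / 8)
                loss.backward()
            opt.step()
            return model.state_dict()

        big = one_step([np.arange(8)])
        accum = one_step([np.arange(0, 4), np.arange(4, 8)])
        for name in big:
            np.testing.assert_allclose(accum[name], big[name], atol=1e-5,
                                       err_msg=name)


@pytest.fixture(scope="module")
def quick_state():
    rng = np.random.default_rng(0)
    crops = rng.random((48, 64, 64)).astype(np.float32) * 0.1
    crops[:, 20:40, 20:40] += 0.8  # a crude bright "cell" to learn
    cells = np.repeat(np.arange(6), 8)
    cfg = tiny_mae_config(epochs=4, batch_size=16)
    return pretrain(crops, cfg, cell_ids=cells)


class TestPretrain:
    def test_loss_history_recorded(self, quick_state):
        assert len(quick_state.history) == 4
        assert quick_state.best_epoch >= 0
        assert quick_state.best_val_loss == min(
            h["val_loss"] for h in quick_state.history
        )

    def test_determinism_same_config_seed(self, quick_state):
        rng = np.random.default_rng(0)
        crops = rng.random((48, 64, 64)).astype(np.float32) * 0.1
        crops[:, 20:40, 20:40] += 0.8
        cells = np.repeat(np.arange(6), 8)
        again = pretrain(crops, tiny_mae_config(epochs=4, batch_size=16),
                         cell_ids=cells)
        assert [h["train_loss"] for h in again.history] == [
            h["train_loss"] for h in quick_state.history
        ]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValidationError, match="non-empty"):
            pretrain(np.zeros((0, 64, 64)), tiny_mae_config())

    def test_checkpoint_roundtrip(self, quick_state, tmp_path):
        path = tmp_path / "mae.npz"
        save_mae_checkpoint(quick_state, path)
        back = load_mae_checkpoint(path)
        assert back.config == quick_state.config
        for k, v in quick_state.encoder_state().items():
            np.testing.assert_array_equal(back.encoder_state()[k], v)

    def test_ema_shadow_matches_structure(self, quick_state):
        live = quick_state.model.state_dict()
        assert set(quick_state.ema) == set(live)
        for k in live:
            assert quick_state.ema[k].shape == live[k].shape
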