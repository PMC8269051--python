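"""IAE model: transforms, losses, training schedule, checkpointing."""

import numpy as np
import pandas as pd
import pytest

from tumorsig import model, nn
from tumorsig.model import ModelConfig


SMALL = dict(latent_shape=(3, 3, 8), base_width=4, disc_fc=16, reg_hidden=16,
             patch_px=48)  # 48 = 3 * 2^4 -> 4 stages


def small_config(**kw):
    return ModelConfig(**{**SMALL, **kw})


class TestConfigValidation:
    def test_defaults_valid(self):
        cfg = ModelConfig()
        assert cfg.latent_shape == (3, 3, 128)
        assert cfg.l1_weight == 500.0

    def test_switch_after_end_rejected(self):
        with pytest.raises(ValueError, match="lr_switch_epoch"):
            ModelConfig(epochs=10, lr_switch_epoch=20)

    def test_incompatible_patch_and_latent_rejected(self):
        with pytest.raises(ValueError, match="power of 2"):
            ModelConfig(patch_px=100)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_noise_variance=-0.1)


class TestAddInputNoise:
    def test_zero_variance_identity(self):
        x = np.random.default_rng(0).uniform(-1, 1, (8, 8))
        np.testing.assert_array_equal(model.add_input_noise(x, 0.0, 1), x)

    def test_noise_variance_monte_carlo(self):
        # moment oracle at the default variance 0.1 over 1e6 draws
        x = np.zeros((1000, 1000))
        noisy = model.add_input_noise(x, 0.1, seed=2)
        assert noisy.var() == pytest.approx(0.1, abs=0.001)
        assert noisy.mean() == pytest.approx(0.0, abs=0.001)

    def test_seed_determinism(self):
        x = np.zeros((16, 16))
        np.testing.assert_array_equal(model.add_input_noise(x, 0.1, 7),
                                      model.add_input_noise(x, 0.1, 7))


class TestAugment:
    def test_pixel_multiset_preserved(self):
        x = np.arange(36.0).reshape(6, 6)
        for seed in range(10):
            out = model.augment(x, seed)
            np.testing.assert_array_equal(np.sort(out.ravel()),
                                          np.sort(x.ravel()))

    def test_double_180_rotation_is_identity(self):
        x = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(np.rot90(np.rot90(x, 2), 2), x)

    def test_rotation_frequencies_uniform(self):
        # frequency-count oracle over 1e4 seeded draws
        probe = np.zeros((2, 2))
        probe[0, 0] = 1.0  # corner marker distinguishes the 4 rotations
        counts = {0: 0, 1: 0, 2: 0, 3: 0}
        for seed in range(10_000):
            out = model.augment(probe, seed, flips=False)
            corner = np.argwhere(out == 1.0)[0]
            counts[int(corner[0]) * 2 + int(corner[1])] += 1
        for c in counts.values():
            assert c / 10_000 == pytest.approx(0.25, abs=0.01)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            model.augment(np.zeros((4, 6)), 0)


@pytest.fixture(scope="module")
def bundle():
    return model.build_bundle(small_config())


class TestEncodeDecode:

    def test_latent_shape(self, bundle):
        z = model.encode(np.zeros((48, 48)), bundle)
        assert z.shape == (3, 3, 8)

    def test_default_config_latent_is_3x3x128(self):
        bundle = model.build_bundle(ModelConfig(base_width=4, disc_fc=8,
                                                reg_hidden=8))
        z = model.encode(np.zeros((96, 96)), bundle)
        assert z.shape == (3, 3, 128)

    def test_encode_deterministic(self, bundle):
        x = np.random.default_rng(0).uniform(-1, 1, (48, 48))
        np.testing.assert_array_equal(model.encode(x, bundle),
                                      model.encode(x, bundle))

    def test_wrong_size_rejected_with_shapes(self, bundle):
        with pytest.raises(ValueError, match="48"):
            model.encode(np.zeros((96, 96)), bundle)
        with pytest.raises(ValueError, match="latent"):
            model.decode(np.zeros((4, 4, 8)), bundle)

    def test_decode_bounded_for_random_latents(self, bundle):
        rng = np.random.default_rng(1)
        for _ in range(100):
            out = model.decode(rng.standard_normal((3, 3, 8)), bundle)
            assert out.min() >= -1.0 and out.max() <= 1.0
        assert out.shape == (48, 48)

    def test_locality_with_stride_only_encoder(self):
        # receptive-field-limited probe: with kernel 2 / no padding each
        # latent cell sees exactly one 16x16 block of a 48x48 patch, so a
        # perturbation confined to one block moves only that cell
        cfg = small_config(kernel_size=2)
        bundle = model.build_bundle(cfg)
        rng = np.random.default_rng(3)
        x = rng.uniform(-0.5, 0.5, (48, 48))
        x2 = x.copy()
        x2[16:32, 16:32] += rng.uniform(0.2, 0.4, (16, 16))
        dz = np.linalg.norm(model.encode(x2, bundle)
                            - model.encode(x, bundle), axis=-1)
        # the perturbed block's cell responds most; the instance-norm
        # statistics leak a little into the other cells, so only the
        # ordering is asserted
        assert dz[1, 1] == dz.max()
        others = [dz[i, j] for i in range(3) for j in range(3)
                  if (i, j) != (1, 1)]
        assert dz[1, 1] > 3 * max(others)


class TestLosses:
    def test_l1_identity_zero(self):
        x = np.random.default_rng(0).uniform(-1, 1, (8, 8))
        assert model.reconstruction_l1(x, x) == 0.0

    def test_l1_hand_summation(self):
        x = np.array([[1.0, -1.0], [0.0, 0.0]])
        xhat = np.zeros((2, 2))
        assert model.reconstruction_l1(x, xhat) == pytest.approx(0.5)

    def test_l1_symmetric(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(-1, 1, (2, 6, 6))
        assert model.reconstruction_l1(x, y) == model.reconstruction_l1(y, x)

    def test_l1_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            model.reconstruction_l1(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_decoder_loss_uninformative_point(self):
        x = np.zeros((4, 4))
        loss = model.decoder_loss(x, x, np.full(4, 0.5), l1_weight=500.0)
        assert loss == pytest.approx(-np.log(0.5), rel=1e-12)

    def test_decoder_loss_lambda_zero_pure_adversarial(self):
        x = np.zeros((4, 4))
        xhat = np.ones((4, 4))
        loss = model.decoder_loss(x, xhat, np.full(3, 0.5), l1_weight=0.0)
        assert loss == pytest.approx(-np.log(0.5))

    def test_decoder_loss_monotone_in_l1(self):
        x = np.zeros((4, 4))
        v = np.full(2, 0.7)
        losses = [model.decoder_loss(x, np.full((4, 4), d), v, 500.0)
                  for d in (0.0, 0.1, 0.2)]
        assert losses == sorted(losses)

    def test_decoder_loss_invalid_verdicts_rejected(self):
        with pytest.raises(ValueError, match="verdicts"):
            model.decoder_loss(np.zeros((2, 2)), np.zeros((2, 2)),
                               np.array([1.2]), 500.0)

    def test_adversarial_losses_uninformative_closed_form(self):
        # oracle: at verdict 0.5 everywhere both discriminator and
        # regularizer losses equal -2 log(1/2)
        cfg = small_config()
        bundle = model.build_bundle(cfg)
        # force uninformative outputs by zeroing the final dense layers
        for net in (bundle.discriminator, bundle.regularizer):
            final = [l for l in net.layers if isinstance(l, nn.Dense)][-1]
            final.params["W"][:] = 0
            final.params["b"][:] = 0
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, (4, 48, 48))
        z = rng.standard_normal((4, 3, 3, 8))
        out = model.adversarial_losses(x, x, z, z, bundle)
        assert out["discriminator"] == pytest.approx(-2 * np.log(0.5),
                                                     rel=1e-6)
        assert out["regularizer"] == pytest.approx(-2 * np.log(0.5),
                                                   rel=1e-6)

    def test_perfect_separation_near_zero_loss(self):
        p_real = np.full(8, 1.0)
        p_fake = np.full(8, 0.0)
        assert model._binary_adv_loss(p_real, p_fake) <= 1e-6

    def test_empty_batch_rejected(self):
        bundle = model.build_bundle(small_config())
        with pytest.raises(ValueError, match="nonempty"):
            model.adversarial_losses(np.empty((0, 48, 48)),
                                     np.empty((0, 48, 48)),
                                     np.empty((0, 3, 3, 8)),
                                     np.empty((0, 3, 3, 8)), bundle)


class TestTraining:
    def test_zero_epochs_leaves_parameters_at_init(self):
        cfg = small_config(epochs=0, lr_switch_epoch=0)
        rng = np.random.default_rng(0)
        data = rng.uniform(-1, 1, (8, 48, 48))
        bundle, history = model.train_model(data, cfg)
        ref = model.build_bundle(cfg)
        for net, refnet in zip(bundle.nets(), ref.nets()):
            for (k1, v1), (k2, v2) in zip(net.state_dict().items(),
                                          refnet.state_dict().items()):
                np.testing.assert_array_equal(v1, v2)
        assert len(history) == 0
        assert not bundle.trained

    def test_learning_rate_schedule_in_history(self):
        cfg = small_config(epochs=4, lr_switch_epoch=2, batch_size=8)
        data = np.random.default_rng(1).uniform(-1, 1, (8, 48, 48))
        _, history = model.train_model(data, cfg)
        assert history.lr.tolist() == [cfg.lr_initial, cfg.lr_initial,
                                       cfg.lr_reduced, cfg.lr_reduced]
        assert history.epoch.tolist() == [1, 2, 3, 4]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            model.train_model(np.empty((0, 48, 48)), small_config())

    def test_history_columns_complete(self):
        cfg = small_config(epochs=2, lr_switch_epoch=1, batch_size=8)
        data = np.random.default_rng(2).uniform(-1, 1, (8, 48, 48))
        _, history = model.train_model(data, cfg)
        assert list(history.columns) == ["epoch", "recon_l1", "dec_adv",
                                         "disc_loss", "reg_loss", "lr"]
        assert np.isfinite(history.drop(columns="epoch").to_numpy()).all()


class TestTrainedModel:
    """Properties of the shared desk-scale training run."""

    def test_reconstruction_beats_mean_image_baseline(self, desk_run,
                                                      phantom_spec):
        from tumorsig import phantom, preprocess
        bundle, _, train_patches, _ = desk_run
        hu, _, _ = phantom.generate_dataset(phantom_spec, 50, 50, seed=909)
        held_out = preprocess.clip_and_scale(hu)
        recon = np.stack([model.reconstruct(p, bundle) for p in held_out])
        mae_model = float(np.abs(recon - held_out).mean())
        mae_baseline = float(
            np.abs(held_out - train_patches.mean(axis=0)).mean())
        assert mae_model < mae_baseline

    def test_training_progress_l1_decreases(self, desk_run):
        _, history, _, _ = desk_run
        k = max(len(history) // 10, 1)
        assert (history.recon_l1.iloc[-k:].median()
                < history.recon_l1.iloc[:k].median())

    def test_l1_term_dominates_decoder_loss(self, desk_run):
        bundle, history, _, _ = desk_run
        lam = bundle.config.l1_weight
        share = lam * history.recon_l1 / (lam * history.recon_l1
                                          + history.dec_adv)
        assert (share > 0.5).all()

    def test_reconstruct_deterministic_and_shaped(self, desk_run):
        bundle, _, patches, _ = desk_run
        r1 = model.reconstruct(patches[0], bundle)
        r2 = model.reconstruct(patches[0], bundle)
        np.testing.assert_array_equal(r1, r2)
        assert r1.shape == patches[0].shape

    def test_lesion_patch_reconstructs_hypodense_region(self, desk_run,
                                                        phantom_spec):
        from tumorsig import phantom, preprocess
        bundle, _, _, _ = desk_run
        hits = 0
        for seed in range(2000, 2010):
            hu, mask, _ = phantom.generate_patch(phantom_spec, True, seed)
            recon = model.reconstruct(preprocess.clip_and_scale(hu), bundle)
            hits += recon[mask].mean() < recon[~mask].mean()
        assert hits >= 8

    def test_latent_pulled_toward_standard_normal(self, desk_run,
                                                  phantom_spec):
        from tumorsig import phantom, preprocess, signatures
        bundle, _, _, _ = desk_run
        hu, _, _ = phantom.generate_dataset(phantom_spec, 32, 32, seed=515)
        feats = signatures.latent_features(
            preprocess.clip_and_scale(hu), bundle)
        assert abs(feats.mean()) <= 0.5  # pooled mean near zero
        var = feats.var(axis=0)
        assert np.mean((var >= 0.3) & (var <= 3.0)) >= 0.9

    def test_checkpoint_round_trip_bit_identical(self, desk_run, tmp_path):
        bundle, history, patches, _ = desk_run
        path = tmp_path / "ckpt.npz"
        model.save_checkpoint(bundle, history, path)
        bundle2, history2 = model.load_checkpoint(path)
        np.testing.assert_array_equal(model.encode(patches[0], bundle),
                                      model.encode(patches[0], bundle2))
        np.testing.assert_array_equal(
            model.decode(model.encode(patches[1], bundle), bundle),
            model.decode(model.encode(patches[1], bundle2), bundle2))
        pd.testing.assert_frame_equal(history, history2)
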