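"""VAE losses (closed forms), architecture arithmetic, gene weighting, and
smoke-scale training behaviour."""

import numpy as np
import pytest

from stvae.vae import (VAE, VAEConfig, composite_loss, conv_size_chain,
                       dice_loss, extract_latent, focal_loss, gaussian_kl,
                       gene_weights, min_crop_size, train)


class TestDiceLoss:
    def test_perfect_reconstruction_is_zero(self):
        t = np.zeros((2, 8, 8)); t[0, 2:4, 2:4] = 1; t[1, 5, 5] = 1
        assert dice_loss(t, t, smooth=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_masks_give_one(self):
        p = np.zeros((1, 6, 6)); p[0, 0, 0] = 1
        t = np.zeros((1, 6, 6)); t[0, 5, 5] = 1
        assert dice_loss(p, t, smooth=0.0) == pytest.approx(1.0)

    def test_hand_computed_overlap(self):
        # |X|=4, |Y|=6, |X n Y|=3 -> 1 - 6/10 = 0.4
        p = np.zeros((1, 6, 6)); p[0, 0, :4] = 1
        t = np.zeros((1, 6, 6)); t[0, 0, 1:7 - 1] = 1; t[0, 1, 0] = 1
        assert p.sum() == 4 and t.sum() == 6 and (p * t).sum() == 3
        assert dice_loss(p, t, smooth=0.0) == pytest.approx(0.4, abs=1e-6)

    def test_gene_weighted_combination(self):
        p = np.zeros((2, 4, 4)); t = np.zeros((2, 4, 4))
        p[0, 0, 0] = 1; t[0, 0, 0] = 1          # plane 0: dice 0
        p[1, 0, 0] = 1; t[1, 3, 3] = 1          # plane 1: dice 1
        w = np.array([3.0, 1.0])
        assert dice_loss(p, t, w, smooth=0.0) == pytest.approx(0.25)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((1, 4, 4)), np.zeros((1, 5, 5)))


class TestFocalLoss:
    def test_confident_correct_pixel_contributes_zero(self):
        p = np.ones((1, 2, 2)); t = np.ones((1, 2, 2))
        assert focal_loss(p, t) == pytest.approx(0.0, abs=1e-5)

    def test_gamma_zero_alpha_half_is_half_bce(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 5, 5))
        t = (rng.random((4, 5, 5)) < 0.3).astype(float)
        bce = -np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))
        assert focal_loss(p, t, alpha=0.5, gamma=0.0) == \
            pytest.approx(0.5 * bce, rel=1e-9)

    def test_hand_computed_single_pixel(self):
        # -0.25 * (0.1)^2 * ln(0.9) = 2.634e-4
        p = np.array([[[0.9]]]); t = np.array([[[1.0]]])
        assert focal_loss(p, t, alpha=0.25, gamma=2.0) == \
            pytest.approx(-0.25 * 0.01 * np.log(0.9), rel=1e-9)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.5]]), np.array([[1.0]]), gamma=-1)


class TestArchitecture:
    def test_size_chain_100px_5_blocks(self):
        assert conv_size_chain(100, 5) == [100, 49, 24, 11, 5, 2]

    def test_crop_32_rejected_with_minimum_stated(self):
        with pytest.raises(ValueError, match="63"):
            conv_size_chain(32, 5)
        assert min_crop_size(5) == 63

    def test_multimodal_input_channels_concatenate(self):
        cfg = VAEConfig(modality="both", n_genes=196, crop_size=200,
                        n_conv_blocks=5)
        assert cfg.in_channels == 198

    def test_double_decoder_for_multimodal_single_otherwise(self):
        both = VAE(VAEConfig(modality="both", n_genes=3, crop_size=31,
                             n_conv_blocks=3, channels=(4, 8, 8), latent_dim=6))
        uni = VAE(VAEConfig(modality="stains", crop_size=31, n_conv_blocks=3,
                            channels=(4, 8, 8), latent_dim=6))
        assert both.n_decoders == 2 and uni.n_decoders == 1

    def test_decoder_mirrors_encoder_sizes(self, rng):
        cfg = VAEConfig(modality="tc", n_genes=3, crop_size=45, n_conv_blocks=3,
                        channels=(4, 6, 8), latent_dim=5)
        m = VAE(cfg)
        out = m.forward((rng.random((2, 3, 45, 45)) < 0.1).astype(np.float32),
                        rng=rng)
        assert out["tc"].shape == (2, 3, 45, 45)
        assert out["mu"].shape == (2, 5)


class TestGeneWeights:
    def test_equal_counts_give_equal_weights(self):
        gw = gene_weights(np.full((4, 5), 7))
        assert np.allclose(gw.values, gw.values[0])

    def test_inverse_expression_ratio_before_rescale(self):
        counts = np.array([[9, 0]])
        inv = 1.0 / (counts + 1.0)
        assert inv[0, 1] / inv[0, 0] == pytest.approx(10.0)

    def test_weights_within_bounds(self, rng):
        gw = gene_weights(rng.poisson(3, size=(16, 10)), bounds=(1, 10))
        assert gw.values.min() >= 1 - 1e-9 and gw.values.max() <= 10 + 1e-9

    def test_anti_monotone_in_batch_expression(self, rng):
        counts = rng.negative_binomial(2, 0.2, size=(32, 12))
        gw = gene_weights(counts)
        assert gw.check_anti_monotone(counts.sum(axis=0))

    def test_per_class_weights_when_labels_given(self, rng):
        counts = rng.poisson(4, size=(20, 6))
        labels = np.repeat(["a", "b"], 10)
        gw = gene_weights(counts, class_labels=labels)
        assert set(gw.per_class) == {"a", "b"}

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            gene_weights(np.zeros((0, 5)))


class TestCompositeLoss:
    def test_stains_only_reduces_to_weighted_mse(self, rng):
        cfg = VAEConfig(modality="stains", crop_size=31, n_conv_blocks=3,
                        channels=(4, 4, 4), w_stain_l2=2.0)
        out = {"stains": rng.random((2, 2, 8, 8))}
        tgt = {"stains": rng.random((2, 2, 8, 8))}
        total, comps = composite_loss(out, tgt, cfg)
        mse = np.mean((out["stains"] - tgt["stains"]) ** 2)
        assert total == pytest.approx(2.0 * mse)

    def test_perfect_reconstruction_zero_total(self):
        cfg = VAEConfig(modality="tc", n_genes=2, crop_size=31, n_conv_blocks=3,
                        channels=(4, 4, 4), dice_smooth=0.0)
        t = np.zeros((1, 2, 4, 4)); t[0, 0, 1, 1] = 1; t[0, 1, 2, 2] = 1
        total, comps = composite_loss({"tc": t}, {"tc": t}, cfg)
        assert total == pytest.approx(0.0, abs=1e-5)

    def test_beta_kl_adds_exact_closed_form(self, rng):
        cfg0 = VAEConfig(modality="stains", crop_size=31, n_conv_blocks=3,
                         channels=(4, 4, 4), beta_kl=0.0)
        cfg1 = VAEConfig(modality="stains", crop_size=31, n_conv_blocks=3,
                         channels=(4, 4, 4), beta_kl=0.7)
        out = {"stains": rng.random((3, 2, 5, 5)),
               "mu": rng.normal(size=(3, 4)), "logvar": rng.normal(size=(3, 4))}
        tgt = {"stains": rng.random((3, 2, 5, 5))}
        t0, _ = composite_loss(out, tgt, cfg0)
        t1, _ = composite_loss(out, tgt, cfg1)
        mu, lv = out["mu"], out["logvar"]
        kl = 0.5 * np.sum(mu ** 2 + np.exp(lv) - lv - 1) / 3
        assert t1 - t0 == pytest.approx(0.7 * kl, rel=1e-9)

    def test_total_equals_weighted_component_sum(self, rng):
        cfg = VAEConfig(modality="both", n_genes=2, crop_size=31, n_conv_blocks=3,
                        channels=(4, 4, 4))
        out = {"tc": rng.uniform(0.01, 0.99, (2, 2, 6, 6)),
               "stains": rng.random((2, 2, 6, 6)),
               "mu": rng.normal(size=(2, 4)), "logvar": rng.normal(size=(2, 4))}
        tgt = {"tc": (rng.random((2, 2, 6, 6)) < 0.2).astype(float),
               "stains": rng.random((2, 2, 6, 6))}
        total, c = composite_loss(out, tgt, cfg)
        assert total == pytest.approx(
            cfg.w_dice * c["dice"] + cfg.w_focal * c["focal"]
            + cfg.w_stain_l2 * c["stain_l2"] + cfg.beta_kl * c["kl"], abs=1e-6)

    def test_modality_mismatch_raises(self):
        cfg = VAEConfig(modality="stains", crop_size=31, n_conv_blocks=3,
                        channels=(4, 4, 4))
        with pytest.raises(ValueError):
            composite_loss({"stains": np.zeros((1, 2, 4, 4))}, {}, cfg)


class TestRotationObjectiveInvariance:
    def test_four_term_average_is_exact_expectation(self, rng):
        """Averaging the loss over the 4 orthogonal rotations equals the
        expectation under the uniform augmentation distribution (it IS the
        4-term average)."""
        t = (rng.random((1, 2, 8, 8)) < 0.2).astype(float)
        p = rng.uniform(0.01, 0.99, (1, 2, 8, 8))
        losses = [focal_loss(np.rot90(p, k, axes=(-2, -1)),
                             np.rot90(t, k, axes=(-2, -1))) for k in range(4)]
        assert np.mean(losses) == pytest.approx(losses[0], rel=1e-9)


def _smoke_data(rng, n=24, genes=3, size=15):
    tc = (rng.random((n, genes, size, size)) < 0.05).astype(np.uint8)
    st = rng.random((n, 2, size, size)).astype(np.float32)
    counts = tc.sum(axis=(2, 3))
    return tc, st, counts


class TestTraining:
    def _config(self, **kw):
        base = dict(modality="tc", n_genes=3, crop_size=15, n_conv_blocks=2,
                    channels=(4, 6), latent_dim=5, batch_size=8, epochs=3,
                    learning_rate=1e-3, seed=2)
        base.update(kw)
        return VAEConfig(**base)

    def test_zero_epochs_leaves_parameters_unchanged(self, rng):
        tc, st, counts = _smoke_data(rng)
        m = VAE(self._config(epochs=0))
        before = [p.value.copy() for p in m.params()]
        train(m, tc_crops=tc, counts=counts)
        assert m.training_log == []
        assert all(np.array_equal(a, p.value)
                   for a, p in zip(before, m.params()))

    def test_loss_decreases_on_structured_fixture(self, small_dataset):
        from stvae.preprocess import build_multiplane_crop

        ds, cfg = small_dataset
        ids = ds.cells["cell"].to_numpy()[:80]
        tc = np.stack([build_multiplane_crop(ds, int(c), 32, 2,
                                             list(range(ds.n_genes))).tensor
                       for c in ids])
        m = VAE(VAEConfig(modality="tc", n_genes=ds.n_genes, crop_size=32,
                          n_conv_blocks=3, channels=(8, 12, 16), latent_dim=8,
                          batch_size=8, epochs=5, learning_rate=1e-3, seed=2))
        train(m, tc_crops=tc, counts=ds.counts[:80])
        assert m.training_log[-1]["total"] < m.training_log[0]["total"]

    def test_same_seed_identical_training_logs(self, rng):
        tc, st, counts = _smoke_data(rng)
        logs = []
        for _ in range(2):
            m = VAE(self._config())
            train(m, tc_crops=tc, counts=counts)
            logs.append(m.training_log)
        assert logs[0] == logs[1]

    def test_loss_component_accounting(self, rng):
        tc, st, counts = _smoke_data(rng)
        cfg = self._config(modality="both", epochs=1)
        m = VAE(cfg)
        train(m, tc_crops=tc, stain_crops=st, counts=counts)
        e = m.training_log[0]
        assert e["total"] == pytest.approx(
            cfg.w_dice * e["dice"] + cfg.w_focal * e["focal"]
            + cfg.w_stain_l2 * e["stain_l2"] + cfg.beta_kl * e["kl"], abs=1e-6)

    def test_missing_modality_rejected(self, rng):
        tc, st, counts = _smoke_data(rng)
        m = VAE(self._config(modality="both"))
        with pytest.raises(ValueError):
            train(m, tc_crops=tc)


class TestLatentExtraction:
    def test_shape_contract(self, rng):
        tc, st, counts = _smoke_data(rng, n=17)
        m = VAE(VAEConfig(modality="tc", n_genes=3, crop_size=15,
                          n_conv_blocks=2, channels=(4, 6), latent_dim=5))
        with pytest.warns(UserWarning, match="untrained"):
            lat = extract_latent(m, tc_crops=tc, batch_size=7)
        assert lat.values.shape == (17, 5)
        assert np.all(np.isfinite(lat.values))

    def test_mean_mode_deterministic(self, rng):
        tc, st, counts = _smoke_data(rng)
        m = VAE(VAEConfig(modality="stains", crop_size=15, n_conv_blocks=2,
                          channels=(4, 6), latent_dim=5, epochs=1))
        train(m, stain_crops=st)
        a = extract_latent(m, stain_crops=st, mode="mean")
        b = extract_latent(m, stain_crops=st, mode="mean")
        assert np.array_equal(a.values, b.values)

    def test_sample_mode_with_tiny_sigma_equals_mean(self, rng):
        tc, st, counts = _smoke_data(rng)
        m = VAE(VAEConfig(modality="stains", crop_size=15, n_conv_blocks=2,
                          channels=(4, 6), latent_dim=5, epochs=1,
                          logvar_bias_init=-60.0, logvar_clamp=100.0))
        # untrained heads: logvar ~= bias -> sigma ~= 0
        with pytest.warns(UserWarning):
            a = extract_latent(m, stain_crops=st, mode="posterior-sample", seed=1)
        with pytest.warns(UserWarning):
            b = extract_latent(m, stain_crops=st, mode="mean")
        assert np.allclose(a.values, b.values, atol=1e-4)


class TestGeneWeightEfficacy:
    def test_weighting_improves_rare_gene_reconstruction(self):
        """With one dominant gene, dynamic gene weighting must improve the
        per-gene Dice of the rare genes, paired over 3 training seeds."""
        from stvae.preprocess import build_multiplane_crop
        from tests_helpers import dominant_gene_dataset

        ds = dominant_gene_dataset(seed=0)
        ids = ds.cells["cell"].to_numpy()
        tc = np.stack([build_multiplane_crop(ds, int(c), 32, 3,
                                             list(range(ds.n_genes))).tensor
                       for c in ids])

        def rare_dice(model):
            num = np.zeros(ds.n_genes)
            den = np.zeros(ds.n_genes)
            for s in range(0, len(tc), 32):
                x = tc[s:s + 32].astype(np.float32)
                out = model.forward(x, train=False, sample=False)
                p = out["tc"].astype(np.float64)
                num += 2 * (p * x).sum(axis=(0, 2, 3))
                den += p.sum(axis=(0, 2, 3)) + x.sum(axis=(0, 2, 3))
            d = 1 - (num + 1) / (den + 1)
            return d[1:].mean()          # genes 1.. are the rare ones

        for seed in (1, 2, 3):
            scores = {}
            for use_w in (True, False):
                cfg = VAEConfig(modality="tc", n_genes=ds.n_genes,
                                crop_size=32, n_conv_blocks=3,
                                channels=(8, 16, 24), latent_dim=10,
                                batch_size=8, epochs=25, learning_rate=2e-3,
                                seed=seed, use_gene_weights=use_w)
                m = VAE(cfg)
                train(m, tc_crops=tc, counts=ds.counts)
                scores[use_w] = rare_dice(m)
            assert scores[True] < scores[False], seed


def test_gaussian_kl_standard_normal_is_zero():
    mu = np.zeros((3, 4)); lv = np.zeros((3, 4))
    assert gaussian_kl(mu, lv) == 0.0
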