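"""Architecture contracts: shapes, determinism, fusion bookkeeping,
degenerate configurations, and checkpoint round-trips (tiny configs)."""

import numpy as np
import pytest

import poehvae as p
from poehvae.autodiff import Tensor
from poehvae.gaussians import poe_fuse
from poehvae.network import LatentLevelState, save_checkpoint, load_checkpoint


@pytest.fixture()
def batch1(tiny_batch):
    return tiny_batch.restrict((0,))


class TestModalityBatch:
    def test_range_contract(self):
        bad = np.full((1, 2, 1, 4, 4), 1.5, np.float32)
        with pytest.raises(ValueError):
            p.ModalityBatch(bad, (0,))

    def test_empty_subset_rejected(self, tiny_batch):
        with pytest.raises(ValueError):
            p.ModalityBatch(tiny_batch.images, ())

    def test_subset_restriction(self, tiny_batch):
        assert tiny_batch.restrict((1,)).available == (1,)


class TestBottomUp:
    def test_shapes_follow_spatial_schedule(self, tiny_model, tiny_batch):
        feats = tiny_model.bottom_up(tiny_batch.modality(0), 0)
        cfg = tiny_model.config
        assert len(feats) == cfg.num_levels
        for f, c, s in zip(feats, cfg.channels, cfg.spatial_sizes):
            assert f.shape[1:] == (c,) + s

    def test_deterministic(self, tiny_model, tiny_batch):
        a = tiny_model.bottom_up(tiny_batch.modality(0), 0)
        b = tiny_model.bottom_up(tiny_batch.modality(0), 0)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.data, fb.data)

    def test_input_sensitivity(self, tiny_model, tiny_batch):
        """No dead identity path: zero input differs from real input everywhere."""
        zero = np.zeros_like(tiny_batch.modality(0))
        a = tiny_model.bottom_up(tiny_batch.modality(0), 0)
        b = tiny_model.bottom_up(zero, 0)
        for fa, fb in zip(a, b):
            assert not np.allclose(fa.data, fb.data)

    def test_wrong_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.bottom_up(np.zeros((1, 1, 8, 8), np.float32), 0)


class TestPriorsAndExperts:
    def test_top_prior_is_standard_normal(self, tiny_model):
        prior = tiny_model.prior_at_level(None, tiny_model.config.num_levels,
                                          batch_size=3)
        assert np.all(prior.mean.data == 0.0)
        assert np.all(prior.log_var.data == 0.0)

    def test_lower_levels_require_context(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.prior_at_level(None, 1)
        with pytest.raises(ValueError):
            tiny_model.expert_at_level(Tensor(np.zeros((1, 4, 16, 16), np.float32)),
                                       None, 1, 0)

    def test_zeroed_network_priors_are_standard_normal(self):
        """Zero weights + zero-init heads emit mean 0, log-variance 0."""
        cfg = p.HierarchyConfig.tiny()
        model = p.MultimodalHVAE(cfg, np.random.default_rng(0))
        for t in model.parameters():
            t.data = np.zeros_like(t.data)
        ctx = Tensor(np.zeros((2, cfg.channels[0]) + cfg.spatial_sizes[0], np.float32))
        prior = model.prior_at_level(ctx, 1, batch_size=2)
        assert np.all(prior.mean.data == 0.0)
        assert np.all(prior.log_var.data == 0.0)

    def test_expert_log_var_clamped(self, tiny_model, tiny_batch):
        states, _ = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        for s in states:
            for e in s.experts.values():
                assert np.all(e.log_var.data >= -14.0)
                assert np.all(e.log_var.data <= 14.0)


class TestInferHierarchy:
    def test_expert_count_tracks_subset(self, tiny_model, tiny_batch, batch1):
        states, _ = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        assert all(len(s.experts) == 2 for s in states)
        states1, _ = tiny_model.infer_hierarchy(batch1, mode="mean")
        assert all(len(s.experts) == 1 for s in states1)

    def test_states_are_coarse_to_fine(self, tiny_model, tiny_batch):
        states, _ = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        assert [s.level for s in states] == [3, 2, 1]

    def test_mean_mode_bitwise_deterministic(self, tiny_model, tiny_batch):
        _, fa = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        _, fb = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        assert np.array_equal(fa.data, fb.data)

    def test_sample_mode_seed_reproducible(self, tiny_model, tiny_batch):
        sa, _ = tiny_model.infer_hierarchy(tiny_batch, rng=np.random.default_rng(5))
        sb, _ = tiny_model.infer_hierarchy(tiny_batch, rng=np.random.default_rng(5))
        for a, b in zip(sa, sb):
            assert np.array_equal(a.z.data, b.z.data)

    def test_posterior_equals_poe_of_prior_and_experts(self, tiny_model, tiny_batch):
        states, _ = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        for s in states:
            refused = poe_fuse(s.prior.detach(), [e.detach() for e in s.experts.values()])
            assert np.allclose(refused.mean, s.posterior.mean.data, atol=1e-6)
            assert np.allclose(refused.log_var, s.posterior.log_var.data, atol=1e-6)

    def test_empty_subset_rejected(self, tiny_model, tiny_batch):
        with pytest.raises(ValueError):
            tiny_model.infer_hierarchy(tiny_batch, mode="nonsense")


class TestSingleLevelDegenerate:
    """L = 1 collapses the model to a (multi-modal) VAE by configuration."""

    @pytest.fixture()
    def vae(self):
        cfg = p.HierarchyConfig(num_levels=1, base_image_size=(16, 16),
                                spatial_sizes=[(1, 1)], channels=[8],
                                num_modalities=1, expansion_ratio=2,
                                se_reduction=4, decoder_resnet_blocks=1,
                                decoder_channels=8, disc_base_channels=8)
        return p.MultimodalHVAE(cfg, np.random.default_rng(3))

    def test_single_level_posterior_matches_hand_fusion(self, vae):
        x = np.clip(np.random.default_rng(0).normal(0, 0.3, (2, 1, 1, 16, 16)),
                    -1, 1).astype(np.float32)
        batch = p.ModalityBatch(x, (0,))
        states, _ = vae.infer_hierarchy(batch, mode="mean")
        assert len(states) == 1
        s = states[0]
        feats = vae.bottom_up(batch.modality(0), 0)
        expert = vae.expert_at_level(feats[0], None, 1, 0)
        # hand fusion with the standard-Normal top prior
        prec = 1.0 + np.exp(-expert.log_var.data)
        mean = np.exp(-expert.log_var.data) * expert.mean.data / prec
        assert np.allclose(s.posterior.mean.data, mean, atol=1e-6)
        assert np.allclose(np.exp(s.posterior.log_var.data), 1.0 / prec, atol=1e-6)

    def test_multimodal_single_level_runs(self):
        cfg = p.HierarchyConfig(num_levels=1, base_image_size=(16, 16),
                                spatial_sizes=[(1, 1)], channels=[8],
                                num_modalities=2, expansion_ratio=2,
                                se_reduction=4, decoder_resnet_blocks=1,
                                decoder_channels=8, disc_base_channels=8)
        mvae = p.MultimodalHVAE(cfg, np.random.default_rng(4))
        ds = p.generate_pairs(2, p.SceneSpec(image_size=16, seed=5))
        states, feat = mvae.infer_hierarchy(p.ModalityBatch(ds.images, (0, 1)),
                                            mode="mean")
        assert len(states) == 1 and len(states[0].experts) == 2
        outs = mvae.decode_images(feat)
        assert len(outs) == 2 and outs[0].shape == (2, 1, 16, 16)


class TestDecodersAndDiscriminator:
    def test_decode_range_and_count(self, tiny_model, tiny_batch, batch1):
        _, feat = tiny_model.infer_hierarchy(batch1, mode="mean")
        outs = tiny_model.decode_images(feat)
        assert len(outs) == tiny_model.config.num_modalities
        for o in outs:
            assert o.shape == (4, 1, 16, 16)
            assert np.all(np.abs(o.data) <= 1.0)

    def test_decode_deterministic(self, tiny_model, tiny_batch):
        _, feat = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        a = tiny_model.decode_images(feat)[0].data
        b = tiny_model.decode_images(feat)[0].data
        assert np.array_equal(a, b)

    def test_patch_logit_map_is_spatial(self, tiny_model, tiny_batch):
        logits = tiny_model.discriminate(tiny_batch.modality(0), 0)
        assert logits.shape[1] == 1
        assert logits.shape[2] > 1 and logits.shape[3] > 1

    def test_discriminator_sensitivity_and_determinism(self, tiny_model, tiny_batch):
        x = tiny_batch.modality(0)
        a = tiny_model.discriminate(x, 0).data
        b = tiny_model.discriminate(x, 0).data
        c = tiny_model.discriminate(np.clip(x + 0.3, -1, 1), 0).data
        assert np.array_equal(a, b)
        assert not np.allclose(a, c)


class TestUnifiedModelProperty:
    def test_parameters_independent_of_subset(self, tiny_model, tiny_batch, batch1):
        """One network serves every synthesis direction: the trainable
        parameter set is identical whichever subset is presented."""
        names_before = [n for n, _ in tiny_model.named_parameters()]
        tiny_model.infer_hierarchy(batch1, mode="mean")
        tiny_model.infer_hierarchy(tiny_batch.restrict((1,)), mode="mean")
        tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        assert [n for n, _ in tiny_model.named_parameters()] == names_before


class TestCheckpoint:
    def test_round_trip_bit_identical(self, tiny_model, tiny_batch, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_model, p.TrainConfig(epochs=2), epoch=2)
        restored, tcfg, extras = load_checkpoint(path)
        assert extras["epoch"] == 2 and tcfg.epochs == 2
        _, fa = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        _, fb = restored.infer_hierarchy(tiny_batch, mode="mean")
        assert np.array_equal(fa.data, fb.data)
        a = tiny_model.decode_images(fa)[1].data
        b = restored.decode_images(fb)[1].data
        assert np.array_equal(a, b)
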