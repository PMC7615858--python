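"""Objective-function checks: subset enumeration, ELBO reductions against an
independent single-level oracle, the warm-up schedule, GAN terms, and
training-loop reproducibility/resume contracts."""

import numpy as np
import pytest
from scipy.stats import norm

import poehvae as p
from poehvae.gaussians import sample
from poehvae.network import save_checkpoint
from poehvae.objective import (
    effective_lambda_gan,
    elbo_terms,
    enumerate_subsets,
    full_elbo,
    gan_losses,
    gan_warmup_epochs,
    training_loss,
)


class TestSubsetEnumeration:
    @pytest.mark.parametrize("m,expected", [
        (1, [(0,)]),
        (2, [(0,), (1,), (0, 1)]),
    ])
    def test_canonical_order(self, m, expected):
        assert enumerate_subsets(m) == expected

    def test_counts_are_two_to_m_minus_one(self):
        for m in range(1, 6):
            assert len(enumerate_subsets(m)) == 2 ** m - 1

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            enumerate_subsets(0)


class TestWarmupSchedule:
    def test_reference_schedule(self):
        cfg = p.TrainConfig(epochs=1000, gan_warmup_fraction=0.8)
        assert gan_warmup_epochs(cfg) == 800
        assert effective_lambda_gan(cfg, 0) == 0.0
        assert effective_lambda_gan(cfg, 799) == 0.0
        assert effective_lambda_gan(cfg, 800) == 1.0
        assert effective_lambda_gan(cfg, 999) == 1.0

    def test_scaled_schedule(self):
        cfg = p.TrainConfig(epochs=20, gan_warmup_fraction=0.8)
        assert [effective_lambda_gan(cfg, e) for e in (15, 16)] == [0.0, 1.0]

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            p.TrainConfig(gan_warmup_fraction=1.5)


def _single_level_vae():
    cfg = p.HierarchyConfig(num_levels=1, base_image_size=(16, 16),
                            spatial_sizes=[(1, 1)], channels=[8],
                            num_modalities=1, expansion_ratio=2,
                            se_reduction=4, decoder_resnet_blocks=1,
                            decoder_channels=8, disc_base_channels=8)
    return p.MultimodalHVAE(cfg, np.random.default_rng(9))


class TestElboReductions:
    def test_single_level_matches_hand_rolled_vae_elbo(self):
        """With L=1, M=1 the bound collapses to the textbook VAE ELBO; an
        independent float64 oracle (scipy log-pdfs + closed-form KL) built
        from the same expert statistics and noise draw must agree."""
        model = _single_level_vae()
        rng = np.random.default_rng(0)
        x = np.clip(rng.normal(0, 0.4, (3, 1, 1, 16, 16)), -1, 1).astype(np.float32)
        batch = p.ModalityBatch(x, (0,))
        eps = rng.standard_normal((3, 8, 1, 1)).astype(np.float32)
        sigma = 0.7
        report = elbo_terms(model, batch, decoder_sigma=sigma, noises=[eps])

        # oracle: same encoder statistics, same noise, independent math
        feats = model.bottom_up(batch.modality(0), 0)
        expert = model.expert_at_level(feats[0], None, 1, 0)
        mu_e = expert.mean.data.astype(np.float64)
        var_e = np.exp(expert.log_var.data.astype(np.float64))
        # posterior = N(0,I) x expert, precision-weighted
        prec = 1.0 + 1.0 / var_e
        var_q = 1.0 / prec
        mu_q = (mu_e / var_e) / prec
        z = mu_q + np.sqrt(var_q) * eps
        from poehvae.autodiff import Tensor
        h = model.z_init(Tensor(z.astype(np.float32))).swish()
        mu_x = model.decode_images(h)[0].data.astype(np.float64)
        recon = norm.logpdf(x[:, 0].astype(np.float64), loc=mu_x, scale=sigma).sum() / 3
        kl = 0.5 * (var_q + mu_q ** 2 - 1.0 - np.log(var_q)).sum() / 3
        assert report.elbo == pytest.approx(recon - kl, rel=1e-5)
        assert report.kl[0] == pytest.approx(kl, rel=1e-4)

    def test_full_set_path_is_subset_path(self, tiny_model, tiny_batch):
        """The complete-set bound is the subset bound at pi = {1..M}: same
        code path, bitwise-equal results on shared noise draws."""
        cfg = tiny_model.config
        rng = np.random.default_rng(3)
        noises = [rng.standard_normal((4, c) + s).astype(np.float32)
                  for c, s in zip(cfg.channels[::-1], cfg.spatial_sizes[::-1])]
        a = elbo_terms(tiny_model, tiny_batch.restrict((0, 1)), noises=noises)
        b = full_elbo(tiny_model, tiny_batch, noises=noises)
        assert a.elbo == b.elbo
        assert a.recon == b.recon and a.kl == b.kl

    def test_reconstruction_covers_all_modalities(self, tiny_model, tiny_batch):
        report = elbo_terms(tiny_model, tiny_batch.restrict((0,)),
                            rng=np.random.default_rng(0))
        assert len(report.recon) == 2  # missing modality reconstructed too
        assert len(report.kl) == tiny_model.config.num_levels
        assert all(k >= 0 for k in report.kl)

    def test_deterministic_under_fixed_seed(self, tiny_model, tiny_batch):
        a = elbo_terms(tiny_model, tiny_batch, rng=np.random.default_rng(8))
        b = elbo_terms(tiny_model, tiny_batch, rng=np.random.default_rng(8))
        assert a.elbo == b.elbo and a.recon == b.recon


class TestTrainingLoss:
    def test_one_pass_per_subset(self, tiny_model, tiny_batch, monkeypatch):
        calls = []
        orig = tiny_model.infer_hierarchy

        def counting(batch, **kw):
            calls.append(batch.available)
            return orig(batch, **kw)

        monkeypatch.setattr(tiny_model, "infer_hierarchy", counting)
        cfg = p.TrainConfig(epochs=10, lambda_gan=0.0)
        training_loss(tiny_model, tiny_batch, cfg, epoch=0,
                      rng=np.random.default_rng(0))
        assert calls == [(0,), (1,), (0, 1)]

    def test_seven_subsets_for_three_modalities(self):
        cfg3 = p.HierarchyConfig.tiny(num_modalities=3)
        model = p.MultimodalHVAE(cfg3, np.random.default_rng(0))
        ds = p.generate_pairs(2, p.SceneSpec(image_size=16, seed=2))
        imgs = np.concatenate([ds.images, ds.images[:, :1]], axis=1)
        batch = p.ModalityBatch(imgs, (0, 1, 2))
        report = training_loss(model, batch, p.TrainConfig(lambda_gan=0.0),
                               epoch=0, rng=np.random.default_rng(0))
        assert len(report.per_subset) == 7

    def test_total_is_equal_weight_subset_mean(self, tiny_model, tiny_batch):
        report = training_loss(tiny_model, tiny_batch,
                               p.TrainConfig(lambda_gan=0.0), epoch=0,
                               rng=np.random.default_rng(1))
        report.check_consistency()
        subtotals = [e["total"] for e in report.per_subset.values()]
        assert len(set(round(s, 6) for s in subtotals)) > 1  # genuinely distinct
        assert report.total == pytest.approx(np.mean(subtotals), rel=1e-6)

    def test_warmup_disables_gan_terms(self, tiny_model, tiny_batch):
        cfg = p.TrainConfig(epochs=10, gan_warmup_fraction=0.8, lambda_gan=1.0)
        early = training_loss(tiny_model, tiny_batch, cfg, epoch=0,
                              rng=np.random.default_rng(2))
        late = training_loss(tiny_model, tiny_batch, cfg, epoch=8,
                             rng=np.random.default_rng(2))
        assert early.effective_lambda_gan == 0.0
        assert all(v == 0.0 for e in early.per_subset.values() for v in e["gan"])
        assert late.effective_lambda_gan == 1.0
        assert any(v != 0.0 for e in late.per_subset.values() for v in e["gan"])


class TestGanLosses:
    def _zero_disc(self):
        from poehvae.nn import PatchDiscriminator
        d = PatchDiscriminator(np.random.default_rng(0), 1, 8, n_strided=1)
        for t in d.parameters():
            t.data = np.zeros_like(t.data)
        return d

    def test_uninformative_discriminator_gives_ln2(self, rng):
        d = self._zero_disc()
        real = rng.uniform(-1, 1, (2, 1, 16, 16)).astype(np.float32)
        fake = rng.uniform(-1, 1, (2, 1, 16, 16)).astype(np.float32)
        gen_term, disc_term = gan_losses(d, real, fake)
        assert float(gen_term.data) == pytest.approx(np.log(2), rel=1e-6)
        assert float(disc_term.data) == pytest.approx(np.log(2), rel=1e-6)

    def test_discriminator_term_isolated_from_generator(self, tiny_model, tiny_batch):
        _, feat = tiny_model.infer_hierarchy(tiny_batch, mode="mean")
        fake = tiny_model.decode_images(feat)[0]
        _, disc_term = gan_losses(tiny_model.discriminators[0],
                                  tiny_batch.modality(0), fake)
        tiny_model.zero_grad()
        disc_term.backward()
        gen_ids = {id(t) for t in tiny_model.generator_parameters()}
        assert all(t.grad is None for t in tiny_model.parameters() if id(t) in gen_ids)
        assert any(t.grad is not None for t in tiny_model.discriminators[0].parameters())

    def test_confident_discriminator_limits(self, rng):
        """Near-perfect discrimination: disc term -> 0, generator term grows
        linearly with the logit magnitude (stable, no overflow)."""
        class Stub:
            def __init__(self, val):
                self.val = val

            def __call__(self, x):
                from poehvae.autodiff import Tensor
                sign = 1.0 if x.data.mean() > 0 else -1.0
                return Tensor(np.full((1, 1, 2, 2), sign * self.val, np.float32))

        real = np.full((1, 1, 4, 4), 0.5, np.float32)
        fake = np.full((1, 1, 4, 4), -0.5, np.float32)
        gen_term, disc_term = gan_losses(Stub(60.0), real, fake)
        assert float(disc_term.data) == pytest.approx(0.0, abs=1e-9)
        assert float(gen_term.data) == pytest.approx(60.0, rel=1e-5)

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            gan_losses(tiny_model.discriminators[0], np.zeros((1, 1, 16, 16)),
                       np.zeros((1, 1, 8, 8)))


class TestTrainLoop:
    def _dataset(self, n=6):
        return p.generate_pairs(n, p.SceneSpec(image_size=16, seed=21))

    def _config(self, epochs=2, **kw):
        return p.TrainConfig(epochs=epochs, batch_size=3, seed=5,
                             learning_rate=1e-3, lambda_gan=0.0, **kw)

    def test_identical_seeds_identical_logs(self):
        ds = self._dataset()
        cfg = p.HierarchyConfig.tiny()
        _, h1 = p.train(ds, cfg, self._config())
        _, h2 = p.train(ds, cfg, self._config())
        for a, b in zip(h1, h2):
            assert a["total"] == pytest.approx(b["total"], abs=1e-6)
            assert a["kl"] == pytest.approx(b["kl"], abs=1e-6)

    def test_checkpoint_resume_continues_identically(self, tmp_path):
        ds = self._dataset()
        cfg = p.HierarchyConfig.tiny()
        _, h_full = p.train(ds, cfg, self._config(epochs=3))
        run = tmp_path / "run"
        p.train(ds, cfg, self._config(epochs=2), run_dir=str(run))
        _, h_resumed = p.train(ds, cfg, self._config(epochs=3),
                               resume_from=str(run / "checkpoint_final.npz"))
        assert len(h_resumed) == 1
        assert h_resumed[0]["total"] == pytest.approx(h_full[2]["total"], rel=1e-5)

    def test_empty_dataset_rejected(self):
        empty = p.PairedDataset(np.zeros((0, 2, 1, 16, 16), np.float32))
        with pytest.raises(ValueError):
            p.train(empty, p.HierarchyConfig.tiny(), self._config())

    def test_gan_phase_updates_discriminator(self):
        ds = self._dataset(4)
        cfg = p.HierarchyConfig.tiny()
        tcfg = self._config(epochs=2, gan_warmup_fraction=0.5)
        tcfg.lambda_gan = 1.0
        model, hist = p.train(ds, cfg, tcfg)
        assert "disc" in hist[1] and "disc" not in hist[0]

    def test_loss_log_written_as_jsonl(self, tmp_path):
        import json
        ds = self._dataset(4)
        run = tmp_path / "run"
        p.train(ds, p.HierarchyConfig.tiny(), self._config(), run_dir=str(run))
        lines = (run / "metrics.jsonl").read_text().strip().splitlines()
        assert len(lines) == 2
        rec = json.loads(lines[-1])
        assert {"epoch", "total", "l1", "kl"} <= set(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
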