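"""Training objective: subset-specific ELBOs, their average over all
non-empty modality subsets, the practical L1 + GAN + KL loss, and the loop.

For a subset pi of observed modalities the bound couples (i) reconstruction
terms for *all* M modalities — available and missing alike, which is what
makes every synthesis direction supervised by one objective — with (ii) one
KL per latent level: the coarsest against the standard-Normal prior, the
finer ones against the model's conditional priors computed in the same
top-down pass. All expectations are estimated with the single reparameterised
sample drawn by that pass. At each training iteration the losses of all
2^M - 1 subsets are averaged with equal weight.

The practical loss works in per-pixel units: L1 is the mean absolute error,
the GAN term the mean patch binary cross-entropy, and the per-level KL sums
are divided by the pixel count. Relative L1:KL weighting is identical to the
literal sum-over-pixels form with an unweighted KL (a global scale Adam is
insensitive to); the GAN:L1 ratio follows the Pix2Pix convention. The
adversarial weight is held at zero for the first ``gan_warmup_fraction`` of
epochs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

from .autodiff import Tensor, bce_with_logits
from .config import HierarchyConfig, TrainConfig
from .gaussians import kl_divergence, log_density, DiagonalGaussian
from .network import (
    Adam,
    ModalityBatch,
    MultimodalHVAE,
    load_checkpoint,
    save_checkpoint,
)

__all__ = [
    "enumerate_subsets",
    "elbo_terms",
    "full_elbo",
    "training_loss",
    "gan_losses",
    "gan_warmup_epochs",
    "effective_lambda_gan",
    "train",
    "LossReport",
    "ElboReport",
]


def enumerate_subsets(num_modalities: int) -> list[tuple]:
    """All non-empty subsets of {0..M-1}, smallest first, lexicographic within size."""
    if num_modalities < 1:
        raise ValueError("need at least one modality")
    out = []
    for size in range(1, num_modalities + 1):
        out.extend(combinations(range(num_modalities), size))
    return out


@dataclass
class ElboReport:
    """One subset-specific ELBO evaluation (nats, averaged over the batch)."""

    subset: tuple
    recon: list        # per-modality E_q[log p(x_i | z_1)]
    kl: list           # per-level KL, coarse-to-fine (level L first)
    elbo: float
    tensor: Optional[Tensor] = None  # differentiable ELBO node


def elbo_terms(model: MultimodalHVAE, batch: ModalityBatch,
               decoder_sigma: float = 1.0,
               rng: Optional[np.random.Generator] = None,
               noises: Optional[list] = None,
               mode: str = "sample") -> ElboReport:
    """Subset-specific ELBO with Normal(sigma) image decoders.

    The availability subset is taken from ``batch.available``; reconstruction
    covers all M modalities. One reparameterised sample estimates every
    expectation (``noises`` pins it for oracle comparisons).
    """
    states, feature = model.infer_hierarchy(batch, mode=mode, rng=rng, noises=noises)
    decoded = model.decode_images(feature)
    B = batch.batch_size
    sigma2 = decoder_sigma ** 2
    recon_terms = []
    for i in range(batch.num_modalities):
        g = DiagonalGaussian(decoded[i], Tensor(np.full(decoded[i].shape,
                                                        math.log(sigma2), np.float32)))
        recon_terms.append(log_density(g, batch.modality(i)) * (1.0 / B))
    kl_terms = [kl_divergence(s.posterior, s.prior) * (1.0 / B) for s in states]
    elbo = recon_terms[0]
    for t in recon_terms[1:]:
        elbo = elbo + t
    for t in kl_terms:
        elbo = elbo - t
    return ElboReport(
        subset=batch.available,
        recon=[float(t.data) for t in recon_terms],
        kl=[float(t.data) for t in kl_terms],
        elbo=float(elbo.data),
        tensor=elbo,
    )


def full_elbo(model: MultimodalHVAE, batch: ModalityBatch, **kwargs) -> ElboReport:
    """The complete-set bound: the subset bound evaluated at pi = {1..M}."""
    return elbo_terms(model, batch.restrict(range(batch.num_modalities)), **kwargs)


def gan_warmup_epochs(config: TrainConfig) -> int:
    """Number of initial epochs with the adversarial weight forced to zero."""
    return int(round(config.gan_warmup_fraction * config.epochs))


def effective_lambda_gan(config: TrainConfig, epoch: int) -> float:
    return 0.0 if epoch < gan_warmup_epochs(config) else config.lambda_gan


def gan_losses(discriminator, real, fake) -> tuple[Tensor, Tensor]:
    """Vanilla (BCE) PatchGAN objectives.

    Returns ``(generator_term, discriminator_term)``: the discriminator pushes
    real patches toward 1 and (detached) fake patches toward 0; the generator
    pushes fake patches toward 1.
    """
    fake_t = fake if isinstance(fake, Tensor) else Tensor(np.asarray(fake, np.float32))
    real_t = real if isinstance(real, Tensor) else Tensor(np.asarray(real, np.float32))
    if real_t.shape != fake_t.shape:
        raise ValueError("real/fake shape mismatch")
    gen_term = bce_with_logits(discriminator(fake_t), 1.0)
    disc_term = 0.5 * (bce_with_logits(discriminator(real_t), 1.0)
                       + bce_with_logits(discriminator(fake_t.detach()), 0.0))
    return gen_term, disc_term


@dataclass
class LossReport:
    """Per-iteration loss decomposition across modality subsets."""

    per_subset: dict = field(default_factory=dict)
    total: float = 0.0
    effective_lambda_gan: float = 0.0
    lambda_l1: float = 0.0
    tensor: Optional[Tensor] = None        # differentiable total (generator side)
    generated: dict = field(default_factory=dict)  # subset -> (B, M, 1, H, W) ndarray
    disc: Optional[list] = None            # per-modality discriminator losses

    def check_consistency(self, tol: float = 1e-6) -> None:
        """Verify the total equals the documented weighted sum of its parts."""
        subtotals = []
        for entry in self.per_subset.values():
            s = (self.lambda_l1 * sum(entry["l1"])
                 + self.effective_lambda_gan * sum(entry["gan"])
                 + sum(entry["kl"]))
            if abs(s - entry["total"]) > tol * max(1.0, abs(s)):
                raise AssertionError(f"subset total inconsistent: {s} vs {entry['total']}")
            subtotals.append(entry["total"])
        mean = sum(subtotals) / len(subtotals)
        if abs(mean - self.total) > tol * max(1.0, abs(mean)):
            raise AssertionError(f"total inconsistent: {mean} vs {self.total}")


def training_loss(model: MultimodalHVAE, batch: ModalityBatch, config: TrainConfig,
                  epoch: int, rng: Optional[np.random.Generator] = None,
                  noises_per_subset: Optional[dict] = None) -> LossReport:
    """The practical loss averaged over every non-empty modality subset.

    For each subset pi: encode only x_pi, decode all M modalities, and
    accumulate lambda_l1 * L1 + lambda_gan * generator-GAN + KL (per-pixel
    units). ``batch`` must carry the complete image set.
    """
    M = batch.num_modalities
    subsets = enumerate_subsets(M)
    lam_gan = effective_lambda_gan(config, epoch)
    n_pixels = float(np.prod(batch.images.shape[2:]))
    report = LossReport(effective_lambda_gan=lam_gan, lambda_l1=config.lambda_l1)
    total = None
    # bottom-up features are subset-independent: encode each modality once and
    # share the (differentiable) features across all subset passes
    feats = {i: model.bottom_up(batch.modality(i), i) for i in range(M)}
    for pi in subsets:
        sub = batch.restrict(pi)
        noises = noises_per_subset.get(pi) if noises_per_subset else None
        states, feature = model.infer_hierarchy(sub, mode="sample", rng=rng, noises=noises,
                                                precomputed_feats=feats)
        decoded = model.decode_images(feature)
        B = batch.batch_size
        l1_terms, gan_terms = [], []
        for i in range(M):
            target = Tensor(batch.modality(i))
            l1_terms.append((decoded[i] - target).abs().mean())
            if lam_gan > 0:
                gan_terms.append(bce_with_logits(
                    model.discriminate(decoded[i], i), 1.0))
        kl_terms = [kl_divergence(s.posterior, s.prior) * (1.0 / (B * n_pixels))
                    for s in states]
        sub_total = None
        for t in l1_terms:
            term = t * config.lambda_l1
            sub_total = term if sub_total is None else sub_total + term
        for t in gan_terms:
            sub_total = sub_total + t * lam_gan
        for t in kl_terms:
            sub_total = sub_total + t
        report.per_subset[pi] = {
            "l1": [float(t.data) for t in l1_terms],
            "gan": [float(t.data) for t in gan_terms] if gan_terms else [0.0] * M,
            "kl": [float(t.data) for t in kl_terms],
            "total": float(sub_total.data),
        }
        report.generated[pi] = np.stack([d.data.copy() for d in decoded], axis=1)
        total = sub_total if total is None else total + sub_total
    total = total * (1.0 / len(subsets))
    report.total = float(total.data)
    report.tensor = total
    return report


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(dataset, hierarchy: HierarchyConfig, config: TrainConfig,
          run_dir: Optional[str] = None,
          resume_from: Optional[str] = None,
          progress: bool = False):
    """Train a unified model on a paired dataset.

    ``dataset`` is any object exposing ``images`` with shape
    (n, M, 1, H, W) in [-1, 1] (see :mod:`poehvae.synthdata`). Alternates
    generator and discriminator updates (the discriminator only once the
    adversarial weight is nonzero), logs one JSONL record per epoch, and
    checkpoints into ``run_dir`` when given. Fully reproducible from
    ``config.seed``.

    Returns ``(model, history)`` with one dict per epoch.
    """
    images = np.asarray(dataset.images, dtype=np.float32)
    if images.shape[0] == 0:
        raise ValueError("empty dataset")
    n = images.shape[0]
    M = images.shape[1]

    seed_seq = np.random.SeedSequence(config.seed)
    init_rng, order_rng, noise_rng = (np.random.default_rng(s)
                                      for s in seed_seq.spawn(3))
    start_epoch = 0
    if resume_from is not None:
        model, _, extras = load_checkpoint(resume_from)
        start_epoch = extras["epoch"]
        gen_opt = Adam(model.generator_parameters(), lr=config.learning_rate,
                       betas=config.adam_betas)
        disc_opt = Adam(model.discriminator_parameters(), lr=config.learning_rate,
                        betas=config.adam_betas)
        if "optimizer_state" in extras:
            gen_opt.load_state_dict(extras["optimizer_state"])
        if "disc_optimizer_state" in extras:
            disc_opt.load_state_dict(extras["disc_optimizer_state"])
        # replay the consumed random streams so resuming continues the sequence
        for _ in range(start_epoch):
            order_rng.permutation(n)
        _advance_noise_stream(noise_rng, model.config, images.shape, config, start_epoch, n)
    else:
        model = MultimodalHVAE(hierarchy, init_rng)
        gen_opt = Adam(model.generator_parameters(), lr=config.learning_rate,
                       betas=config.adam_betas)
        disc_opt = Adam(model.discriminator_parameters(), lr=config.learning_rate,
                        betas=config.adam_betas)

    log_path = None
    if run_dir is not None:
        os.makedirs(run_dir, exist_ok=True)
        log_path = os.path.join(run_dir, "metrics.jsonl")

    full_set = tuple(range(M))
    history = []
    epochs = range(start_epoch, config.epochs)
    if progress:
        from tqdm import tqdm
        epochs = tqdm(epochs, desc="train")
    for epoch in epochs:
        order = order_rng.permutation(n)
        lam_gan = effective_lambda_gan(config, epoch)
        epoch_terms: dict[str, float] = {}
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch = ModalityBatch(images[idx], full_set)
            model.zero_grad()
            report = training_loss(model, batch, config, epoch, rng=noise_rng)
            if not np.isfinite(report.total):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {report.per_subset}")
            report.tensor.backward()
            gen_opt.step()
            disc_vals = []
            if lam_gan > 0:
                fakes = report.generated[full_set]
                for i in range(M):
                    model.zero_grad()
                    _, disc_term = gan_losses(model.discriminators[i],
                                              batch.modality(i), fakes[:, i])
                    disc_term.backward()
                    disc_opt.step()
                    disc_vals.append(float(disc_term.data))
            _accumulate_epoch_terms(epoch_terms, report, disc_vals)
            report.tensor = None  # release the autodiff graph before the next step
            report.generated.clear()
            n_batches += 1
        record = {k: v / n_batches for k, v in epoch_terms.items()}
        record.update(epoch=epoch, effective_lambda_gan=lam_gan)
        history.append(record)
        if log_path is not None:
            with open(log_path, "a") as f:
                f.write(json.dumps(record) + "\n")
        if run_dir is not None and config.checkpoint_every and \
                (epoch + 1) % config.checkpoint_every == 0:
            save_checkpoint(os.path.join(run_dir, f"checkpoint_{epoch + 1:05d}.npz"),
                            model, config, epoch=epoch + 1,
                            optimizer=gen_opt, disc_optimizer=disc_opt)
    if run_dir is not None:
        save_checkpoint(os.path.join(run_dir, "checkpoint_final.npz"),
                        model, config, epoch=config.epochs,
                        optimizer=gen_opt, disc_optimizer=disc_opt)
    return model, history


def _accumulate_epoch_terms(acc: dict, report: LossReport, disc_vals: list):
    acc["total"] = acc.get("total", 0.0) + report.total
    l1 = np.mean([sum(e["l1"]) for e in report.per_subset.values()])
    kl = np.mean([sum(e["kl"]) for e in report.per_subset.values()])
    gan = np.mean([sum(e["gan"]) for e in report.per_subset.values()])
    acc["l1"] = acc.get("l1", 0.0) + float(l1)
    acc["kl"] = acc.get("kl", 0.0) + float(kl)
    acc["gan"] = acc.get("gan", 0.0) + float(gan)
    if disc_vals:
        acc["disc"] = acc.get("disc", 0.0) + float(np.mean(disc_vals))


def _advance_noise_stream(rng, hierarchy: HierarchyConfig, images_shape,
                          config: TrainConfig, epochs_done: int, n: int):
    """Skip the noise draws a finished run would have consumed (for resume)."""
    M = images_shape[1]
    subsets = enumerate_subsets(M)
    sizes = [(c,) + s for c, s in zip(hierarchy.channels, hierarchy.spatial_sizes)]
    for _ in range(epochs_done):
        for lo in range(0, n, config.batch_size):
            b = min(config.batch_size, n - lo)
            for _pi in subsets:
                for cs in reversed(sizes):
                    rng.standard_normal((b,) + cs)
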