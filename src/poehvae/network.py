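"""The hierarchical multi-modal architecture.

One model holds, for each of the M modalities, a bottom-up (contracting)
encoder producing a deterministic feature map per latent level, and shares a
single top-down (expansive) path that walks the hierarchy coarse-to-fine:
at each level it emits the conditional prior p(z_l | z_{>l}), merges the
per-modality bottom-up features with the top-down context into one Gaussian
expert per *available* modality, fuses prior and experts by product-of-
experts, samples (or takes the mean of) the fused posterior, and feeds the
latent back into the shared context. The finest context is decoded by one
independent ResNet image decoder per modality, so all M images are produced
no matter which subset was observed. A per-modality PatchGAN discriminator
supports the adversarial reconstruction term.

Levels are numbered 1 (finest, image resolution) to L (coarsest, a 1x1
global code with an isotropic standard-Normal prior); internal lists are
finest-first, index ``l - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat, upsample_nearest
from .config import HierarchyConfig, TrainConfig
from .gaussians import (
    LOG_VAR_MAX,
    LOG_VAR_MIN,
    DiagonalGaussian,
    poe_fuse,
    sample,
)
from .nn import Adam, Conv2d, InvertedResidualCell, Module, PatchDiscriminator, ResNetBlock

__all__ = [
    "ModalityBatch",
    "LatentLevelState",
    "MultimodalHVAE",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_FORMAT",
]

CHECKPOINT_FORMAT = "poehvae-checkpoint-1"


@dataclass
class ModalityBatch:
    """A batch of co-registered images plus the availability subset.

    ``images`` has shape (batch, M, 1, H, W) with intensities in [-1, 1];
    ``available`` lists the 0-based indices of the modalities presented to
    the encoders (non-empty; shared across the batch).
    """

    images: np.ndarray
    available: tuple

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 5 or self.images.shape[2] != 1:
            raise ValueError("images must have shape (batch, M, 1, H, W)")
        if self.images.min() < -1.0 - 1e-6 or self.images.max() > 1.0 + 1e-6:
            raise ValueError("pixel values must lie in [-1, 1]")
        self.available = tuple(sorted(set(int(i) for i in self.available)))
        if not self.available:
            raise ValueError("available modality subset must be non-empty")
        M = self.images.shape[1]
        if any(i < 0 or i >= M for i in self.available):
            raise ValueError("available indices out of range")

    @property
    def batch_size(self) -> int:
        return self.images.shape[0]

    @property
    def num_modalities(self) -> int:
        return self.images.shape[1]

    def restrict(self, available: Sequence[int]) -> "ModalityBatch":
        """Same images, different availability subset."""
        return ModalityBatch(self.images, tuple(available))

    def modality(self, i: int) -> np.ndarray:
        return self.images[:, i]


@dataclass
class LatentLevelState:
    """Per-level inference record: prior, experts, fused posterior, latent."""

    level: int
    prior: DiagonalGaussian
    experts: dict
    posterior: DiagonalGaussian
    z: Tensor


class _Transition(Module):
    """Encoder step from one level's resolution to the next-coarser one."""

    def __init__(self, cin, cout, src, dst, rng):
        super().__init__()
        if dst == (1, 1) and src != (2, 2):
            self.kind = "pool"
            self.conv = Conv2d(cin, cout, 1, rng, padding=0)
        else:
            self.kind = "stride2"
            self.conv = Conv2d(cin, cout, 3, rng, stride=2, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        if self.kind == "pool":
            return self.conv(x.mean(axis=(2, 3), keepdims=True)).swish()
        return self.conv(x).swish()


class _Encoder(Module):
    """Bottom-up path of one modality: a feature map per latent level."""

    def __init__(self, cfg: HierarchyConfig, rng):
        super().__init__()
        self.cfg = cfg
        L = cfg.num_levels
        self.stem = Conv2d(1, cfg.channels[0], 3, rng)
        cells, transitions = [], []
        cur_size = cfg.base_image_size
        cur_c = cfg.channels[0]
        pre = None
        if L == 1 or cfg.spatial_sizes[0] != cfg.base_image_size:
            # degenerate single-level config: reduce straight to the coarsest code
            pre = _Transition(cur_c, cfg.channels[0], cur_size, cfg.spatial_sizes[0], rng)
            cur_size = cfg.spatial_sizes[0]
        self.pre = pre if pre is not None else Module()
        self._has_pre = pre is not None
        for idx in range(L):
            cells.append(InvertedResidualCell(cfg.channels[idx], rng,
                                              cfg.expansion_ratio, cfg.se_reduction))
            if idx < L - 1:
                transitions.append(_Transition(cfg.channels[idx], cfg.channels[idx + 1],
                                               cfg.spatial_sizes[idx],
                                               cfg.spatial_sizes[idx + 1], rng))
        self.cells = cells
        self.transitions = transitions

    def __call__(self, x: Tensor) -> list:
        cfg = self.cfg
        if x.shape[2:] != cfg.base_image_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} != base_image_size {cfg.base_image_size}")
        h = self.stem(x).swish()
        if self._has_pre:
            h = self.pre(h)
        feats = []
        for idx in range(cfg.num_levels):
            h = self.cells[idx](h)
            feats.append(h)
            if idx < cfg.num_levels - 1:
                h = self.transitions[idx](h)
        return feats


class _TopDownStep(Module):
    """Shared expansive step from level l+1's context to level l's context."""

    def __init__(self, cfg: HierarchyConfig, idx: int, rng):
        super().__init__()
        cin, cout = cfg.channels[idx + 1], cfg.channels[idx]
        self.factor = cfg.spatial_sizes[idx][0] // cfg.spatial_sizes[idx + 1][0]
        self.expand = Conv2d(cin, cout, 3, rng)
        self.cell = InvertedResidualCell(cout, rng, cfg.expansion_ratio, cfg.se_reduction)

    def __call__(self, h: Tensor) -> Tensor:
        h = upsample_nearest(h, self.factor)
        return self.cell(self.expand(h).swish())


class _Decoder(Module):
    """Per-modality image decoder: ResNet blocks ending in a tanh head.

    With ``decoder_trunk_stride > 1`` the ResNet trunk runs at reduced
    resolution between a strided entry conv and a nearest upsample before the
    output head (a compute saving used by the desk-scale preset).
    """

    def __init__(self, cfg: HierarchyConfig, rng):
        super().__init__()
        self.upsample_factor = cfg.base_image_size[0] // cfg.spatial_sizes[0][0]
        self.trunk_stride = cfg.decoder_trunk_stride
        self.head_in = Conv2d(cfg.channels[0], cfg.decoder_channels, 3, rng,
                              stride=self.trunk_stride)
        self.blocks = [ResNetBlock(cfg.decoder_channels, rng)
                       for _ in range(cfg.decoder_resnet_blocks)]
        self.head_out = Conv2d(cfg.decoder_channels, 1, 3, rng)

    def __call__(self, h: Tensor) -> Tensor:
        if self.upsample_factor > 1:
            h = upsample_nearest(h, self.upsample_factor)
        h = self.head_in(h).swish()
        for blk in self.blocks:
            h = blk(h)
        if self.trunk_stride > 1:
            h = upsample_nearest(h, self.trunk_stride)
        return self.head_out(h).tanh()


def _gaussian_from_head(stats: Tensor, channels: int) -> DiagonalGaussian:
    mean = stats.slice_channels(0, channels)
    log_var = stats.slice_channels(channels, 2 * channels).clamp(LOG_VAR_MIN, LOG_VAR_MAX)
    return DiagonalGaussian(mean, log_var)


class MultimodalHVAE(Module):
    """Unified multi-modal hierarchical VAE; one model, every synthesis direction."""

    def __init__(self, config: HierarchyConfig, rng: np.random.Generator):
        super().__init__()
        cfg = self.config = config
        L, M = cfg.num_levels, cfg.num_modalities
        self.encoders = [_Encoder(cfg, rng) for _ in range(M)]
        # expert heads: per modality, per level. Level L sees the coarsest
        # bottom-up feature only; levels l < L see [feature, context].
        expert_heads = []
        for _ in range(M):
            heads = []
            for idx in range(L):
                cin = cfg.channels[idx] if idx == L - 1 else 2 * cfg.channels[idx]
                heads.append(Conv2d(cin, 2 * cfg.channels[idx], 1, rng, padding=0))
            expert_heads.append(heads)
        self.expert_heads = [h for heads in expert_heads for h in heads]
        self._expert_heads = expert_heads
        # prior heads for levels l < L, zero-initialised so an untrained
        # top-down path emits standard-Normal conditional priors.
        self.prior_heads = [
            Conv2d(cfg.channels[idx], 2 * cfg.channels[idx], 1, rng, padding=0, zero_init=True)
            for idx in range(L - 1)
        ]
        self.z_init = Conv2d(cfg.channels[L - 1], cfg.channels[L - 1], 1, rng, padding=0)
        self.merge = [Conv2d(2 * cfg.channels[idx], cfg.channels[idx], 1, rng, padding=0)
                      for idx in range(L - 1)]
        self.steps = [_TopDownStep(cfg, idx, rng) for idx in range(L - 1)]
        self.decoders = [_Decoder(cfg, rng) for _ in range(M)]
        # keep the patch logit map spatial even for small image sizes
        n_strided = max(1, min(3, cfg.base_image_size[0].bit_length() - 4))
        self.discriminators = [
            PatchDiscriminator(rng, 1, cfg.disc_base_channels, n_strided=n_strided)
            for _ in range(M)]

    # -- generator/discriminator parameter split ---------------------------
    def generator_parameters(self) -> list:
        disc = {id(p) for d in self.discriminators for p in d.parameters()}
        return [p for p in self.parameters() if id(p) not in disc]

    def discriminator_parameters(self) -> list:
        return [p for d in self.discriminators for p in d.parameters()]

    # -- spec'd operations --------------------------------------------------
    def bottom_up(self, x_i, modality: int) -> list:
        """Encode one modality into L feature maps, finest-first."""
        x = x_i if isinstance(x_i, Tensor) else Tensor(np.asarray(x_i, np.float32))
        return self.encoders[modality](x)

    def expert_at_level(self, features_i: Tensor, top_down_context: Optional[Tensor],
                        level: int, modality: int) -> DiagonalGaussian:
        """Unimodal variational expert q_i(z_l | x_i, z_{>l}) at one level."""
        L = self.config.num_levels
        idx = level - 1
        if not 1 <= level <= L:
            raise ValueError(f"level must be in 1..{L}")
        head = self._expert_heads[modality][idx]
        if level == L:
            stats = head(features_i)
        else:
            if top_down_context is None:
                raise ValueError("levels below the coarsest require top-down context")
            stats = head(concat([features_i, top_down_context], axis=1))
        return _gaussian_from_head(stats, self.config.channels[idx])

    def prior_at_level(self, top_down_context: Optional[Tensor], level: int,
                       batch_size: int = 1) -> DiagonalGaussian:
        """Conditional prior p(z_l | z_{>l}); exactly N(0, I) at the top."""
        L = self.config.num_levels
        idx = level - 1
        if not 1 <= level <= L:
            raise ValueError(f"level must be in 1..{L}")
        if level == L:
            c = self.config.channels[idx]
            h, w = self.config.spatial_sizes[idx]
            zeros = np.zeros((batch_size, c, h, w), np.float32)
            return DiagonalGaussian(Tensor(zeros), Tensor(zeros.copy()))
        if top_down_context is None:
            raise ValueError("levels below the coarsest require top-down context")
        stats = self.prior_heads[idx](top_down_context)
        return _gaussian_from_head(stats, self.config.channels[idx])

    def infer_hierarchy(self, batch: ModalityBatch, mode: str = "sample",
                        rng: Optional[np.random.Generator] = None,
                        noises: Optional[list] = None,
                        precomputed_feats: Optional[dict] = None):
        """Walk the hierarchy coarse-to-fine, fusing experts at every level.

        Returns ``(states, final_feature)`` with states listed coarse-to-fine
        (level L first). ``mode='mean'`` takes every posterior mean;
        ``mode='sample'`` draws reparameterised samples using ``rng`` or the
        explicit per-level ``noises`` list (coarse-to-fine).
        """
        if mode not in ("sample", "mean"):
            raise ValueError("mode must be 'sample' or 'mean'")
        cfg = self.config
        L = cfg.num_levels
        if precomputed_feats is not None:
            feats = {i: precomputed_feats[i] for i in batch.available}
        else:
            feats = {i: self.bottom_up(batch.modality(i), i) for i in batch.available}
        B = batch.batch_size
        states: list[LatentLevelState] = []
        context = None
        h = None
        for n, level in enumerate(range(L, 0, -1)):
            idx = level - 1
            prior = self.prior_at_level(context, level, batch_size=B)
            experts = {
                i: self.expert_at_level(feats[i][idx], context, level, i)
                for i in batch.available
            }
            posterior = poe_fuse(prior, list(experts.values()))
            if mode == "mean":
                z = posterior.mean
            else:
                if noises is not None:
                    eps = noises[n]
                elif rng is not None:
                    eps = rng.standard_normal(
                        (B, cfg.channels[idx]) + cfg.spatial_sizes[idx]).astype(np.float32)
                else:
                    raise ValueError("sample mode needs rng or explicit noises")
                z = sample(posterior, noise=eps)
            states.append(LatentLevelState(level, prior, experts, posterior, z))
            # feed the latent into the shared top-down context
            if level == L:
                h = self.z_init(z).swish()
            else:
                h = self.merge[idx](concat([context, z], axis=1)).swish()
            if level > 1:
                context = self.steps[idx - 1](h)
        return states, h

    def decode_images(self, final_feature: Tensor) -> list:
        """Decode the finest context into all M modality images in [-1, 1]."""
        return [dec(final_feature) for dec in self.decoders]

    def discriminate(self, images, modality: int) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, np.float32))
        return self.discriminators[modality](x)

    def synthesize_arrays(self, batch: ModalityBatch, mode: str = "mean",
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Convenience forward pass returning (batch, M, 1, H, W) ndarray."""
        _, feature = self.infer_hierarchy(batch, mode=mode, rng=rng)
        outs = self.decode_images(feature)
        return np.stack([o.data for o in outs], axis=1)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: MultimodalHVAE, train_config: TrainConfig,
                    epoch: int = 0, optimizer: Optional[Adam] = None,
                    disc_optimizer: Optional[Adam] = None):
    """Serialise model weights + configs (+ optimizer state) to one archive."""
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    payload["meta/format"] = np.array(CHECKPOINT_FORMAT)
    payload["meta/epoch"] = np.array(epoch)
    payload["meta/hierarchy"] = np.array(json.dumps(model.config.to_dict()))
    payload["meta/train"] = np.array(json.dumps(train_config.to_dict()))
    if optimizer is not None:
        payload.update({f"opt/{k}": v for k, v in optimizer.state_dict().items()})
    if disc_optimizer is not None:
        payload.update({f"dopt/{k}": v for k, v in disc_optimizer.state_dict().items()})
    with open(path, "wb") as f:
        np.savez(f, **payload)


def load_checkpoint(path):
    """Restore a model (and configs) saved by :func:`save_checkpoint`.

    Returns ``(model, train_config, extras)`` where ``extras`` carries the
    epoch and any optimizer state dicts.
    """
    with np.load(path, allow_pickle=False) as data:
        fmt = str(data["meta/format"])
        if fmt != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format: {fmt}")
        hier = HierarchyConfig.from_dict(json.loads(str(data["meta/hierarchy"])))
        train = TrainConfig.from_dict(json.loads(str(data["meta/train"])))
        model = MultimodalHVAE(hier, np.random.default_rng(0))
        model.load_state_dict(
            {k[len("model/"):]: data[k] for k in data.files if k.startswith("model/")})
        extras = {"epoch": int(data["meta/epoch"])}
        for prefix, key in (("opt/", "optimizer_state"), ("dopt/", "disc_optimizer_state")):
            sub = {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            if sub:
                extras[key] = sub
    return model, train, extras
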