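"""Model and training configuration.

Two presets matter in practice:

* ``HierarchyConfig.paper_scale()`` — the full-size architecture: 192x192
  inputs, L = 7 latent levels, spatial size halving per level down to a
  1x1x256 coarsest latent (the final step via global pooling), channel widths
  doubling coarse-ward from 8 to 256, 5-ResNet-block image decoders.
* ``HierarchyConfig.desk_scale()`` — a reduced geometry (64x64, L = 5) with
  the same structure, sized so that CPU smoke training on synthetic pairs
  finishes in minutes. Used throughout the tests and examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = ["HierarchyConfig", "TrainConfig"]


def _halving_sizes(base: int, levels: int) -> list[tuple[int, int]]:
    sizes = []
    s = base
    for _ in range(levels - 1):
        sizes.append((s, s))
        s //= 2
    sizes.append((1, 1))  # coarsest level reached via global pooling
    return sizes


@dataclass
class HierarchyConfig:
    """Architecture hyperparameters of the latent hierarchy.

    ``spatial_sizes`` and ``channels`` are listed finest-first (level 1 at
    index 0, level L last); spatial sizes strictly decrease and the coarsest
    level is 1x1, so the coarsest latent is a global code as in non-
    hierarchical multi-modal VAEs.
    """

    num_levels: int = 7
    base_image_size: tuple[int, int] = (192, 192)
    spatial_sizes: list = field(default_factory=lambda: _halving_sizes(192, 7))
    channels: list = field(default_factory=lambda: [8, 8, 16, 32, 64, 128, 256])
    num_modalities: int = 2
    expansion_ratio: int = 6
    se_reduction: int = 16
    decoder_resnet_blocks: int = 5
    decoder_channels: int = 32
    decoder_trunk_stride: int = 1  # >1: run the ResNet trunk at reduced resolution
    disc_base_channels: int = 64

    def __post_init__(self):
        self.base_image_size = tuple(self.base_image_size)
        self.spatial_sizes = [tuple(s) for s in self.spatial_sizes]
        L = self.num_levels
        if L < 1:
            raise ValueError("num_levels must be >= 1")
        if len(self.spatial_sizes) != L or len(self.channels) != L:
            raise ValueError("spatial_sizes and channels must have num_levels entries")
        for a, b in zip(self.spatial_sizes, self.spatial_sizes[1:]):
            if not (b[0] < a[0] and b[1] < a[1]) and a != b:
                raise ValueError("spatial_sizes must strictly decrease finest-to-coarsest")
        if self.spatial_sizes[-1] != (1, 1):
            raise ValueError("coarsest spatial size must be (1, 1)")
        if L > 1 and self.spatial_sizes[0] != self.base_image_size:
            raise ValueError("finest spatial size must equal base_image_size")
        if self.num_modalities < 1:
            raise ValueError("num_modalities must be >= 1")

    @classmethod
    def paper_scale(cls, num_modalities: int = 2) -> "HierarchyConfig":
        return cls(num_modalities=num_modalities)

    @classmethod
    def desk_scale(cls, num_modalities: int = 2, num_levels: int = 5,
                   base: int = 64) -> "HierarchyConfig":
        channels = [max(8, 128 >> (num_levels - 1 - i)) for i in range(num_levels)]
        return cls(
            num_levels=num_levels,
            base_image_size=(base, base),
            spatial_sizes=_halving_sizes(base, num_levels),
            channels=channels,  # [8, 16, 32, 64, 128] at the default depth
            num_modalities=num_modalities,
            expansion_ratio=2,
            se_reduction=8,
            decoder_resnet_blocks=2,
            decoder_channels=16,
            decoder_trunk_stride=2,
            disc_base_channels=16,
        )

    @classmethod
    def tiny(cls, num_modalities: int = 2, num_levels: int = 3,
             base: int = 16) -> "HierarchyConfig":
        """Smallest config that still exercises every code path (unit tests)."""
        return cls(
            num_levels=num_levels,
            base_image_size=(base, base),
            spatial_sizes=_halving_sizes(base, num_levels),
            channels=[4] * num_levels if num_levels > 1 else [8],
            num_modalities=num_modalities,
            expansion_ratio=2,
            se_reduction=4,
            decoder_resnet_blocks=1,
            decoder_channels=8,
            disc_base_channels=8,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the reference protocol: L1 weight 100, GAN weight 1,
    1000 epochs at batch size 16 with the adversarial term switched on only
    for the final 20% of epochs; Adam with learning rate 1e-4. ``decoder_sigma``
    is the standard deviation of the Normal decoding distribution used by the
    pure-ELBO objective (it is absorbed into the L1/GAN weights in the
    practical loss).
    """

    lambda_l1: float = 100.0
    lambda_gan: float = 1.0
    gan_warmup_fraction: float = 0.8
    epochs: int = 1000
    batch_size: int = 16
    decoder_sigma: float = 1.0
    seed: int = 0
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    checkpoint_every: int = 0  # 0: final checkpoint only

    def __post_init__(self):
        if self.lambda_l1 < 0 or self.lambda_gan < 0:
            raise ValueError("loss weights must be nonnegative")
        if not (0.0 <= self.gan_warmup_fraction <= 1.0):
            raise ValueError("gan_warmup_fraction must lie in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.decoder_sigma <= 0:
            raise ValueError("decoder_sigma must be positive")
        self.adam_betas = tuple(self.adam_betas)

    @classmethod
    def smoke(cls, epochs: int = 20, seed: int = 0) -> "TrainConfig":
        """Desk-scale smoke-training settings: fewer epochs, a larger learning
        rate suited to the small networks, adversarial term off."""
        return cls(epochs=epochs, lambda_gan=0.0, learning_rate=1e-3, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def config_to_json(hier: HierarchyConfig, train: TrainConfig) -> str:
    return json.dumps({"hierarchy": hier.to_dict(), "train": train.to_dict()})


def config_from_json(s: str) -> tuple[HierarchyConfig, TrainConfig]:
    d = json.loads(s)
    return HierarchyConfig.from_dict(d["hierarchy"]), TrainConfig.from_dict(d["train"])
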