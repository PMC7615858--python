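"""Synthetic paired-modality image generator.

Emulates the structure of co-registered pre-operative MR / intra-operative
ultrasound slice pairs without any clinical data: each scene is a smooth
random "tissue" field with a few elliptical lesion inclusions, rendered twice
by modality-specific pipelines that share the geometry but differ in contrast
mapping and noise character —

* modality A ("MR-like"): a monotone gamma-style contrast curve, a
  low-frequency multiplicative bias field, and mild additive Gaussian noise;
* modality B ("US-like"): a different, non-affine contrast curve and
  spatially correlated multiplicative speckle (squared filtered Gaussian,
  i.e. an intensity-scaled Rayleigh-like texture).

Because both renders are deterministic functions of the same anatomy plus
independent noise, the cross-modal mapping is learnable; a trained model must
beat the trivial per-pixel mean-image predictor. All outputs are normalised
to [-1, 1] and satisfy the :class:`~poehvae.network.ModalityBatch` contract
directly. Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imageio import write_image

__all__ = [
    "SceneSpec",
    "make_anatomy",
    "render_modality_a",
    "render_modality_b",
    "make_pair",
    "generate_pairs",
    "PairedDataset",
    "make_dataset",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene family.

    Defaults are sized for 64x64 desk-scale experiments: a handful of smooth
    background blobs, up to three lesions with a clear intensity offset,
    moderate MR noise (SNR well above 20 dB) and speckle strong enough to
    raise local variance visibly without drowning the anatomy.
    """

    image_size: int = 64
    num_blobs: int = 6
    lesion_count_range: tuple = (0, 3)
    lesion_radius_range: tuple = (4, 10)
    lesion_contrast: float = 0.35
    blob_sigma_range: tuple = (6.0, 14.0)
    noise_level: float = 0.02        # additive Gaussian sd on the [0,1] MR render
    bias_field_strength: float = 0.08
    speckle_strength: float = 0.35   # mixing weight of the speckle texture
    speckle_sigma: float = 1.0       # spatial correlation of the speckle
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16 px")


def make_anatomy(spec: SceneSpec, rng: np.random.Generator | None = None):
    """Build one scene: a smooth tissue field in [0, 1] plus lesion inclusions.

    Returns ``(field, lesion_mask)``. Deterministic for a given spec (and
    seed); pass an external ``rng`` to draw a sequence of distinct scenes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    field = np.zeros((s, s))
    for _ in range(spec.num_blobs):
        cy, cx = rng.uniform(0, s, 2)
        sig = rng.uniform(*spec.blob_sigma_range)
        amp = rng.uniform(0.3, 1.0)
        field += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2)))
    # squash smoothly into [0, 1]
    field -= field.min()
    if field.max() > 0:
        field /= field.max()
    field = 0.15 + 0.7 * field
    mask = np.zeros((s, s), dtype=bool)
    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    for _ in range(n_lesions):
        cy, cx = rng.uniform(0.2 * s, 0.8 * s, 2)
        ry = rng.uniform(*spec.lesion_radius_range)
        rx = rng.uniform(*spec.lesion_radius_range)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        m = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        mask |= m
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    field = np.where(mask, np.clip(field + sign * spec.lesion_contrast, 0, 1), field)
    return field, mask


def _to_signed(img01: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * img01 - 1.0, -1.0, 1.0).astype(np.float32)


def render_modality_a(anatomy: np.ndarray, spec: SceneSpec,
                      rng: np.random.Generator | None = None,
                      noiseless: bool = False) -> np.ndarray:
    """MR-like render: gamma contrast + bias field + additive noise, in [-1, 1]."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    img = np.power(np.clip(anatomy, 0, 1), 0.7)
    if not noiseless:
        bias = gaussian_filter(rng.standard_normal(anatomy.shape),
                               sigma=spec.image_size / 4)
        bias = 1.0 + spec.bias_field_strength * bias / (np.abs(bias).max() + 1e-12)
        img = img * bias
        img = img + spec.noise_level * rng.standard_normal(anatomy.shape)
    return _to_signed(img)


def render_modality_b(anatomy: np.ndarray, spec: SceneSpec,
                      rng: np.random.Generator | None = None,
                      noiseless: bool = False) -> np.ndarray:
    """US-like render: smoothstep contrast + correlated multiplicative speckle."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    t = np.clip(anatomy, 0, 1)
    img = t * t * (3.0 - 2.0 * t)  # smoothstep: non-affine in the MR contrast
    if not noiseless:
        g = gaussian_filter(rng.standard_normal(anatomy.shape), sigma=spec.speckle_sigma)
        g /= g.std() + 1e-12
        speckle = g * g  # squared Gaussian: exponential-like intensity speckle
        img = img * (1.0 - spec.speckle_strength + spec.speckle_strength * speckle)
    return _to_signed(img)


def make_pair(spec: SceneSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """One paired sample shaped (2, 1, H, W): [MR-like, US-like]."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    anatomy, _ = make_anatomy(spec, rng)
    a = render_modality_a(anatomy, spec, rng)
    b = render_modality_b(anatomy, spec, rng)
    return np.stack([a[None], b[None]], axis=0)


@dataclass
class PairedDataset:
    """In-memory paired dataset: ``images`` (n, M, 1, H, W) plus a split."""

    images: np.ndarray
    split: np.ndarray = None  # 'train' / 'test' per sample

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.split is None:
            self.split = np.array(["train"] * len(self.images))

    def subset(self, name: str) -> "PairedDataset":
        sel = self.split == name
        return PairedDataset(self.images[sel], self.split[sel])

    def __len__(self):
        return len(self.images)


def generate_pairs(n: int, spec: SceneSpec, test_fraction: float = 0.0) -> PairedDataset:
    """Draw n independent paired scenes; optionally tag a deterministic split."""
    rng = np.random.default_rng(spec.seed)
    images = np.stack([make_pair(spec, rng) for _ in range(n)], axis=0)
    split = np.array(["train"] * n)
    if test_fraction > 0:
        n_test = int(round(test_fraction * n))
        test_idx = rng.permutation(n)[:n_test]
        split[test_idx] = "test"
    return PairedDataset(images, split)


def make_dataset(n: int, spec: SceneSpec, out_dir: str,
                 test_fraction: float = 0.2, fmt: str = "png") -> pd.DataFrame:
    """Write n paired images to disk plus a manifest CSV.

    Images go out as 16-bit grayscale PNG (or NIfTI with ``fmt='nifti'``)
    with [-1, 1] mapped linearly onto the integer range; the manifest has
    columns id, path_modality_a, path_modality_b, split and is returned as a
    DataFrame. Byte-identical across re-runs with the same spec.
    """
    ds = generate_pairs(n, spec, test_fraction=test_fraction)
    os.makedirs(out_dir, exist_ok=True)
    ext = {"png": "png", "nifti": "nii.gz"}[fmt]
    rows = []
    for k in range(n):
        pa = os.path.join(out_dir, f"{k:04d}_a.{ext}")
        pb = os.path.join(out_dir, f"{k:04d}_b.{ext}")
        write_image(pa, ds.images[k, 0, 0])
        write_image(pb, ds.images[k, 1, 0])
        rows.append({"id": f"{k:04d}", "path_modality_a": os.path.basename(pa),
                     "path_modality_b": os.path.basename(pb), "split": ds.split[k]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
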