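"""Missing-modality synthesis and full-reference image-quality metrics.

``synthesize`` runs a trained model on any non-empty subset of modalities and
returns all M decoded images — reconstruction for the modalities that were
given, synthesis for the ones that were withheld. ``evaluate`` scores every
(input subset, target modality) direction on a paired test set with PSNR and
SSIM, laying the rows out the way unified-synthesis comparisons are usually
tabulated (available modalities marked with a filled dot, missing with an
open one).

PSNR uses data range 2 by default ([-1, 1] images); SSIM uses the standard
constants C1 = (0.01 R)^2, C2 = (0.03 R)^2 over 7x7 uniform windows with
sample (N-1) covariance normalisation, matching the common reference
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .network import ModalityBatch, MultimodalHVAE
from .objective import enumerate_subsets

__all__ = ["SynthesisResult", "synthesize", "psnr", "ssim", "evaluate",
           "mean_image_baseline", "PSNR_CAP"]

# reported when the test image equals the reference exactly (MSE = 0)
PSNR_CAP = 100.0


@dataclass
class SynthesisResult:
    """All M generated images for one input subset."""

    images: np.ndarray          # (batch, M, 1, H, W), values in [-1, 1]
    subset: tuple               # modality indices that were observed
    mode: str                   # 'mean' or 'sample'

    def modality(self, i: int) -> np.ndarray:
        return self.images[:, i]


def synthesize(model: MultimodalHVAE, available: dict, mode: str = "mean",
               rng: np.random.Generator | None = None) -> SynthesisResult:
    """Synthesize the missing modalities from the available ones.

    ``available`` maps modality index -> image array (H, W) or batch
    (B, 1, H, W), normalised to [-1, 1]. Mean mode (default) is fully
    deterministic; sample mode draws the hierarchy's latents from ``rng``.
    """
    if not available:
        raise ValueError("need at least one available modality")
    M = model.config.num_modalities
    imgs = {}
    batch_size = None
    for i, img in available.items():
        arr = np.asarray(img, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        if np.abs(arr).max() > 1.0 + 1e-6:
            raise ValueError("input images must be normalised to [-1, 1]")
        imgs[int(i)] = arr
        batch_size = arr.shape[0]
    full = np.zeros((batch_size, M, 1) + model.config.base_image_size, np.float32)
    for i, arr in imgs.items():
        full[:, i] = arr
    batch = ModalityBatch(full, tuple(imgs))
    out = model.synthesize_arrays(batch, mode=mode, rng=rng)
    return SynthesisResult(images=out, subset=batch.available, mode=mode)


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 2.0) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(R^2 / MSE); capped at
    ``PSNR_CAP`` dB for identical images."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("psnr: shape mismatch")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return min(PSNR_CAP, 10.0 * np.log10(data_range ** 2 / mse))


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float = 2.0,
         win_size: int = 7) -> float:
    """Mean local structural similarity over uniform windows.

    Local means/variances/covariance come from a ``win_size`` uniform filter
    with sample (N-1) covariance normalisation; the mean is taken over the
    valid (pad-cropped) region.
    """
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("ssim: shape mismatch")
    if x.ndim != 2:
        x, y = np.squeeze(x), np.squeeze(y)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    n = win_size ** 2
    cov_norm = n / (n - 1)
    ux = uniform_filter(x, size=win_size)
    uy = uniform_filter(y, size=win_size)
    uxx = uniform_filter(x * x, size=win_size)
    uyy = uniform_filter(y * y, size=win_size)
    uxy = uniform_filter(x * y, size=win_size)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / \
        ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def _subset_code(subset: tuple, M: int) -> str:
    return "".join("•" if i in subset else "◦" for i in range(M))


def evaluate(model: MultimodalHVAE, dataset, mode: str = "mean",
             rng: np.random.Generator | None = None,
             batch_size: int = 16) -> pd.DataFrame:
    """Score every (input subset, target modality) direction on a paired set.

    Returns a table with one row per direction: the subset encoded with
    filled (available) / open (missing) dots, and mean +/- sd of PSNR (dB)
    and SSIM (%) over the set.
    """
    images = np.asarray(dataset.images, dtype=np.float32)
    if images.shape[0] == 0:
        raise ValueError("empty test set")
    M = images.shape[1]
    rows = []
    for subset in enumerate_subsets(M):
        scores: dict = {i: {"psnr": [], "ssim": []} for i in range(M)}
        for lo in range(0, images.shape[0], batch_size):
            chunk = images[lo:lo + batch_size]
            batch = ModalityBatch(chunk, subset)
            out = model.synthesize_arrays(batch, mode=mode, rng=rng)
            for k in range(chunk.shape[0]):
                for i in range(M):
                    ref = chunk[k, i, 0]
                    gen = np.clip(out[k, i, 0], -1, 1)
                    scores[i]["psnr"].append(psnr(ref, gen))
                    scores[i]["ssim"].append(ssim(ref, gen))
        for i in range(M):
            rows.append({
                "input_subset": _subset_code(subset, M),
                "target_modality": i,
                "role": "reconstruction" if i in subset else "synthesis",
                "psnr_mean": float(np.mean(scores[i]["psnr"])),
                "psnr_sd": float(np.std(scores[i]["psnr"])),
                "ssim_mean_pct": float(100 * np.mean(scores[i]["ssim"])),
                "ssim_sd_pct": float(100 * np.std(scores[i]["ssim"])),
            })
    return pd.DataFrame(rows)


def mean_image_baseline(train_dataset, test_dataset, data_range: float = 2.0) -> dict:
    """Trivial predictor: the per-pixel mean training image of each modality.

    Returns per-modality mean PSNR/SSIM of that constant prediction on the
    test set — the floor any learned cross-modal synthesis must beat.
    """
    train = np.asarray(train_dataset.images, dtype=np.float64)
    test = np.asarray(test_dataset.images, dtype=np.float64)
    M = train.shape[1]
    out = {}
    for i in range(M):
        mean_img = train[:, i, 0].mean(axis=0)
        ps = [psnr(test[k, i, 0], mean_img, data_range) for k in range(test.shape[0])]
        ss = [ssim(test[k, i, 0], mean_img, data_range) for k in range(test.shape[0])]
        out[i] = {"psnr": float(np.mean(ps)), "ssim": float(np.mean(ss))}
    return out
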