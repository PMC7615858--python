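"""Diagonal-Gaussian algebra: KL divergence, product-of-experts fusion,
reparameterised sampling, and log-density.

These are the probabilistic primitives of the hierarchy. Every prior,
per-modality expert and fused posterior is a factorised Normal over a
channel x height x width lattice, stored as (mean, log-variance). Fusion of a
prior with a set of unimodal experts is the normalised product of the factor
densities: precisions add, and the fused mean is the precision-weighted
average of the factor means scaled by the fused covariance.

Functions accept either plain NumPy arrays or autodiff ``Tensor``s and return
the matching kind, so the same algebra serves closed-form oracles (float64
arrays) and the differentiable training graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LOG_VAR_MIN",
    "LOG_VAR_MAX",
    "DiagonalGaussian",
    "kl_divergence",
    "poe_fuse",
    "sample",
    "log_density",
    "standard_normal",
]

# Clamp range for network-produced log-variances; keeps exp() finite in float32.
LOG_VAR_MIN = -14.0
LOG_VAR_MAX = 14.0

ArrayLike = Union[np.ndarray, Tensor]


def _data(x: ArrayLike) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _exp(x: ArrayLike):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def _log(x: ArrayLike):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _sum(x: ArrayLike) -> float | Tensor:
    return x.sum() if isinstance(x, Tensor) else float(np.sum(x))


@dataclass
class DiagonalGaussian:
    """Factorised Normal with diagonal covariance stored as log-variance.

    ``mean`` and ``log_var`` share one shape — typically (channels, H, W) per
    sample or (batch, channels, H, W) inside the network — and all entries of
    ``log_var`` must be finite so the variance is strictly positive.
    """

    mean: ArrayLike
    log_var: ArrayLike

    def __post_init__(self):
        m, lv = _data(self.mean), _data(self.log_var)
        if m.shape != lv.shape:
            raise ValueError(f"mean shape {m.shape} != log_var shape {lv.shape}")
        if not np.all(np.isfinite(lv)):
            raise ValueError("log_var must be finite (variance strictly positive)")

    @property
    def shape(self):
        return _data(self.mean).shape

    def detach(self) -> "DiagonalGaussian":
        """Numeric copy outside any autodiff graph."""
        return DiagonalGaussian(_data(self.mean).copy(), _data(self.log_var).copy())


def standard_normal(shape, dtype=np.float64) -> DiagonalGaussian:
    """N(0, I) over the given lattice shape."""
    z = np.zeros(shape, dtype=dtype)
    return DiagonalGaussian(z, z.copy())


def _check_same_shape(*gs: DiagonalGaussian):
    shapes = {g.shape for g in gs}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch between Gaussians: {sorted(shapes)}")


def kl_divergence(q: DiagonalGaussian, p: DiagonalGaussian):
    """Closed-form KL[q || p] summed over all lattice sites.

    Per site: 0.5 * (var_q/var_p + (mu_q - mu_p)^2/var_p - 1 + log var_p - log var_q).
    Nonnegative; zero iff q == p elementwise.
    """
    _check_same_shape(q, p)
    dlv = q.log_var - p.log_var
    inv_vp = _exp(-p.log_var if isinstance(p.log_var, Tensor) else -np.asarray(p.log_var))
    diff = q.mean - p.mean
    term = _exp(dlv) + diff * diff * inv_vp - 1.0 - dlv
    return 0.5 * _sum(term)


def poe_fuse(prior: DiagonalGaussian, experts: Sequence[DiagonalGaussian]) -> DiagonalGaussian:
    """Product-of-experts fusion of a prior with zero or more unimodal experts.

    Returns the normalised product of all Gaussian factors: the fused precision
    is the sum of factor precisions and the fused mean is the fused covariance
    times the precision-weighted sum of factor means. With no experts the
    prior is returned unchanged (empty product).

    Computed in precision space on the log-variances; one log at the end.
    """
    experts = list(experts)
    _check_same_shape(prior, *experts)
    if not experts:
        return prior
    neg = lambda lv: -lv if isinstance(lv, Tensor) else -np.asarray(lv)
    prec = _exp(neg(prior.log_var))
    wsum = prec * prior.mean
    for e in experts:
        pe = _exp(neg(e.log_var))
        prec = prec + pe
        wsum = wsum + pe * e.mean
    fused_log_var = -_log(prec)
    fused_mean = wsum / prec
    return DiagonalGaussian(fused_mean, fused_log_var)


def sample(g: DiagonalGaussian, noise: ArrayLike | None = None,
           rng: np.random.Generator | None = None, mean_mode: bool = False):
    """Reparameterised draw: mean + exp(0.5 * log_var) * eps.

    ``noise`` supplies the standard-Normal eps directly; otherwise it is drawn
    from ``rng``. ``mean_mode=True`` returns the mean exactly (the
    deterministic zero-variance limit).
    """
    if mean_mode:
        return g.mean
    if noise is None:
        if rng is None:
            raise ValueError("sample needs either explicit noise or an rng")
        noise = rng.standard_normal(g.shape)
    eps = _data(noise)
    if eps.shape != g.shape:
        raise ValueError(f"noise shape {eps.shape} != Gaussian shape {g.shape}")
    std = _exp(0.5 * g.log_var)
    return g.mean + std * eps


def log_density(g: DiagonalGaussian, x: ArrayLike):
    """Sum over sites of the univariate Normal log-density at x."""
    xd = _data(x)
    if xd.shape != g.shape:
        raise ValueError(f"x shape {xd.shape} != Gaussian shape {g.shape}")
    diff = x - g.mean
    inv_v = _exp(-g.log_var if isinstance(g.log_var, Tensor) else -np.asarray(g.log_var))
    term = g.log_var + diff * diff * inv_v + np.log(2.0 * np.pi)
    return -0.5 * _sum(term)
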