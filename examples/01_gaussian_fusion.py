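"""Product-of-experts fusion of diagonal Gaussians.

Builds a standard-Normal prior and two disagreeing unimodal experts, fuses
them, and shows that precisions add while the mean is a precision-weighted
compromise — the operation the model applies at every latent level.
"""

import numpy as np

from poehvae import DiagonalGaussian, kl_divergence, poe_fuse


def gaussian(mean, var):
    return DiagonalGaussian(np.array([mean]), np.log(np.array([var])))


prior = gaussian(0.0, 1.0)
expert_mr = gaussian(2.0, 0.5)    # confident expert pulling up
expert_us = gaussian(-1.0, 4.0)   # vague expert pulling down

fused = poe_fuse(prior, [expert_mr, expert_us])
mean, var = fused.mean[0], np.exp(fused.log_var[0])
print(f"fused mean     = {mean:+.4f}")
print(f"fused variance = {var:.4f}")
print(f"precisions     : prior 1.0 + expert 2.0 + expert 0.25 = {1/var:.2f}")
print(f"KL(fused || prior) = {kl_divergence(fused, prior):.4f} nats")

# The fused mean sits near the confident expert; the fused variance is
# smaller than any single factor's because every expert adds precision.
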