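# poehvae

**Unified missing-modality medical image synthesis with a multi-modal
hierarchical VAE and product-of-experts fusion.**

Clinical imaging routinely produces *incomplete* sets of co-registered
images: intra-operative ultrasound (iUS) is cheap but hard to read, while
intra-operative MR is often unavailable, so one wants to synthesize the
missing modality from whatever was acquired. Conditional GANs can do this,
but need one trained network per synthesis direction. `poehvae` implements
the unified alternative: a single hierarchical variational autoencoder that
encodes *any* non-empty subset of modalities into a shared hierarchy of
latent Gaussians and decodes *all* modalities back out — one model, every
direction, with a principled probabilistic fusion rule instead of ad-hoc
feature arithmetic.

## The model in brief

Images x = (x₁, …, x_M) are assumed conditionally independent given a
latent z split into L groups (finest z₁ … coarsest z_L):

    p_θ(x, z) = p(z_L) ∏_{l<L} p_θ(z_l | z_{>l}) · ∏_i p_θ(x_i | z₁),
    p(z_L) = N(0, I).

At every level the approximate posterior for an availability subset π is a
**product of experts**: the conditional prior times one Gaussian expert per
available modality,

    q(z_l | x_π, z_{>l}) ∝ p_θ(z_l | z_{>l}) ∏_{i∈π} q_i(z_l | x_i, z_{>l}),

closed-form for diagonal Gaussians (precisions add; the fused mean is the
precision-weighted average). Missing modalities simply contribute no
expert. Training averages the subset-specific evidence lower bound over
all 2^M − 1 subsets every iteration, so cross-modal supervision is always
on, and the practical loss replaces the Gaussian likelihood with
λ_L1·L1 + λ_GAN·PatchGAN terms (λ_L1 = 100, λ_GAN = 1, adversarial part
switched on only for the final 20% of epochs) plus the unweighted KL.

Everything runs on NumPy via a small reverse-mode autodiff engine built
into the package (`poehvae.autodiff`) — no deep-learning framework
required. See `docs/methods.md` for assumptions, parameters and
limitations, and the `examples/` scripts for runnable walkthroughs.

## Worked example

No clinical data is needed: `poehvae.synthdata` generates co-registered
pairs that share geometry but differ in contrast and noise character
(MR-like: smooth contrast + additive noise; US-like: different contrast +
multiplicative speckle). From `examples/03_train_and_synthesize.py`
(tiny 16×16 configuration, under a minute on a laptop CPU):

```
loss: epoch 0 116.98 -> epoch 14 61.17
MR reconstruction PSNR: 18.50 dB
US synthesis PSNR:      13.64 dB
```

The training loss falls, and reconstruction of the observed modality
scores above synthesis of the withheld one — the signature pattern of
subset-trained unified models. At the package's desk scale (64×64, L = 5
levels, 200 training pairs, 20 epochs, ~10 CPU-minutes) cross-modal
synthesis reaches roughly 27 dB (US→MR) and 17 dB (MR→US) on held-out
pairs, versus ~15 dB and ~12 dB for the trivial per-pixel mean-image
predictor.

The same workflows are available from the shell:

```bash
poehvae simulate --out-dir data --n 250 --seed 0
poehvae train --data data/manifest.csv --out run --epochs 20 --lambda-gan 0
poehvae synthesize --checkpoint run/checkpoint_final.npz \
    --input 0=data/0000_a.png --out-dir synth
poehvae evaluate --checkpoint run/checkpoint_final.npz \
    --data data/manifest.csv --out metrics.csv
```

## Package layout

| module | contents |
|---|---|
| `poehvae.gaussians` | diagonal-Gaussian algebra: KL, PoE fusion, sampling, log-density |
| `poehvae.network` | encoders, shared top-down hierarchy, decoders, PatchGAN, checkpoints |
| `poehvae.objective` | subset ELBOs, L1+GAN+KL loss, warm-up schedule, training loop |
| `poehvae.synthesis` | missing-modality synthesis, PSNR/SSIM, per-direction evaluation |
| `poehvae.synthdata` | synthetic paired-modality generator and fixture writer |
| `poehvae.autodiff` / `poehvae.nn` | NumPy reverse-mode autodiff and layers |
| `poehvae.cli` | `simulate` / `train` / `synthesize` / `evaluate` commands |
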