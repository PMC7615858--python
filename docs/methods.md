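# Methods

## Model

`poehvae` implements a multi-modal hierarchical variational autoencoder for
co-registered single-channel 2-D images of M modalities (M = 2 by default:
an "MR-like" and an "ultrasound-like" channel). The generative model assumes
the images x = (x_1, …, x_M) are conditionally independent given a latent
variable z partitioned into L groups z_1, …, z_L (finest to coarsest):

    p_θ(x, z) = p(z_L) ∏_{l<L} p_θ(z_l | z_{>l}) · ∏_i p_θ(x_i | z_1),

with p(z_L) = N(0, I) an isotropic Normal over a 1×1×C_L global code and
every conditional prior a factorised Normal with mean and log-variance
emitted by the shared top-down network. Image decoders are Normal with fixed
variance σ (in the practical loss the Gaussian likelihood is replaced by
L1 + adversarial terms, below).

Inference is bidirectional and ladder-style. Each available modality runs a
bottom-up convolutional encoder producing one deterministic feature map per
level; the shared top-down pass walks the hierarchy coarse to fine and, at
each level, forms one Gaussian *expert* per available modality from the
concatenation of that modality's bottom-up feature with the top-down
context (at the coarsest level, from the bottom-up feature alone). The
approximate posterior at each level is the product of experts (PoE)

    q(z_l | x_π, z_{>l}) ∝ p_θ(z_l | z_{>l}) · ∏_{i∈π} q_i(z_l | x_i, z_{>l}),

which for diagonal Gaussians is closed-form: precisions add, and the fused
mean is the fused covariance times the precision-weighted sum of factor
means. (Some presentations print the *inverse* fused covariance in the mean
formula; only the covariance itself yields the normalised product of
densities, which a numeric grid-product oracle in the test suite confirms,
so that form is implemented.) With zero experts the posterior reduces to
the prior, so any non-empty subset π of modalities is valid input and one
trained network serves every synthesis direction. Missing-modality
synthesis is simply inference on the available subset followed by decoding
all M images.

Setting L = 1 recovers a (multi-modal) VAE with a global PoE code;
L = 1, M = 1 is a plain VAE. Both are reachable purely by configuration and
are exercised in the tests.

## Objective

For a subset π the bound couples reconstruction of *all* M modalities with
one KL term per level: the coarsest against N(0, I), the finer ones against
the conditional priors computed in the same top-down pass. Every
expectation is estimated with the single reparameterised sample drawn by
that pass. At each training iteration the losses of all 2^M − 1 non-empty
subsets are computed (none are sampled) and averaged with equal weight
1/(2^M − 1); the empty subset is excluded because inference requires at
least one image and unconditional generation is not a goal.

The practical loss per subset is

    λ_L1 · Σ_i L1(μ_i, x_i) + λ_GAN · Σ_i L_GAN(μ_i) + KL,

with defaults λ_L1 = 100, λ_GAN = 1. Reductions are in per-pixel units: L1
is the mean absolute error, the GAN term the mean patch binary
cross-entropy, and the per-level KL sums are divided by the pixel count.
The L1:KL ratio is then identical to the literal sum-over-pixels form with
an unweighted KL sum (Adam is insensitive to the global scale), and the
GAN:L1 ratio follows the Pix2Pix convention. KL terms are not annealed or
re-weighted per level. The adversarial part uses one unconditional
PatchGAN discriminator per modality with the vanilla BCE objective
(real→1, fake→0 for the discriminator; fake→1 for the generator); the
discriminator sees detached images and is updated only when the effective
λ_GAN is nonzero. λ_GAN is forced to 0 for the first
`round(gan_warmup_fraction · epochs)` epochs (default fraction 0.8, i.e.
800 of 1000 reference epochs; 16 of 20 at smoke scale).

Optimisation is Adam (lr 1e-4, β = (0.9, 0.999)) for generator and
discriminators alike; the optimiser is unspecified in the reference
protocol and this is the conventional choice. The desk-scale smoke preset
(`TrainConfig.smoke`) raises the learning rate to 1e-3, which suits the
much smaller networks and short schedules.

## Architecture

Residual cells are MobileNetV2-style inverted residuals (1×1 expand,
depthwise 3×3, squeeze-and-excitation, 1×1 project) with Swish activations.
Normalisation layers are omitted; He fan-in initialisation keeps the small
networks stable without them. Spatial sizes halve per level with the final
step to the 1×1 coarsest code taken by global average pooling on the way up
and nearest-neighbour broadcast on the way down (the reference geometry
192 → 96 → 48 → 24 → 12 → 6 → 1 does not reach 1×1 by exact halving).
Channel widths halve coarse-to-fine from 256 with a floor of 8
([8, 8, 16, 32, 64, 128, 256] at L = 7). Prior heads are zero-initialised
1×1 convolutions, so an untrained top-down path emits standard-Normal
conditional priors; expert heads are randomly initialised. Network-emitted
log-variances are clamped to [−14, 14]. Image decoders are independent
per-modality ResNet stacks ending in tanh, bounding outputs to the [−1, 1]
intensity convention of the inputs.

Two presets matter:

* `paper_scale`: 192×192, L = 7, 256-channel coarsest code, 5 decoder
  ResNet blocks, expansion 6 — the reference geometry.
* `desk_scale`: 64×64, L = 5, channels [8, 16, 32, 64, 128], expansion 2,
  2 decoder blocks run at half resolution between a strided entry and a
  final upsample, 16-channel decoders. Sized so a complete training run on
  a few hundred synthetic pairs takes minutes of CPU; used by tests,
  examples and the acceptance script.

All tensors are float32; the tensor backend is a small tape-based
reverse-mode autodiff engine over NumPy written for this package
(`poehvae.autodiff`), with convolutions evaluated tap-wise as batched
channel-mixing matmuls. Its gradients are verified against central finite
differences in the test suite.

## Synthetic data

The generator (`poehvae.synthdata`) emulates the *structure* of paired
pre-operative MR / intra-operative ultrasound slices: each scene is a
smooth random blob field in [0, 1] with 0–3 elliptical lesion inclusions
offset by a configured contrast (default 0.35), rendered twice from the
same geometry. The MR-like render applies a gamma contrast curve (exponent
0.7), a low-frequency multiplicative bias field (8%) and additive Gaussian
noise (sd 0.02 on the [0, 1] scale); the US-like render applies a smoothstep
contrast curve (non-affine in the first) and spatially correlated
multiplicative speckle (squared filtered Gaussian, mixing weight 0.35,
correlation length 1 px). Defaults keep the speckle noise floor well above
20 dB PSNR so cross-modal synthesis quality is measurable, while scene
variability keeps the trivial per-pixel mean-image predictor weak; because
both renders are deterministic functions of one anatomy plus independent
noise, a trained model must beat that baseline.

What the generator does *not* reproduce: real ultrasound physics
(attenuation, shadowing, probe geometry), 3-D anatomy and registration
error, scanner-specific MR contrast, and pathology realism. Passing tests
therefore demonstrate that the machinery — hierarchy, fusion, subset
training, synthesis — works and learns cross-modal structure from paired
data; they say nothing about clinical image quality.

## Numerical and design notes

* Gaussians are stored as (mean, log-variance); fusion works in precision
  space with a single log at the end. Log-variances are validated finite.
* `sample` supports an exact "mean mode"; synthesis and evaluation default
  to it so metric tables are deterministic. Sampled synthesis is a flag.
* PSNR uses data range 2 for [−1, 1] images and is capped at 100 dB when
  the MSE is exactly zero. Users comparing against [0, 255] conventions
  must override the range. SSIM uses C1 = (0.01·R)², C2 = (0.03·R)², 7×7
  uniform windows, sample (N−1) covariance normalisation, and averages the
  pad-cropped valid region — matching scikit-image's uniform-window path to
  which it is tested equal.
* Training is reproducible from a single seed: one stream orders batches,
  one initialises weights, one drives the per-level reparameterisation
  noise; resuming a checkpoint replays consumed draws so a resumed run
  continues the original sequence exactly. A non-finite loss aborts with
  the offending decomposition.
* Checkpoints are single `.npz` archives holding all weights, both configs
  and optimiser state, tagged with a format version; loading restores
  bit-identical behaviour.
* The per-epoch loss log is JSONL with the effective λ_GAN recorded.

## Problem sizes used by tests and the acceptance script

Unit tests run on 16×16, L = 3 configurations. The learnability check and
the acceptance script train the desk-scale preset on 200 synthetic 64×64
pairs for 20 epochs at batch size 8 with λ_GAN = 0, then score PSNR/SSIM on
50 held-out pairs against the mean-training-image baseline. These sizes are
the package's smoke-scale defaults; the full reference protocol (192×192,
L = 7, 1000 epochs, batch 16, GAN on for the last 200 epochs) is expressed
by `HierarchyConfig.paper_scale()` and the `TrainConfig` defaults.

## Known limitations

* CPU-only float32 training; no mixed precision, no data parallelism.
* The "partially shared" bidirectional coupling is one admissible reading
  (concatenation + 1×1 merge of bottom-up features with the shared
  top-down context); layer counts per level are free parameters.
* No tempering of the expert product, no importance-weighted bounds, no
  subset subsampling for large M (all 2^M − 1 subsets are evaluated, so
  cost grows exponentially in M).
* LPIPS is not provided (it requires pretrained perceptual weights);
  statistical testing beyond per-case metric export is out of scope.
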