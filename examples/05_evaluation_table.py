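"""Per-direction evaluation table and the mean-image baseline.

Trains a tiny model briefly, then scores every (input subset, target
modality) combination on held-out pairs: filled dots mark observed
modalities, open dots missing ones. 'reconstruction' rows decode a modality
that was given as input; 'synthesis' rows decode one that was withheld.
"""

import numpy as np

from poehvae import (
    HierarchyConfig,
    SceneSpec,
    TrainConfig,
    evaluate,
    generate_pairs,
    mean_image_baseline,
    train,
)

ds = generate_pairs(50, SceneSpec(image_size=16, seed=4), test_fraction=0.2)
train_set, test_set = ds.subset("train"), ds.subset("test")

model, _ = train(train_set, HierarchyConfig.tiny(),
                 TrainConfig(epochs=10, batch_size=8, seed=0,
                             learning_rate=1e-3, lambda_gan=0.0))

table = evaluate(model, test_set)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

base = mean_image_baseline(train_set, test_set)
print("\nmean-training-image baseline (the floor a learned model must beat):")
for i, scores in base.items():
    print(f"  modality {i}: PSNR {scores['psnr']:.2f} dB, "
          f"SSIM {100 * scores['ssim']:.1f}%")
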