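import numpy as np
import pytest

import poehvae as p


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """A small random-weight model exercising every code path (16x16, L=3, M=2)."""
    cfg = p.HierarchyConfig.tiny()
    return p.MultimodalHVAE(cfg, np.random.default_rng(0))


@pytest.fixture(scope="session")
def tiny_batch():
    ds = p.generate_pairs(4, p.SceneSpec(image_size=16, seed=11))
    return p.ModalityBatch(ds.images, (0, 1))


@pytest.fixture(scope="session")
def smoke_run():
    """One desk-scale smoke training on synthetic pairs, shared by the
    learnability and metric-ordering acceptance checks.

    Conditions: 200 64x64 training pairs, L=5 hierarchy, adversarial term
    off, 20 epochs — a deliberately small but complete training run.
    """
    ds = p.generate_pairs(250, p.SceneSpec(seed=7), test_fraction=0.2)
    train_set, test_set = ds.subset("train"), ds.subset("test")
    cfg = p.HierarchyConfig.desk_scale()
    tcfg = p.TrainConfig.smoke(epochs=20, seed=0)
    tcfg.batch_size = 8
    model, history = p.train(train_set, cfg, tcfg)
    return {"model": model, "history": history,
            "train": train_set, "test": test_set}
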