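import numpy as np
import pytest

from mugennet.config import model_preset, run_preset
from mugennet.model import build_model
from mugennet.synthetic import PolypSceneSpec, generate_sample, sample_seed


def synthetic_batch(n=8, size=64, base_seed=7):
    """n synthetic image/mask pairs as stacked training arrays."""
    imgs, masks = [], []
    for i in range(n):
        img, mask = generate_sample(
            PolypSceneSpec(seed=sample_seed(base_seed, i), height=size, width=size))
        imgs.append(img.transpose(2, 0, 1).astype(np.float32) / 255.0)
        masks.append(mask.astype(np.float64))
    return np.stack(imgs), np.stack(masks)


@pytest.fixture(scope="session")
def desk_model():
    return build_model(model_preset("desk"))


@pytest.fixture(scope="session")
def train_batch():
    return synthetic_batch()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_pair(rng, h=16, w=16):
    """A random (continuous prediction, binary ground truth) pair."""
    pred = rng.random((h, w))
    gt = (rng.random((h, w)) < rng.uniform(0.1, 0.9)).astype(np.float64)
    return pred, gt
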