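import numpy as np
import pytest

from gastroql.data import LabeledImage, normalize_intensity
from gastroql.features import CNNConfig, PretrainConfig, build_cnn, pretrain_cnn
from gastroql.fixtures import FixtureSpec, classification_arrays, segmentation_arrays


@pytest.fixture(scope="session")
def class_fixture_small():
    """4-class separable texture/colour fixture, 20 images per class, 32x32."""
    spec = FixtureSpec(task="classification", num_classes=4, n_per_class=20,
                       image_size=32, seed=11)
    return classification_arrays(spec)


@pytest.fixture(scope="session")
def seg_fixture_small():
    """40 ellipse/mask pairs at 32x32 for fast segmentation tests."""
    spec = FixtureSpec(task="segmentation", n_images=40, image_size=32, seed=11)
    return segmentation_arrays(spec)


@pytest.fixture(scope="session")
def dark_bright_records():
    """Linearly separable two-class set: uniform dark vs uniform bright."""
    rng = np.random.default_rng(3)
    records = []
    for i in range(400):
        label = i % 2
        level = 40 if label == 0 else 210
        pix = np.clip(level + rng.normal(0, 5, (32, 32, 3)), 0, 255).astype(np.uint8)
        records.append(LabeledImage(pixels=pix, label=label, source_id=f"img{i}"))
    return records


@pytest.fixture(scope="session")
def trained_cnn_small(dark_bright_records):
    """A small frozen CNN pretrained on the dark/bright fixture."""
    model = build_cnn(CNNConfig(input_size=32, num_classes=2), seed=5)
    return pretrain_cnn(model, dark_bright_records,
                        PretrainConfig(epochs=3, seed=5))


@pytest.fixture()
def norm_images(class_fixture_small):
    x, y = class_fixture_small
    return np.stack([normalize_intensity(im) for im in x]), y
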