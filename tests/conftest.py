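import pytest

from mmfusion import GeneratorConfig, generate_dataset
from mmfusion.protocol import TrainConfig


@pytest.fixture(scope="session")
def small_binary_dataset():
    """120 patients, 32x32 images, moderate complementary signal."""
    cfg = GeneratorConfig(n_patients=120, image_size=32, seed=7,
                          signal_overlap=0.0)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_multilabel_dataset():
    cfg = GeneratorConfig(n_patients=80, image_size=32, seed=9,
                          task_mode="multilabel_sigmoid", n_classes=11,
                          vocab_size=160)
    return generate_dataset(cfg)


@pytest.fixture
def desk_config():
    return TrainConfig.desk_scale(epochs=3, seed=0)
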