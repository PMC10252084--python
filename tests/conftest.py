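import numpy as np
import pytest

from sheepface.data import generate_fixture_dataset
from sheepface.models import ModelConfig, build_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic face dataset shared across tests (2 identities)."""
    return generate_fixture_dataset(n_classes=2, n_per_class=6, image_size=160,
                                    seed=11)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The 5-identity benchmark fixture set at its default conditions."""
    return generate_fixture_dataset(n_classes=5, n_per_class=20, image_size=320,
                                    seed=7)


@pytest.fixture(scope="session")
def preset_models():
    """All ablation-grid variants built once at the 63-class setting."""
    names = ["yolov5s", "ghost_neck", "ghost_backbone", "ghost_all",
             "shufflenetv2", "lsr_yolo"]
    return {n: build_model(n) for n in names}


@pytest.fixture()
def small_cfg():
    return ModelConfig(nc=2, input_size=64)
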