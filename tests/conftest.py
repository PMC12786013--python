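import numpy as np
import pytest

from idfnet.fusion import IDFNet, ModelConfig
from idfnet.synthdata import SyntheticSpec, generate_dataset
from idfnet.training import TrainConfig, train, train_val_test_split


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """60 small cases, balanced, 2 cases per patient."""
    spec = SyntheticSpec(n_cases=60, image_size=32, cases_per_patient=2, seed=123)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(image_size=32, d_latent=16, d_fused=32, n_heads=4, seed=5)


@pytest.fixture(scope="session")
def untrained_model(tiny_model_config):
    return IDFNet(tiny_model_config)


@pytest.fixture(scope="session")
def desk_model():
    """A desk-scale model trained on clean synthetic data (shared across
    interpretability and missing-modality tests), with its splits."""
    spec = SyntheticSpec(n_cases=400, image_size=64, cases_per_patient=2, seed=42)
    dataset = generate_dataset(spec)
    tr, va, te = train_val_test_split(dataset, seed=42)
    train_cases = [dataset.cases[i] for i in tr]
    val_cases = [dataset.cases[i] for i in va]
    test_cases = [dataset.cases[i] for i in te]
    result = train(
        train_cases,
        val_cases,
        model_config=ModelConfig(seed=42),
        config=TrainConfig.desk(seed=42),
    )
    return {
        "result": result,
        "model": result.model,
        "train": train_cases,
        "val": val_cases,
        "test": test_cases,
        "dataset": dataset,
    }
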