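import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from nutrispec import (
    Dataset,
    TrainConfig,
    build_forward_model,
    calibrate_tau,
    fit,
    simulate_dataset,
)

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

# Unit tests run on a reduced grid (64 bands -> sandwich 64/32/16) so that
# training-based checks stay fast; full-width behaviour is exercised by the
# evaluation-scale tests.
N_BANDS = 64


@pytest.fixture(scope="session")
def fwd_model():
    return build_forward_model({"n_bands": N_BANDS}, seed=1)


@pytest.fixture(scope="session")
def small_dataset(fwd_model):
    """60 labeled foods, 5 replicate regions each."""
    return simulate_dataset(fwd_model, n_foods=60, n_regions=5, seed=2)


@pytest.fixture(scope="session")
def train_test_split(small_dataset):
    train = Dataset(small_dataset.samples[:48], small_dataset.grid)
    test = small_dataset.samples[48:]
    return train, test


@pytest.fixture(scope="session")
def trained_proposed(train_test_split):
    train, _ = train_test_split
    return fit(train, TrainConfig(variant="proposed", epochs=150, seed=0))


@pytest.fixture(scope="session")
def trained_multimodal(train_test_split):
    train, _ = train_test_split
    return fit(train, TrainConfig(variant="multimodal", epochs=150, seed=0))


@pytest.fixture(scope="session")
def small_calibration(train_test_split):
    train, _ = train_test_split
    return calibrate_tau(train)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
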