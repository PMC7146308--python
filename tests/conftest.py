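import numpy as np
import pytest

from wearhar.features import ACC_FEATURES, feature_matrix
from wearhar.hierarchy import fit_hierarchy
from wearhar.synthetic import band_of, default_activity_specs, generate_dataset

TRAIN_WINDOWS_PER_CLASS = 150
TEST_WINDOWS_PER_CLASS = 50
TRAIN_SEED = 20260
TEST_SEED = 977
MODEL_SEED = 424242


@pytest.fixture(scope="session")
def train_set():
    """Balanced synthetic training windows: 9 activities x 150 windows."""
    specs = default_activity_specs()
    return generate_dataset(specs, TRAIN_WINDOWS_PER_CLASS, TRAIN_SEED)


@pytest.fixture(scope="session")
def test_set():
    """Held-out windows generated from an independent seed."""
    specs = default_activity_specs()
    return generate_dataset(specs, TEST_WINDOWS_PER_CLASS, TEST_SEED)


@pytest.fixture(scope="session")
def model(train_set):
    """The two-tier hierarchy trained on the synthetic fixture."""
    windows, labels = train_set
    return fit_hierarchy(windows, labels, seed=MODEL_SEED)


@pytest.fixture(scope="session")
def test_features(test_set):
    """All-sensor feature matrix and label arrays for the held-out windows."""
    windows, labels = test_set
    X = feature_matrix(windows, list(ACC_FEATURES) + ["gyr_mean_x"])
    bands = np.array([band_of(a) for a in labels], dtype=object)
    return X, np.asarray(labels, dtype=object), bands
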