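import numpy as np
import pytest

from focalbeat import SyntheticConfig, generate_patients, prepare_dataset


@pytest.fixture(scope="session")
def synthetic_split():
    """Inter-patient synthetic benchmark: 18 training patients, 6 held-out.

    ~6,700 training beats with the benchmark-like class imbalance
    (~89.5% N / 2.8% SVEB / 6.9% VEB / 0.8% F); test records come from
    patients (seeds, resting rates, amplitudes) never seen in training.
    """
    base = SyntheticConfig(duration_s=300.0, seed=0)
    train_set = prepare_dataset(generate_patients(18, base, seed=100))
    test_set = prepare_dataset(generate_patients(6, base, seed=200))
    return {"train": train_set, "test": test_set}


@pytest.fixture(scope="session")
def balanced_small_set():
    """Small balanced 4-class set for fast learnability/reproducibility tests."""
    base = SyntheticConfig(
        duration_s=150.0, seed=0, class_proportions=(0.25, 0.25, 0.25, 0.25)
    )
    return prepare_dataset(generate_patients(4, base, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
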