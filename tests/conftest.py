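import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from moonpep.forest import train_forest
from moonpep.synth import SynthParams, generate_synthetic_dataset

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_sequences(rng, n, min_len=5, max_len=50):
    from moonpep.scales import AMINO_ACIDS
    aa = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(aa, size=int(rng.integers(min_len, max_len + 1))))
            for _ in range(n)]


@pytest.fixture(scope="session")
def rule_dataset():
    """Small rule-labeled synthetic dataset shared across tests."""
    return generate_synthetic_dataset(
        SynthParams(n_pos=60, n_neg=60, label_rule="by_descriptor_rule",
                    seed=11)).dataset


@pytest.fixture(scope="session")
def small_model(rule_dataset):
    """A modest fitted featurize+forest pipeline for plumbing tests."""
    return train_forest(rule_dataset, n_trees=60, random_state=11)
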