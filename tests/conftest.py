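import numpy as np
import pytest

from quadnb import (
    MeripDataset,
    SimulationConfig,
    estimate_size_factors,
    simulate,
)


@pytest.fixture(scope="session")
def sim_seed7():
    """A 1000-feature simulated dataset used by the estimator oracle tests."""
    config = SimulationConfig(n_features=1000, seed=7)
    dataset, truth = simulate(config)
    return dataset, truth


@pytest.fixture(scope="session")
def sim_seed7_factors(sim_seed7):
    dataset, _ = sim_seed7
    return estimate_size_factors(dataset, "geometric")


@pytest.fixture()
def tiny_dataset():
    """3 features x 4 replicates, hand-written counts."""
    return MeripDataset(
        feature_ids=("f1", "f2", "f3"),
        ip_counts=np.array([[6, 12, 4, 8], [3, 3, 3, 3], [0, 0, 5, 5]]),
        input_counts=np.array([[4, 8, 6, 2], [1, 1, 1, 1], [0, 0, 5, 5]]),
        conditions=("A", "A", "B", "B"),
    )
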