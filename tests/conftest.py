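import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sparsepk as sp
from sparsepk.lstm_ann import ArchitectureSpec, TrainConfig, build_model, train
from sparsepk.poppk import CategoricalEffect
from sparsepk.preprocessing import prepare

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_dataset():
    """200-subject dataset at the default (olanzapine-like) parameters."""
    dataset, truth = sp.simulate_dataset(200, seed=42)
    return dataset, truth


@pytest.fixture(scope="session")
def smoking_dataset():
    """300 subjects with a strong smoking effect (clearance x1.5)."""
    params = sp.default_pop_params()
    params.categorical_effects.append(CategoricalEffect("SMOK", 1.0, 1.5))
    dataset, truth = sp.simulate_dataset(300, pop_params=params, seed=77)
    return dataset, truth


@pytest.fixture(scope="session")
def smoking_split(smoking_dataset):
    dataset, _ = smoking_dataset
    return prepare(dataset)


@pytest.fixture(scope="session")
def smoking_model(smoking_split):
    """Reference-architecture LSTM-ANN trained on the smoking-effect data.

    40 epochs keep the fit fast while leaving ample signal; shared by the
    learning-sanity and importance-ranking checks.
    """
    cfg = TrainConfig(learning_rate=0.000125, epochs=40, seed=1)
    return train(build_model(ArchitectureSpec(), seed=1), smoking_split, cfg)
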