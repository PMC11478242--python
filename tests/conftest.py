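import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cannclass import SimConfig, generate_dataset, train_cascade
from cannclass.cascade import default_cascade_config


def light_cascade_config():
    """Cascade config with a small GA budget for fast unit-level training."""
    cfg = default_cascade_config()
    for node_cfg in cfg.nodes.values():
        node_cfg.ga.population_size = 16
        node_cfg.ga.max_generations = 8
    return cfg


@pytest.fixture(scope="session")
def noiseless_small():
    """Small noiseless dataset: classes linearly separable by construction."""
    cfg = SimConfig.noiseless(n_train_per_class=8, n_test_per_class=4, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_small):
    train, _ = noiseless_small
    return train_cascade(train, light_cascade_config(), seed=3)
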