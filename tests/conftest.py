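"""Shared fixtures: desk-scale configs and pre-trained ensembles.

Heavy artifacts (subject pools, trained ensembles) are session-scoped so the
whole suite trains as few networks as possible.
"""

import numpy as np
import pytest

from patshortcut.experiments import PROFILES, ExperimentConfig, build_pools, default_plans
from patshortcut.modeling import train_ensemble


@pytest.fixture(scope="session")
def fast_config() -> ExperimentConfig:
    """The desk-scale audit condition: 32x32 images, shortcut dial at 0.8."""
    cfg = PROFILES["fast"]
    return cfg.replace(generator=cfg.generator.replace(overlap=0.8), master_seed=0)


@pytest.fixture(scope="session")
def tiny_config(fast_config) -> ExperimentConfig:
    """Minimal structural-test condition: 1-member ensembles, few epochs."""
    return fast_config.replace(
        n_models=1, n_iter=20, n_runs_disparity=1, n_runs_representation=5,
        n_ood_per_sex=6, max_epochs=6, patience=3,
    )


@pytest.fixture(scope="session")
def pools(fast_config):
    return build_pools(fast_config)


@pytest.fixture(scope="session")
def plans(fast_config):
    return default_plans(fast_config)


@pytest.fixture(scope="session")
def disease_ensemble_pr1(fast_config, pools, plans):
    train_pool, val_pool, _ = pools
    return train_ensemble(
        train_pool, val_pool, plans[1], task="disease",
        spec=fast_config.make_spec("disease"), n_models=2, master_seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
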