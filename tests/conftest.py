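import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import hergfit as hf
from hergfit import regressor as reg


@pytest.fixture(scope="session")
def staircase():
    return hf.build_default_staircase()


@pytest.fixture(scope="session")
def lit_theta():
    return hf.literature_params()


@pytest.fixture(scope="session")
def small_dataset():
    """80 prior-drawn noisy training examples at the default pipeline settings."""
    return hf.generate_dataset(80, seed=123)


@pytest.fixture(scope="session")
def training_corpus():
    """The desk-scale training corpus: ~2,000 prior-drawn examples."""
    full = hf.generate_dataset(2000, seed=42)
    train = reg._subset(full, 1800)
    val = hf.Dataset(traces=full.traces[1800:], targets=full.targets[1800:],
                     theta=full.theta[1800:], manifest=dict(full.manifest))
    return train, val


@pytest.fixture(scope="session")
def trained_model(training_corpus):
    """Regressor trained with the two-stage resolution schedule."""
    train, val = training_corpus
    cfg = hf.RegressorConfig(
        seed=0,
        stage_schedule=(
            reg.StageSpec(resolution=(97, 97), n_examples=1200, epochs=60),
            reg.StageSpec(resolution=(129, 129), n_examples=None, epochs=40),
        ),
    )
    return reg.train(cfg, train, val)
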