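import numpy as np
import pytest

from daedsr import GeneratorConfig, generate_registry
from daedsr.util import make_survival_target


@pytest.fixture(scope="session")
def small_registry():
    """120-trial registry with default missingness, fixed seed."""
    cfg = GeneratorConfig(n_trials=120, seed=42)
    return cfg, generate_registry(cfg)


@pytest.fixture(scope="session")
def clean_registry():
    """200-trial registry without missing cells (and no noise), fixed seed."""
    cfg = GeneratorConfig(n_trials=200, missing_rate=0.0, noise_sd=0.0, seed=7)
    return cfg, generate_registry(cfg)


@pytest.fixture()
def survival_y():
    return make_survival_target
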