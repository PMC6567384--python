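import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poachmort as pm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    """Published-estimate parameter presets and generating structures."""
    params = {s: pm.study_preset(s)[0] for s in "MF"}
    structures = {s: pm.study_preset(s)[1] for s in "MF"}
    return params, structures


@pytest.fixture(scope="session")
def study_dataset(presets):
    """One study-scale simulated dataset (141 animals, 11 occasions)."""
    params, _ = presets
    return pm.simulate_histories(pm.default_design(), params, seed=20260929)


@pytest.fixture(scope="session")
def big_dataset(presets):
    """A large surrogate dataset for estimation smoke tests."""
    params, _ = presets
    return pm.simulate_histories(pm.scaled_design(800), params, seed=7)
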