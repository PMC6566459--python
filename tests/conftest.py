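import numpy as np
import pytest

from subpoptests import ModelSpec, NestedDesign, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def step_null_spec():
    """Global null with a strong prognostic step effect (variance varies
    across subpopulations)."""
    return ModelSpec(beta2=2.0, shape="step-decreasing", gamma=0.5, n_per_group=80)


@pytest.fixture
def step_alt_spec():
    """One-SD treatment effect confined to the biomarker-positive half."""
    return ModelSpec(beta3=1.0, shape="step-decreasing", gamma=0.5, n_per_group=80)


@pytest.fixture
def quartile_design():
    return NestedDesign(thresholds=(0.25, 0.5, 0.75, 1.0), alpha=0.025)


@pytest.fixture
def alt_data(step_alt_spec):
    return simulate_trial(step_alt_spec, 42)
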