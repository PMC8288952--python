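import numpy as np
import pytest

from alm import (
    ALMConfig,
    LinearSystemConfig,
    MultivariateSeries,
    linear_transition_matrix,
    simulate_linear_system,
)


@pytest.fixture
def small_series():
    """5 variables x 12 points with simple deterministic structure."""
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(5, 12)).cumsum(axis=1)
    return MultivariateSeries(vals, [f"v{i}" for i in range(5)], tau=0.5, start_time=1.0)


@pytest.fixture
def linear_fixture():
    """Stable 6-variable linear system plus its exact transition matrix."""
    cfg = LinearSystemConfig(dimension=6, spectral_radius=0.9, M_total=30, seed=3)
    return simulate_linear_system(cfg), linear_transition_matrix(cfg)


@pytest.fixture
def light_config():
    """Small, fast network configuration for plumbing-level tests."""
    return ALMConfig(
        L=4,
        horizon=3,
        hidden_sizes=(16,),
        epochs_pairwise=300,
        epochs_consistent=300,
        refit_epochs=100,
        refine_epochs=50,
        seed=0,
    )
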