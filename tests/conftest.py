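import numpy as np
import pytest

from kneerig import RigConfig, TissueModel, simulate_experiment


def small_config(**overrides) -> RigConfig:
    """Desk-scale rig configuration for tests (coarse sampling)."""
    defaults = dict(
        n_specimens=2,
        flexion_angles=(30.0, 60.0),
        cycles=3,
        sample_rate=20.0,
        seed=123,
    )
    defaults.update(overrides)
    return RigConfig(**defaults)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic tissue, no rig noise: superposition holds exactly."""
    cfg = small_config().no_noise()
    return simulate_experiment(cfg, TissueModel().no_noise())


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise dataset on a reduced grid."""
    return simulate_experiment(small_config(n_specimens=3), TissueModel())


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
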