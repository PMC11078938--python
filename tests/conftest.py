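import numpy as np
import pytest

from cycliq import SynthConfig, make_experiment


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A compact noisy experiment reused across test modules."""
    return SynthConfig(
        n_cells=12,
        image_height=384,
        image_width=384,
        n_cycles=3,
        markers_per_cycle=2,
        drift_max=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def experiment(small_cfg):
    return make_experiment(small_cfg)


@pytest.fixture(scope="session")
def clean_cfg() -> SynthConfig:
    """Noise-free, drift-free variant for exactness checks."""
    return SynthConfig(
        n_cells=10,
        image_height=384,
        image_width=384,
        n_cycles=2,
        markers_per_cycle=2,
        noise_sd=0.0,
        spot_noise_sd=0.0,
        drift_max=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_experiment(clean_cfg):
    return make_experiment(clean_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
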