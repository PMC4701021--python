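import numpy as np
import pytest

from vbfa_bci import FitConfig, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return FitConfig(n_factors=3, max_iter=100)


def small_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A reduced-scale two-class session spec for fast end-to-end tests."""
    params = dict(
        n_channels=16,
        samples_per_trial=64,
        n_factors_true=3,
        n_trials_per_class=40,
        separation=0.9,
        noise_variance=3 / (16 * 10),  # SNR ~ 10
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)
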