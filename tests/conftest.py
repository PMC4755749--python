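import numpy as np
import pytest

from kinarch.classify import AngleThresholds, ResolutionModel
from kinarch.simulate import get_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def resolution():
    return ResolutionModel()


@pytest.fixture
def thresholds():
    return AngleThresholds()


@pytest.fixture
def young_small():
    """Small noisy young-donor cohort profile for fast pipeline tests."""
    return get_profile("young_baseline", seed=11, n_oocytes=5)


@pytest.fixture
def noise_free_profile():
    """Noise-free profile exercising every label type."""
    return get_profile(
        "young_baseline",
        seed=21,
        n_oocytes=8,
        noise_sigma_um=(0.0, 0.0, 0.0),
        p_disintegrate=0.08,
        p_fully_inverted=0.05,
        p_half_inverted=0.05,
        p_weak_gap=0.15,
    )
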