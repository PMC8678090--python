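import numpy as np
import pytest

from canopyn import SynthConfig

#: printed coefficients of the two canopy-nitrogen models
MODEL_I_COEFFS = (5.75, 8.17, 0.58)
MODEL_II_COEFFS = (1.06, 4.57)


@pytest.fixture
def small_config():
    """A compact 12-variety collection for fast scene-level tests."""
    return SynthConfig(n_varieties=12, plot_grid=(3, 4), plot_size_px=6, seed=42)


@pytest.fixture
def zero_noise_config():
    """12-variety collection with every noise source switched off."""
    return SynthConfig(
        n_varieties=12,
        plot_grid=(3, 4),
        plot_size_px=6,
        seed=7,
        dn_noise_sd=0.0,
        reflectance_noise_sd=0.0,
        pixel_noise_sd=0.0,
        traj_noise_sd=0.0,
        eqa_noise_sd=0.0,
        spad_noise_sd=0.0,
        npen_noise_sd=0.0,
        dosage_noise_scale=0.0,
    )


@pytest.fixture
def full_zero_noise_config():
    """Full 51-variety collection, noiseless, for exact label recovery."""
    return SynthConfig(
        n_varieties=51,
        seed=11,
        dn_noise_sd=0.0,
        reflectance_noise_sd=0.0,
        pixel_noise_sd=0.0,
        traj_noise_sd=0.0,
        eqa_noise_sd=0.0,
        spad_noise_sd=0.0,
        npen_noise_sd=0.0,
        dosage_noise_scale=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
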