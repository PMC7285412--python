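import numpy as np
import pytest

from osteosurf.synthetic import SynthParams, generate_ground_truth, simulate_ct_volume, simulate_us_volume


@pytest.fixture(scope="session")
def clean_params():
    """Small noise-free, defect-free disk: every downstream stage should
    recover the truth to within one voxel."""
    return SynthParams(
        field_size_mm=1.5,
        seed=42,
        crack_fraction=0.0,
        hole_fraction=0.0,
        speckle_strength=0.0,
        us_noise_floor=0.0,
        ct_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_gt(clean_params):
    return generate_ground_truth(clean_params)


@pytest.fixture(scope="session")
def clean_us(clean_params, clean_gt):
    return simulate_us_volume(clean_gt, clean_params)


@pytest.fixture(scope="session")
def clean_ct(clean_params, clean_gt):
    return simulate_ct_volume(clean_gt, clean_params)


@pytest.fixture(scope="session")
def noisy_params():
    """Small disk under default noise with cracks and holes."""
    return SynthParams(field_size_mm=1.5, seed=7)


@pytest.fixture(scope="session")
def noisy_gt(noisy_params):
    return generate_ground_truth(noisy_params)


@pytest.fixture(scope="session")
def noisy_us(noisy_params, noisy_gt):
    return simulate_us_volume(noisy_gt, noisy_params)


@pytest.fixture(scope="session")
def noisy_ct(noisy_params, noisy_gt):
    return simulate_ct_volume(noisy_gt, noisy_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
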