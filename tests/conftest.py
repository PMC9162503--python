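import numpy as np
import pytest

from multifocus import BlurModel, generate_bead_scene, simulate_stack, solve_layer_spectra

#: default blur coefficient for the phantom pipeline: adjacent-plane blur
#: radii 0.2·16.7 ≈ 3.3 px and 0.2·33.3 ≈ 6.7 px
R0_DEFAULT = 0.2


@pytest.fixture(scope="session")
def blur():
    return BlurModel(R0=R0_DEFAULT)


@pytest.fixture(scope="session")
def symmetric_scene():
    """Default 3-ring phantom without angular jitter: mirror-symmetric in x."""
    return generate_bead_scene(angular_jitter_rad=0.0, seed=0)


@pytest.fixture(scope="session")
def jittered_scene():
    return generate_bead_scene(angular_jitter_rad=0.05, seed=7)


@pytest.fixture(scope="session")
def sim_stack(symmetric_scene, blur):
    return simulate_stack(symmetric_scene, blur, noise_sigma=0.0)


@pytest.fixture(scope="session")
def spectra(sim_stack, blur):
    return solve_layer_spectra(sim_stack, blur)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
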