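import numpy as np
import pytest
from hypothesis import settings

import natsynth_fus as nf
from natsynth_fus import preprocess as pp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


SMALL = dict(
    n_pairs=20,
    category_counts={"speech": 4, "music": 4, "vocalization": 4, "environment": 8},
    n_slices=3,
    slice_shape=(10, 3),
    n_out_voxels=12,
)

NOISELESS = dict(snr=0.0, sigma_slice=0.0, motion_scale_default=0.0,
                 motion_scales={})


@pytest.fixture(scope="session")
def small_sim():
    """Reduced-size simulation with the default noise structure."""
    return nf.simulate(seed=0, **SMALL)


@pytest.fixture(scope="session")
def small_noiseless_sim():
    return nf.simulate(seed=0, **SMALL, **NOISELESS)


@pytest.fixture(scope="session")
def small_fractional(small_sim):
    return pp.percent_signal_change(small_sim.dataset)


@pytest.fixture(scope="session")
def default_sim():
    """The study's default conditions: 8 components, 4 reps, 6 slices, SNR 1."""
    return nf.simulate(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
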