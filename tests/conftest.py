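import numpy as np
import pytest

import qmripipe as q
from qmripipe.pipeline import PipelineConfig, fit_subject


@pytest.fixture(scope="session")
def default_phantom():
    """32-cube phantom with the default tissue table and field amplitudes."""
    return q.make_phantom(shape=(32, 32, 32), seed=11)


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """Phantom with perfectly homogeneous B1/B0/receive fields."""
    return q.make_phantom(
        shape=(32, 32, 32), seed=11, field_spec=q.FieldSpec(0.0, 0.0, 0.0)
    )


@pytest.fixture(scope="session")
def noiseless_subject(default_phantom):
    """Full noiseless acquisition + fitting chain on the default phantom.

    B1/B0 calibration runs at the target grid here; the low-resolution
    acquisition + trilinear upsampling contract (exact only to interpolation
    error) is tested separately.
    """
    config = PipelineConfig(shape=default_phantom.shape, voxel_size_mm=2.0, b1_grid_scale=1)
    return fit_subject(default_phantom, config, noise_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
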