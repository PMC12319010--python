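import numpy as np
import pytest

from tuningbayes import GridSpec, NoiseModel, TuningParams


@pytest.fixture
def well_tuned_params():
    return TuningParams(C=1.0, Rp=10.0, alpha=0.5, theta_pref=90.0, sigma=30.0)


@pytest.fixture
def poorly_tuned_params():
    return TuningParams(C=1.0, Rp=1.0, alpha=0.0, theta_pref=90.0, sigma=30.0)


@pytest.fixture
def linear_noise():
    """Noise law matching 50% multiplicative noise with a small floor."""
    return NoiseModel(Cn=0.1, K=0.5, S=1.0)


@pytest.fixture
def tiny_grid():
    """A few hundred combinations; cheap enough for brute-force checks."""
    return GridSpec(
        c=np.array([0.5, 1.0, 2.0]),
        rp=np.array([0.5, 5.0, 10.0]),
        alpha=np.array([0.0, 0.5, 1.0]),
        theta_pref=np.array([0.0, 90.0, 180.0, 270.0]),
        sigma=np.array([15.0, 30.0, 60.0]),
    )
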