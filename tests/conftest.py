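import numpy as np
import pytest

from mcnedi.synthetic import DegradationSpec, degrade, make_brain_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """Default 128x128 multi-contrast phantom, seed 0."""
    return make_brain_phantom(0)


@pytest.fixture(scope="session")
def phantom_lr(phantom_pair):
    """Degraded LR version of the phantom's second contrast."""
    return degrade(phantom_pair.image_b, DegradationSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def diagonal_step_hr():
    """64x64 two-level image constant along the main diagonal."""
    rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    return np.where(rr - cc >= 0, 0.78, 0.0)
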