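import numpy as np
import pytest

from tagstrain.model import TagStrainModel


@pytest.fixture(scope="session")
def annulus_fit():
    """Full pipeline on the default noise-free contracting/twisting annulus.

    Expensive (one optic-flow sweep over 20 frame pairs at 128x128), so it
    is fitted once per session and shared by the end-to-end tests.
    Returns (model, results); the phantom motion model is on model.phantom.
    """
    model = TagStrainModel.from_phantom(noise_sd=0.0, n_frames=21, seed=0)
    return model, model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
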