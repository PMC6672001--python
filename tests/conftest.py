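import numpy as np
import pytest

from callosal import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def acquisition():
    """Single-shell acquisition: 1 b0 + 60 directions at b = 800 s/mm^2."""
    return synthetic.make_acquisition(800.0, 60)


@pytest.fixture
def annuli_image():
    """Three disjoint noiseless annuli with known geometry."""
    specs = [
        synthetic.AxonSpec((60.0, 60.0), 40.0, 60.0),
        synthetic.AxonSpec((60.0, 180.0), 30.0, 50.0),
        synthetic.AxonSpec((180.0, 120.0), 50.0, 80.0),
    ]
    img, truth = synthetic.gen_em_image(specs, (240, 240), pixel_size_nm=7.0)
    return img, truth
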