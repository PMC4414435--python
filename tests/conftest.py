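import numpy as np
import pytest

from myolam import synthetic


@pytest.fixture(scope="session")
def slab_spec():
    return synthetic.PhantomSpec(shape=(24, 24, 24))


@pytest.fixture(scope="session")
def slab_phantom(slab_spec):
    """Noiseless axis-aligned slab phantom (normal +z) with ground truth."""
    return synthetic.make_slab_phantom(slab_spec, (0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def oblique_slab_phantom(slab_spec):
    """Noiseless slab phantom with an oblique normal."""
    return synthetic.make_slab_phantom(slab_spec, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def annulus_phantom():
    spec = synthetic.PhantomSpec(shape=(48, 48, 16), geometry="annulus",
                                 helix_endo=60.0, helix_epi=-60.0)
    vol, truth = synthetic.make_annulus_phantom(spec)
    return spec, vol, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
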