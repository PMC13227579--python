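import warnings

import numpy as np
import pytest

from fi2ffa.synthetic import generate_vessel_tree, rasterize_structure, render_ffa, render_fi

# the classical pipeline warns on purpose for degenerate inputs; tests that
# check the warnings assert them explicitly
warnings.filterwarnings("ignore", module="fi2ffa")


@pytest.fixture(scope="session")
def scene256():
    return generate_vessel_tree(seed=0, field_radius=128.0)


@pytest.fixture(scope="session")
def gt256(scene256):
    return rasterize_structure(scene256, 256)


@pytest.fixture(scope="session")
def fi256(scene256):
    return render_fi(scene256, 256, seed=100)


@pytest.fixture(scope="session")
def ffa256(scene256):
    return render_ffa(scene256, 256, seed=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
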