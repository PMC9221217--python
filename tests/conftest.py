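import numpy as np
import pytest

from atlasfusion import ClassifierConfig, SelectionConfig, make_lattice_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_atlas():
    """8-region lattice on an 8x8x8 grid at 3 mm isotropic."""
    return make_lattice_atlas((8, 8, 8), (2, 2, 2))


@pytest.fixture
def fast_config():
    """Reduced classifier configuration used by simulation-heavy tests:
    3x3 hyperparameter grid and the fixed-hyperparameter SFC evaluator."""
    grid = 2.0 ** np.array([-2.0, 0.0, 2.0])
    return ClassifierConfig(c_grid=grid, gamma_grid=grid, sfc_hyperparams=(1.0, 0.125))


@pytest.fixture
def small_selection():
    return SelectionConfig(mrmr_k=6)
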