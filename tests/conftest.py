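import numpy as np
import pytest

from trfit.core_model import MultiExpModel, TimeGrid
from trfit.synthetic import make_gaussian_irf


@pytest.fixture
def grid():
    """1024-bin grid over 0-50 ns (dt ~ 49 ps): resolves sub-ns IRFs fast."""
    return TimeGrid(t_start=0.0, dt=50.0 / 1024.0, n_bins=1024)


@pytest.fixture
def irf(grid):
    """Sub-ns Gaussian IRF (FWHM 0.25 ns) early in the grid."""
    return make_gaussian_irf(0.25, 0.75, grid)


@pytest.fixture
def fine_grid():
    """2048-bin grid over 0-25 ns (dt ~ 12 ps): resolves 0.4-ns components."""
    return TimeGrid(t_start=0.0, dt=25.0 / 2048.0, n_bins=2048)


@pytest.fixture
def fine_irf(fine_grid):
    return make_gaussian_irf(0.1, 0.3, fine_grid)


@pytest.fixture
def triexp():
    """Trp-like tri-exponential decay model."""
    return MultiExpModel(amplitudes=(0.5, 0.3, 0.2), lifetimes=(0.5, 2.0, 5.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
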