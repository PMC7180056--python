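import numpy as np
import pytest

from specisn import connectivity, rf_stimuli


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 40x40-pixel visual field for fast rasterization."""
    return rf_stimuli.GridSpec(extent=10.0, resolution=4.0)


@pytest.fixture(scope="session")
def small_bank(small_grid):
    return rf_stimuli.sample_rf_bank(6, 5, small_grid, seed=11)


@pytest.fixture(scope="session")
def fig2_params():
    """Fig-2 column of the rate-network parameter table, noise off."""
    return connectivity.BlockParams(
        j={"EE": 0.05, "IE": 0.05, "EI": -0.075, "II": -0.075},
        m={b: 1.0 for b in connectivity.BLOCKS},
        zeta=False,
    )


@pytest.fixture(scope="session")
def even_ring(fig2_params):
    """Deterministic ring network with evenly spaced orientations.

    sin/cos of the doubled angle are exact discrete Fourier eigenmodes here,
    so the specific-mode eigenvalue is exactly N*J*m/2.
    """
    theta = np.tile(np.linspace(0.0, np.pi, 200, endpoint=False), 2)
    wm = connectivity.build_ring_weights(theta, fig2_params, n_e=200)
    return wm, theta
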