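import numpy as np
import pytest

import burstpide as bp

# the five printed positive-feedback parameter sets: (a, b) at H=-4, K=45, eps=0.15
FIG_PARAMS = {
    "fig4": (5.0, 10.0),
    "fig5": (5.0, 30.0),
    "fig6": (10.0, 5.0),
    "fig7": (8.0, 16.0),
    "fig8": (15.0, 20.0),
}


@pytest.fixture(scope="session")
def hill_fb():
    return bp.HillFeedback1D(H=-4, K=45.0, epsilon=0.15)


@pytest.fixture(scope="session")
def fig4_model(hill_fb):
    return bp.Model1D(a=5.0, b=10.0, feedback=hill_fb)


@pytest.fixture(scope="session")
def fig4_density(fig4_model):
    return bp.normalise(fig4_model)


def make_grid(density, n):
    """Axis over the stationary law's truncation domain plus its cell averages."""
    axis = bp.Axis(x_max=density.x_max, n=n)
    return axis, density.cell_averages(axis.faces)


@pytest.fixture(scope="session")
def fig4_grid512(fig4_density):
    return make_grid(fig4_density, 512)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
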