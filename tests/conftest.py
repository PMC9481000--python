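"""Shared fixtures: phantom-like media and precomputed forward curves.

Session-scoped fixtures cache the expensive forward evaluations so the
property and inversion tests can share them.
"""

import numpy as np
import pytest

from dcslayer import (
    LayeredMedium,
    OpticalLayer,
    default_tau_grid,
    g1_layered,
)


@pytest.fixture(scope="session")
def bottom_layer() -> OpticalLayer:
    """Dynamic liquid half-space (cortex surrogate), baseline properties."""
    return OpticalLayer(mu_a=0.12, mu_s_prime=10.46, n_refr=1.33, d_b=2e-9)


@pytest.fixture(scope="session")
def top_layer() -> OpticalLayer:
    """Static solid slab material (skull surrogate), baseline properties."""
    return OpticalLayer(mu_a=0.11, mu_s_prime=8.50, n_refr=1.40, d_b=0.0,
                        thickness=0.201)


@pytest.fixture(scope="session")
def tau_grid() -> np.ndarray:
    return default_tau_grid()


@pytest.fixture(scope="session")
def homogeneous_medium(bottom_layer) -> LayeredMedium:
    return LayeredMedium.homogeneous(bottom_layer)


@pytest.fixture(scope="session")
def two_layer_medium(top_layer, bottom_layer) -> LayeredMedium:
    """2.01 mm static top over the dynamic half-space."""
    return LayeredMedium.two_layer(top_layer, bottom_layer)


@pytest.fixture(scope="session")
def homogeneous_g1_sd20(homogeneous_medium, tau_grid):
    return g1_layered(homogeneous_medium, 2.0, tau_grid)


@pytest.fixture(scope="session")
def two_layer_g1_sd20(two_layer_medium, tau_grid):
    return g1_layered(two_layer_medium, 2.0, tau_grid)
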