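import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tissuelight.montecarlo import McConfig, SimulationGrid, run_simulation
from tissuelight.optics import Layer, OpticalProperties, TissueStack

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def single_layer_stack(mu_a, mu_s, g=0.0, n=1.0, thickness=1.0,
                       semi_infinite=False, wavelength=800.0,
                       n_above=1.0, n_below=1.0) -> TissueStack:
    layer = Layer("medium", thickness,
                  {wavelength: OpticalProperties(mu_a, mu_s, g, n)},
                  semi_infinite=semi_infinite)
    return TissueStack([layer], n_above=n_above, n_below=n_below)


@pytest.fixture(scope="session")
def beer_slab_imp():
    """Pure absorber, 1 mm slab, matched boundaries: Beer-Lambert oracle."""
    stack = single_layer_stack(mu_a=1.0, mu_s=0.0, thickness=1.0)
    grid = SimulationGrid(dz=0.01, dr=0.05, nz=100, nr=100)
    return run_simulation(stack, 800.0, grid, McConfig(n_photons=100_000, seed=7))


@pytest.fixture(scope="session")
def scatter_imp():
    """Absorbing-scattering 2 mm slab used by the convolution tests."""
    stack = single_layer_stack(mu_a=0.3, mu_s=5.0, g=0.8, n=1.37, thickness=2.0)
    grid = SimulationGrid(dz=0.01, dr=0.025, nz=200, nr=400)
    return run_simulation(stack, 800.0, grid, McConfig(n_photons=50_000, seed=11)), stack
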