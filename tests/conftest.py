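import numpy as np
import pytest

from nanoperm.constants import thermal_energy
from nanoperm.profiles import Profile
from nanoperm.synthetic import ToyBilayerSpec, gen_toy_bilayer

RT310 = thermal_energy(310.0)


@pytest.fixture(scope="session")
def flat_bilayer():
    """144 lipids per leaflet on a 12x12 nm box, no tilt or undulation."""
    return gen_toy_bilayer(ToyBilayerSpec(n_lipids_per_leaflet=144, box=(12.0, 12.0, 16.0)))


@pytest.fixture()
def flat_profiles():
    """Flat dG and constant D on [-8, 8] at the 0.2 nm window grid."""
    z = np.linspace(-8.0, 8.0, 81)
    dG = Profile.constant(0.0, z, quantity="dG", units="kJ/mol")
    D = Profile.constant(0.05, z, quantity="D", units="nm^2/ps")
    return dG, D
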