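import numpy as np
import pytest

from memdefect.topology import default_topology_spec
from memdefect.synth import SyntheticMembraneSpec, generate_bilayer


@pytest.fixture(scope="session")
def topo():
    return default_topology_spec()


@pytest.fixture(scope="session")
def small_bilayer():
    """A 16-lipid-per-leaflet sterol-free bilayer (fully covering)."""
    spec = SyntheticMembraneSpec(n_lipids_per_leaflet=16, seed=7)
    return generate_bilayer(spec)


@pytest.fixture(scope="session")
def medium_bilayer():
    """A 64-lipid-per-leaflet sterol-free bilayer."""
    spec = SyntheticMembraneSpec(n_lipids_per_leaflet=64, seed=11)
    return generate_bilayer(spec)
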