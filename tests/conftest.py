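import numpy as np
import pytest

from atcmdose.fixtures import make_water_cylinder
from atcmdose.materials import load_default_materials
from atcmdose.phantoms import generate_phantom, reference_phantom
from atcmdose.spectra import build_spectrum


@pytest.fixture(scope="session")
def materials():
    return load_default_materials()


@pytest.fixture(scope="session")
def spectrum_120(materials):
    return build_spectrum(120.0, 3.5, materials)


@pytest.fixture(scope="session")
def water_cylinder_fine():
    """300 mm water cylinder at 2 mm voxels for projection-geometry oracles."""
    return make_water_cylinder(300.0, 60.0, spacing_mm=2.0)


@pytest.fixture(scope="session")
def water_cylinder_coarse():
    """300 mm water cylinder at 5 mm voxels for transport oracles."""
    return make_water_cylinder(300.0, 100.0, spacing_mm=5.0, margin_mm=40.0)


@pytest.fixture(scope="session")
def ref_phantom():
    return reference_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """A compact anthropomorphic phantom for fast unit tests."""
    return generate_phantom("female", "normal", seed=11, shape=(48, 72, 72))
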