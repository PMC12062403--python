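import numpy as np
import pytest

from finprop.geometry import CAUDAL_PRESETS, GeometrySpec, build_swimmer_geometry


@pytest.fixture(scope="session")
def preset_meshes():
    """The four caudal-opening preset meshes at default resolution."""
    return {name: build_swimmer_geometry(GeometrySpec(caudal_open_angle=phi))
            for name, phi in CAUDAL_PRESETS.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
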