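import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brachytrack.geometry import (
    CollimatorSpec,
    DetectorSpec,
    SourceState,
    build_layout,
    default_layout,
)
from brachytrack.recon import VolumeGrid, make_projector
from brachytrack.transport import TransportConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def detector():
    return DetectorSpec()


@pytest.fixture(scope="session")
def collimator():
    return CollimatorSpec()


@pytest.fixture(scope="session")
def single_panel_layout():
    """One panel on the +x axis at the reference 500 mm distance."""
    return build_layout(500.0, [0.0], [0.0])


@pytest.fixture(scope="session")
def ring_layout():
    return default_layout()


@pytest.fixture(scope="session")
def point_source():
    """A near-point source (degenerate capsule) for PSF studies."""
    return SourceState(diameter=1e-9, length=1e-9)


@pytest.fixture(scope="session")
def fast_cfg():
    """Deterministic analytic transport with a modest photon budget."""
    return TransportConfig(source_subsamples=1, emitted_photons=1e6)


@pytest.fixture(scope="session")
def coarse_grid():
    """2 mm voxels over the 160 mm effective cube: fast reconstruction tests."""
    return VolumeGrid.centered(160.0, 2.0)


@pytest.fixture(scope="session")
def coarse_projector(ring_layout, coarse_grid):
    return make_projector(ring_layout, coarse_grid, upsample_factor=2, gaussian_sigma=0.6)
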