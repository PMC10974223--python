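import numpy as np
import pytest

from castct import (
    ScanGeometry,
    ScanMode,
    Spectrum,
    default_spectrum,
    forward_project,
    geometry_for_phantom,
    make_phantom,
)


@pytest.fixture(scope="session")
def disk_phantom():
    return make_phantom("disk", size=128, voxel_size=0.5)


@pytest.fixture(scope="session")
def arch_phantom():
    return make_phantom("dental_arch", size=128, voxel_size=0.5)


@pytest.fixture(scope="session")
def mono_spectrum():
    return Spectrum.mono(60.0)


@pytest.fixture(scope="session")
def poly_spectrum():
    return default_spectrum()


@pytest.fixture(scope="session")
def mono_disk_scan(disk_phantom, mono_spectrum):
    """Monoenergetic scatter-free disk projections, 180 views."""
    geo = geometry_for_phantom(disk_phantom, n_views=180)
    return forward_project(disk_phantom, geo, mono_spectrum)


@pytest.fixture(scope="session")
def poly_disk_scan(disk_phantom, poly_spectrum):
    geo = geometry_for_phantom(disk_phantom, n_views=180)
    return forward_project(disk_phantom, geo, poly_spectrum)


@pytest.fixture
def small_geometry():
    return ScanGeometry(
        mode=ScanMode.PARALLEL2D,
        source_object_dist=400.0,
        source_detector_dist=680.0,
        det_rows=1,
        det_cols=32,
        pixel_pitch=0.85,
        angles=np.arange(24) * 15.0,
    )
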