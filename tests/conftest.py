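import numpy as np
import pytest

from petiq.acquisition import AcquisitionConfig, BedGeometry, simulate_acquisition
from petiq.experiments import ExperimentScale
from petiq.phantoms import DEFAULT_DZ, build_nema_iq, rasterize


@pytest.fixture(scope="session")
def tiny_scale():
    """Desk-scale settings for fast end-to-end tests."""
    return ExperimentScale(
        n_pixels=32,
        in_plane_spacing=10.0,
        micro_spacing=4.0,
        angles=48,
        slices_per_bed=11,
        overlap_slices=3,
        subsets=12,
        osem_iterations=2,
        bpl_cap=8,
        bpl_tolerance=1e-3,
    )


@pytest.fixture(scope="session")
def tiny_nema(tiny_scale):
    """Rasterized single-bed 10:1 torso phantom at tiny scale."""
    bed_len = tiny_scale.slices_per_bed * tiny_scale.dz
    phantom = build_nema_iq("10:1", z_center=bed_len / 2.0, axial_length=bed_len)
    grid = tiny_scale.grid(1)
    return phantom, rasterize(phantom, grid, supersample=2)


@pytest.fixture(scope="session")
def tiny_sinos(tiny_scale, tiny_nema):
    _, volumes = tiny_nema
    geometry = BedGeometry(tiny_scale.slices_per_bed, tiny_scale.overlap_slices, 1)
    config = AcquisitionConfig(
        time_per_bed=300.0,
        angles=tiny_scale.angles,
        psf_fwhm=tiny_scale.acq_psf_fwhm,
        calibration=tiny_scale.calibration,
        seed=42,
    )
    return simulate_acquisition(volumes, geometry, config)
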