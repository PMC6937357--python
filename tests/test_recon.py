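import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petiq.acquisition import (
    AcquisitionConfig,
    AxialSensitivityProfile,
    BedGeometry,
    ParallelProjector,
    axial_sensitivity,
    simulate_acquisition,
)
from petiq.errors import ConfigurationError, ShapeError
from petiq.phantoms import BodyOutline, BodySection, PhantomSpec, VoxelGrid, rasterize
from petiq.recon import (
    ImageVolume,
    ReconConfig,
    _BedSystem,
    axial_weighted_filter,
    bsrem_rdp_reconstruct,
    gaussian_postfilter,
    osem_reconstruct,
    rdp_penalty,
    reconstruct_bed_bsrem,
    reconstruct_bed_osem,
    stitch_beds,
)

# ---------------------------------------------------------------- RDP penalty


class TestRDPPenalty:
    def test_uniform_image_zero(self):
        pen = rdp_penalty(np.full((5, 5), 3.0), beta=2.0, gamma=2.0)
        assert pen.value == 0.0
        assert np.all(pen.gradient == 0.0)

    def test_two_voxel_hand_value(self):
        # (2, 0), w=1, beta=1, gamma=2, eps=0: U = 4 / (2 + 2*2) = 2/3
        img = np.array([[2.0], [0.0]])
        pen = rdp_penalty(img, beta=1.0, gamma=2.0, epsilon=0.0)
        assert pen.value == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_gamma_validation(self):
        with pytest.raises(ConfigurationError):
            rdp_penalty(np.ones((3, 3)), beta=1.0, gamma=0.0)

    def test_gradient_matches_finite_differences_2d(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0.5, 4.0, (6, 7))
        pen = rdp_penalty(img, beta=1.3, gamma=2.0)
        h = 1e-6
        for idx in [(0, 0), (2, 3), (5, 6), (3, 0)]:
            up, dn = img.copy(), img.copy()
            up[idx] += h
            dn[idx] -= h
            fd = (
                rdp_penalty(up, 1.3, 2.0).value - rdp_penalty(dn, 1.3, 2.0).value
            ) / (2 * h)
            assert pen.gradient[idx] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_gradient_matches_finite_differences_3d(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0.1, 2.0, (4, 4, 3))
        spacing = (2.0, 2.0, 3.3)
        pen = rdp_penalty(img, beta=0.7, gamma=2.0, spacing=spacing)
        h = 1e-6
        for idx in [(0, 0, 0), (2, 1, 1), (3, 3, 2)]:
            up, dn = img.copy(), img.copy()
            up[idx] += h
            dn[idx] -= h
            fd = (
                rdp_penalty(up, 0.7, 2.0, spacing).value
                - rdp_penalty(dn, 0.7, 2.0, spacing).value
            ) / (2 * h)
            assert pen.gradient[idx] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_value_nonnegative_property(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0.0, 5.0, (4, 5))
        pen = rdp_penalty(img, beta=1.0, gamma=2.0)
        assert pen.value >= 0.0


# ----------------------------------------------------------- noiseless system


def _disk_phantom_volumes(n=32, nz=5, spacing=6.0, conc=4.0):
    ph = PhantomSpec(
        sections=(BodySection(0, nz * 4.0, BodyOutline("ellipse", 130, 130)),),
        background_concentration=conc,
    )
    grid = VoxelGrid.centered((n, n, nz), (spacing, spacing, 4.0))
    return rasterize(ph, grid, supersample=2)


def _noiseless_sinos(volumes, nz=5, angles=48, psf=0.0):
    geom = BedGeometry(nz, 0, 1)
    cfg = AcquisitionConfig(time_per_bed=60.0, angles=angles, psf_fwhm=psf,
                            calibration=0.05, half_life_min=1e9, seed=0)
    sinos = simulate_acquisition(volumes, geom, cfg)
    sinos.counts = sinos.expected.copy()  # noiseless data for consistency tests
    return sinos


@pytest.fixture(scope="module")
def noiseless():
    volumes = _disk_phantom_volumes()
    return volumes, _noiseless_sinos(volumes)


class TestOSEM:
    def test_noiseless_consistency(self, noiseless):
        volumes, sinos = noiseless
        cfg = ReconConfig(algorithm="OSEM", iterations=60, subsets=12,
                          postfilter_fwhm=0.0, axial_weights=(0, 1, 0))
        vol = osem_reconstruct(sinos, cfg, apply_postfilters=False)
        truth = volumes.activity
        interior = truth > 0.99 * truth.max()
        rel = np.abs(vol.values[interior] - truth[interior]) / truth[interior]
        assert rel.max() < 0.02

    def test_nonnegativity(self, noiseless):
        _, sinos = noiseless
        cfg = ReconConfig(algorithm="OSEM", iterations=2, subsets=12)
        assert np.all(osem_reconstruct(sinos, cfg).values >= 0)

    def test_mlem_likelihood_nondecreasing(self, noiseless):
        # 1 subset, beta = 0: the BSREM trace is the Poisson log-likelihood
        _, sinos = noiseless
        cfg = ReconConfig(algorithm="BPL", subsets=1, beta=0.0, psf_fwhm=0.0,
                          bpl_iterations=8, bpl_tolerance=0.0)
        _, trace = reconstruct_bed_bsrem(sinos, 0, cfg, return_trace=True)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-6 * np.abs(trace[0]))

    def test_subsets_must_divide_angles(self, noiseless):
        _, sinos = noiseless
        cfg = ReconConfig(algorithm="OSEM", subsets=7)
        with pytest.raises(ConfigurationError):
            osem_reconstruct(sinos, cfg)

    def test_matched_projector_reproduces_data(self, noiseless):
        # forward-projecting a converged noiseless reconstruction recovers counts
        _, sinos = noiseless
        cfg = ReconConfig(algorithm="OSEM", iterations=60, subsets=12,
                          postfilter_fwhm=0.0, axial_weights=(0, 1, 0))
        vol = osem_reconstruct(sinos, cfg, apply_postfilters=False)
        sys = _BedSystem(sinos, 0, cfg)
        n2 = sys.nx * sys.nx
        F = vol.values.reshape(n2, sys.nz)
        refit = np.concatenate([sys.fwd(m, F).ravel() for m in range(cfg.subsets)])
        data = np.concatenate([sys.counts_subset(m).ravel() for m in range(cfg.subsets)])
        sig = data > 0.05 * data.max()
        rel = np.abs(refit[sig] - data[sig]) / data[sig]
        assert np.median(rel) < 0.01
        assert rel.max() < 0.1


class TestBSREM:
    def test_beta_zero_first_pass_equals_osem(self, noiseless):
        _, sinos = noiseless
        osem_cfg = ReconConfig(algorithm="OSEM", iterations=1, subsets=12,
                               psf_fwhm=0.0, postfilter_fwhm=0.0)
        bpl_cfg = ReconConfig(algorithm="BPL", subsets=12, beta=0.0, psf_fwhm=0.0,
                              bpl_iterations=1, bpl_tolerance=0.0)
        a = reconstruct_bed_osem(sinos, 0, osem_cfg)
        b = reconstruct_bed_bsrem(sinos, 0, bpl_cfg)
        scale = a.max()
        assert np.abs(a - b).max() <= 1e-10 * scale

    def test_objective_nondecreasing_with_penalty(self, noiseless):
        _, sinos = noiseless
        cfg = ReconConfig(algorithm="BPL", subsets=12, beta=0.5, psf_fwhm=0.0,
                          bpl_iterations=10, bpl_tolerance=0.0)
        _, trace = reconstruct_bed_bsrem(sinos, 0, cfg, return_trace=True)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-6 * np.abs(trace[0]))

    def test_nonnegativity(self, noiseless):
        _, sinos = noiseless
        cfg = ReconConfig(algorithm="BPL", subsets=12, beta=1.0, bpl_iterations=5)
        assert np.all(bsrem_rdp_reconstruct(sinos, cfg).values >= 0)

    def test_penalty_value_nonincreasing_in_beta(self, tiny_scale, tiny_sinos):
        # roughness of the output decreases as the penalty weight grows
        penalties = []
        for beta in (0.2, 1.0, 4.0):
            cfg = tiny_scale.recon_config("BPL", beta=beta)
            vol = bsrem_rdp_reconstruct(tiny_sinos, cfg)
            pen = rdp_penalty(vol.values, beta=1.0, gamma=cfg.gamma,
                              spacing=vol.grid.spacing)
            penalties.append(pen.value)
        assert penalties[0] > penalties[1] > penalties[2]

    def test_background_cov_decreasing_in_beta(self, tiny_scale, tiny_nema, tiny_sinos):
        from petiq.experiments import background_cov

        _, volumes = tiny_nema
        covs = []
        for beta in (0.2, 0.6, 2.0):
            cfg = tiny_scale.recon_config("BPL", beta=beta)
            vol = bsrem_rdp_reconstruct(tiny_sinos, cfg)
            covs.append(background_cov(vol, volumes.region_labels, range(4, 7)))
        assert covs[0] > covs[1] > covs[2]


# ----------------------------------------------------------------- postfilters


class TestGaussianPostfilter:
    def _delta_volume(self, n=41, nz=21, spacing=(2.0, 2.0, 2.0)):
        grid = VoxelGrid.centered((n, n, nz), spacing)
        values = np.zeros((n, n, nz))
        values[n // 2, n // 2, nz // 2] = 1.0
        return ImageVolume(values, grid)

    def test_zero_fwhm_identity(self):
        vol = self._delta_volume()
        out = gaussian_postfilter(vol, 0.0)
        assert np.array_equal(out.values, vol.values)

    def test_sum_preserved(self):
        vol = self._delta_volume()
        out = gaussian_postfilter(vol, 6.4)
        assert out.values.sum() == pytest.approx(1.0, rel=1e-6)

    def test_measured_fwhm(self):
        vol = self._delta_volume()
        out = gaussian_postfilter(vol, 6.4)
        n = vol.values.shape[0]
        profile = out.values[:, n // 2, vol.values.shape[2] // 2]
        half_max = profile.max() / 2
        above = np.nonzero(profile >= half_max)[0]
        # linear interpolation at the crossings
        lo, hi = above[0], above[-1]
        f = lambda i, j: i + (j - i) * (half_max - profile[i]) / (profile[j] - profile[i])
        width_vox = f(hi, hi + 1) - f(lo, lo - 1)
        assert abs(width_vox * 2.0 - 6.4) <= 1.0  # within half a voxel

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ConfigurationError):
            gaussian_postfilter(self._delta_volume(), -1.0)


class TestAxialWeightedFilter:
    def _volume(self, values):
        grid = VoxelGrid.centered(values.shape, (2.0, 2.0, 3.0))
        return ImageVolume(values, grid)

    def test_identity_weights(self):
        rng = np.random.default_rng(0)
        vol = self._volume(rng.random((4, 4, 6)))
        out = axial_weighted_filter(vol, (0, 1, 0))
        assert np.allclose(out.values, vol.values)

    def test_constant_unchanged(self):
        vol = self._volume(np.full((4, 4, 6), 2.5))
        out = axial_weighted_filter(vol, (1, 4, 1))
        assert np.allclose(out.values, 2.5)

    def test_alternating_amplitude_third(self):
        # +1/-1 alternation: interior amplitude (4 - 2)/6 = 1/3 under [1,4,1]
        nz = 9
        values = np.ones((3, 3, nz)) * np.array([(-1.0) ** k for k in range(nz)])
        out = axial_weighted_filter(self._volume(values), (1, 4, 1))
        interior = out.values[1, 1, 1:-1]
        assert np.allclose(np.abs(interior), 1.0 / 3.0)

    def test_weight_validation(self):
        vol = self._volume(np.zeros((3, 3, 4)))
        with pytest.raises(ConfigurationError):
            axial_weighted_filter(vol, (1, 2))
        with pytest.raises(ConfigurationError):
            axial_weighted_filter(vol, (-1, 1, 0))


# ------------------------------------------------------------------ stitching


class TestStitchBeds:
    def test_single_bed_passthrough(self):
        geom = BedGeometry(5, 0, 1)
        profile = axial_sensitivity(5)
        grid = VoxelGrid.centered((4, 4, 5), (2.0, 2.0, 3.0))
        vol = np.random.default_rng(0).random((4, 4, 5))
        out = stitch_beds([vol], profile, geom, grid)
        assert np.allclose(out.values, vol)

    def test_uniform_no_seam(self):
        geom = BedGeometry(11, 3, 2)
        profile = axial_sensitivity(11)
        grid = VoxelGrid.centered((4, 4, geom.total_slices), (2.0, 2.0, 3.0))
        beds = [np.full((4, 4, 11), 3.0), np.full((4, 4, 11), 3.0)]
        out = stitch_beds(beds, profile, geom, grid)
        slice_means = out.values.mean(axis=(0, 1))
        assert np.ptp(slice_means) < 1e-12

    def test_overlap_variance_reduced(self):
        # convex combination of independent noise has lower variance
        geom = BedGeometry(11, 3, 2)
        profile = axial_sensitivity(11)
        grid = VoxelGrid.centered((6, 6, geom.total_slices), (2.0, 2.0, 3.0))
        rng = np.random.default_rng(1)
        reps = 400
        overlap_slice = geom.overlap_regions()[0].start + 1
        stitched_vals, bed_vals = [], []
        for _ in range(reps):
            beds = [5.0 + rng.normal(0, 1, (6, 6, 11)) for _ in range(2)]
            out = stitch_beds(beds, profile, geom, grid)
            stitched_vals.append(out.values[3, 3, overlap_slice])
            bed_vals.append(beds[0][3, 3, overlap_slice - 0])
        assert np.var(stitched_vals) <= np.var(bed_vals)

    def test_provenance_records_beds(self):
        geom = BedGeometry(11, 3, 2)
        profile = axial_sensitivity(11)
        grid = VoxelGrid.centered((4, 4, geom.total_slices), (2.0, 2.0, 3.0))
        beds = [np.zeros((4, 4, 11))] * 2
        out = stitch_beds(beds, profile, geom, grid)
        sb = out.provenance["slice_beds"]
        assert sb[0] == [0]
        assert sb[geom.overlap_regions()[0].start] == [0, 1]
        assert sb[-1] == [1]

    def test_grid_mismatch(self):
        geom = BedGeometry(11, 3, 2)
        profile = axial_sensitivity(11)
        grid = VoxelGrid.centered((4, 4, geom.total_slices), (2.0, 2.0, 3.0))
        with pytest.raises(ShapeError):
            stitch_beds([np.zeros((4, 4, 11)), np.zeros((5, 5, 11))], profile, geom, grid)


class TestReconConfig:
    def test_unknown_algorithm(self):
        with pytest.raises(ConfigurationError):
            ReconConfig(algorithm="FBP")

    def test_beta_gamma_validation(self):
        with pytest.raises(ConfigurationError):
            ReconConfig(algorithm="BPL", beta=-1.0)
        with pytest.raises(ConfigurationError):
            ReconConfig(algorithm="BPL", gamma=0.0)

    def test_model_psf_only_for_psf_variants(self):
        assert ReconConfig(algorithm="OSEM", psf_fwhm=5.0).model_psf_fwhm == 0.0
        assert ReconConfig(algorithm="OSEM_PSF", psf_fwhm=5.0).model_psf_fwhm == 5.0
        assert ReconConfig(algorithm="BPL", psf_fwhm=5.0).model_psf_fwhm == 5.0
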