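"""Forward acquisition model: projector, axial sensitivity, beds, Poisson counts.

The acquisition is modelled slice-wise in 2-D: each axial slice is
projected with a parallel-beam Joseph projector, attenuated along the same
rays, optionally blurred radially (detector resolution), scaled by a
calibration constant, scan time, radioactive decay, and the slice's
position in the triangular axial sensitivity profile of its bed.  Counts
are Poisson draws from the expected sinograms; shorter acquisitions are
derived by binomial thinning, emulating list-mode retro-reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, ShapeError
from .phantoms import LabelledVolumes, VoxelGrid

#: Half-life of F-18, minutes (physical constant).
F18_HALF_LIFE_MIN = 109.77

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548


# -- axial sensitivity and bed geometry --------------------------------------


@dataclass(frozen=True)
class AxialSensitivityProfile:
    """Per-slice relative sensitivity of one bed, peak-normalized to 1."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class BedGeometry:
    """Multi-bed axial layout: slices per bed, overlap, number of beds."""

    slices_per_bed: int = 47
    overlap_slices: int = 11
    n_beds: int = 1

    def __post_init__(self):
        if not (0 <= self.overlap_slices < self.slices_per_bed):
            raise ConfigurationError("need 0 <= overlap_slices < slices_per_bed")
        if self.n_beds < 1:
            raise ConfigurationError("n_beds must be >= 1")

    @property
    def pitch(self) -> int:
        return self.slices_per_bed - self.overlap_slices

    @property
    def total_slices(self) -> int:
        return self.pitch * (self.n_beds - 1) + self.slices_per_bed

    def bed_slice_range(self, bed: int) -> range:
        start = bed * self.pitch
        return range(start, start + self.slices_per_bed)

    def overlap_regions(self):
        """Global slice ranges where two consecutive beds both contribute."""
        return [
            range(b * self.pitch + self.pitch, b * self.pitch + self.slices_per_bed)
            for b in range(self.n_beds - 1)
        ]


def axial_sensitivity(slices_per_bed: int) -> AxialSensitivityProfile:
    """Triangular profile: 1 at the bed center, linearly falling to zero one
    slice outside each FOV edge.

    For 47 slices the edge slices carry 1/24 of the peak, and two beds
    overlapping by 11 slices sum to exactly 50% of peak over the overlap.
    """
    if slices_per_bed < 3:
        raise ConfigurationError("slices_per_bed must be >= 3")
    k = np.arange(slices_per_bed, dtype=float)
    center = (slices_per_bed - 1) / 2.0
    half = (slices_per_bed + 1) / 2.0  # zero crossing one slice outside the FOV
    s = 1.0 - np.abs(k - center) / half
    return AxialSensitivityProfile(values=s)


def combined_sensitivity(profile: AxialSensitivityProfile, geometry: BedGeometry) -> np.ndarray:
    """Sum of per-bed profiles at each global slice."""
    if len(profile) != geometry.slices_per_bed:
        raise ShapeError("profile length must equal slices_per_bed")
    out = np.zeros(geometry.total_slices)
    for b in range(geometry.n_beds):
        sl = geometry.bed_slice_range(b)
        out[sl.start : sl.stop] += profile.values
    return out


def overlap_fraction(geometry: BedGeometry) -> float:
    """Axial bed overlap as a percentage of the bed length."""
    return 100.0 * geometry.overlap_slices / geometry.slices_per_bed


# -- decay -------------------------------------------------------------------


def decayed_concentration(c0: float, elapsed_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Concentration after ``elapsed_min`` minutes of exponential decay."""
    if half_life_min <= 0:
        raise ConfigurationError("half_life must be > 0")
    if elapsed_min < 0:
        raise ConfigurationError("elapsed time must be >= 0")
    return c0 * 2.0 ** (-elapsed_min / half_life_min)


def mean_decay_factor(duration_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Time-averaged decay factor over a scan window starting at factor 1.

    Closed form of (1/T) * integral_0^T 2^(-t/hl) dt; equals 1 at T = 0.
    """
    if duration_min < 0:
        raise ConfigurationError("duration must be >= 0")
    if duration_min == 0:
        return 1.0
    lam = math.log(2.0) / half_life_min
    x = lam * duration_min
    return -math.expm1(-x) / x  # expm1 avoids cancellation for tiny x


# -- projector ---------------------------------------------------------------


class ParallelProjector:
    """Matched sparse parallel-beam projector with exact pixel chords.

    Builds one sparse matrix ``A`` of shape (n_angles * n_radial, n * n)
    whose entry (ray, pixel) is the exact intersection length (mm) of the
    ray with the square pixel, i.e. the radiological path through the
    piecewise-constant pixel basis; the adjoint is exactly ``A.T``.
    Images are square ``(n, n)`` slices in ``(x, y)`` order; multiple
    slices may be projected at once by passing a ``(n*n, nz)`` matrix.
    """

    def __init__(self, n: int, spacing_mm: float, n_angles: int, n_radial: Optional[int] = None):
        if n < 2 or n_angles < 1:
            raise ConfigurationError("need n >= 2 and n_angles >= 1")
        self.n = int(n)
        self.spacing = float(spacing_mm)
        self.n_angles = int(n_angles)
        self.n_radial = int(n_radial) if n_radial is not None else int(n)
        self.angles = np.pi * np.arange(self.n_angles) / self.n_angles
        self.matrix = self._build()

    def _chord(self, dist_mm: np.ndarray, cos_t: float, sin_t: float) -> np.ndarray:
        """Chord length of a ray at distance ``dist`` from a pixel center.

        For a square of side h viewed under angle theta the footprint is a
        symmetric trapezoid: plateau h/hi for |s| <= (hi-lo)h/2, falling
        linearly to zero at |s| = (hi+lo)h/2, where hi/lo are the larger
        and smaller of |cos|, |sin|.
        """
        h = self.spacing
        aa, bb = abs(cos_t), abs(sin_t)
        hi, lo = max(aa, bb), min(aa, bb)
        s = np.abs(dist_mm)
        plateau = (hi - lo) * h / 2.0
        edge = (hi + lo) * h / 2.0
        out = np.zeros_like(s)
        out[s <= plateau] = h / hi
        if lo > 1e-12:
            ramp = (s > plateau) & (s < edge)
            out[ramp] = (edge - s[ramp]) / (hi * lo)
        return out

    def _build(self) -> sparse.csr_matrix:
        n, nr, h = self.n, self.n_radial, self.spacing
        half = (n - 1) / 2.0
        coords = (np.arange(n) - half) * h  # pixel center world coords, mm
        t_centers = (np.arange(nr) - (nr - 1) / 2.0) * h
        pix_idx = np.arange(n * n)
        rows_all, cols_all, vals_all = [], [], []
        for a, theta in enumerate(self.angles):
            c, s = math.cos(theta), math.sin(theta)
            proj = (coords[:, None] * c + coords[None, :] * s).ravel()  # mm
            pbin = proj / h + (nr - 1) / 2.0
            base = np.round(pbin).astype(np.int64)
            for k in (-1, 0, 1):
                b = base + k
                valid = (b >= 0) & (b < nr)
                if not valid.any():
                    continue
                dist = t_centers[b[valid]] - proj[valid]
                w = self._chord(dist, c, s)
                nz = w > 0
                rows_all.append(a * nr + b[valid][nz])
                cols_all.append(pix_idx[valid][nz])
                vals_all.append(w[nz])
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        vals = np.concatenate(vals_all)
        A = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_angles * nr, n * n)
        ).tocsr()
        return A

    # -- application ---------------------------------------------------------

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Line integrals (mm-weighted) of a 2-D image -> (n_angles, n_radial)."""
        if image.shape != (self.n, self.n):
            raise ShapeError(f"expected image shape {(self.n, self.n)}, got {image.shape}")
        return (self.matrix @ image.reshape(-1)).reshape(self.n_angles, self.n_radial)

    def back(self, sino: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        if sino.shape != (self.n_angles, self.n_radial):
            raise ShapeError("sinogram shape mismatch")
        return (self.matrix.T @ sino.reshape(-1)).reshape(self.n, self.n)

    def subset_matrix(self, angle_indices: Sequence[int]) -> sparse.csr_matrix:
        """Row block of ``A`` for a subset of angles."""
        rows = np.concatenate(
            [np.arange(a * self.n_radial, (a + 1) * self.n_radial) for a in angle_indices]
        )
        return self.matrix[rows]


def radial_psf_blur(sino: np.ndarray, psf_fwhm_mm: float, bin_spacing_mm: float) -> np.ndarray:
    """Gaussian blur along the radial axis; self-adjoint (zero-padded)."""
    if psf_fwhm_mm <= 0:
        return sino
    sigma = psf_fwhm_mm * FWHM_TO_SIGMA / bin_spacing_mm
    return gaussian_filter1d(sino, sigma, axis=-1, mode="constant", cval=0.0)


# -- acquisition configuration and simulation --------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan-level parameters of the simulated acquisition."""

    time_per_bed: tuple = (300.0,)  # seconds, one entry per bed (or broadcast)
    angles: int = 120
    radial_bins: Optional[int] = None
    psf_fwhm: float = 4.0  # mm, detector-resolution blur in projection space
    calibration: float = 0.01  # expected counts per (kBq/ml * mm * s * unit sens)
    half_life_min: float = F18_HALF_LIFE_MIN
    start_time_offset_min: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        t = self.time_per_bed
        if np.isscalar(t):
            t = (float(t),)
        object.__setattr__(self, "time_per_bed", tuple(float(x) for x in t))
        if any(x <= 0 for x in self.time_per_bed):
            raise ConfigurationError("time_per_bed entries must be > 0")
        if self.calibration <= 0:
            raise ConfigurationError("calibration must be > 0")

    def bed_time(self, bed: int) -> float:
        if len(self.time_per_bed) == 1:
            return self.time_per_bed[0]
        return self.time_per_bed[bed]


@dataclass
class SinogramSet:
    """Per-bed, per-slice projection data plus everything needed to reconstruct.

    ``counts``/``expected``/``attenuation_factors`` have shape
    (n_beds, slices_per_bed, n_angles, n_radial); ``slice_scale`` holds the
    multiplicative factor (calibration x time x sensitivity x decay) that
    maps blurred, attenuated line integrals to expected counts.
    """

    counts: np.ndarray
    expected: np.ndarray
    attenuation_factors: np.ndarray
    slice_scale: np.ndarray  # (n_beds, slices_per_bed)
    geometry: BedGeometry
    sensitivity: AxialSensitivityProfile
    config: AcquisitionConfig
    grid: VoxelGrid

    @property
    def n_beds(self) -> int:
        return self.geometry.n_beds


def forward_project(
    activity_slice: np.ndarray,
    attenuation_slice: np.ndarray,
    projector: ParallelProjector,
    config: AcquisitionConfig,
    scale: float = 1.0,
) -> np.ndarray:
    """Expected sinogram of one slice: attenuated, blurred, scaled line integrals.

    ``scale`` already contains calibration x time x sensitivity x decay.
    Attenuation is integrated along the same rays (mm path; mu is 1/cm,
    hence the 0.1 conversion).
    """
    if activity_slice.shape != attenuation_slice.shape:
        raise ShapeError("activity and attenuation slices must share the grid")
    proj = projector.forward(activity_slice)
    mu_line = projector.forward(attenuation_slice) * 0.1  # mm -> cm
    att = np.exp(-mu_line)
    expected = radial_psf_blur(proj * att, config.psf_fwhm, projector.spacing)
    return expected * scale


def attenuation_factors(attenuation_slice: np.ndarray, projector: ParallelProjector) -> np.ndarray:
    """exp(-integral mu dl) along every ray of one slice."""
    return np.exp(-projector.forward(attenuation_slice) * 0.1)


def simulate_acquisition(
    volumes: LabelledVolumes,
    geometry: BedGeometry,
    config: AcquisitionConfig,
    projector: Optional[ParallelProjector] = None,
) -> SinogramSet:
    """Simulate a full multi-bed acquisition with Poisson counting noise.

    Beds are scanned sequentially; within-scan decay is integrated in
    closed form. A seed is mandatory (reproducibility contract).
    """
    if config.seed is None:
        raise ConfigurationError("AcquisitionConfig.seed is required for simulation")
    nx, ny, nz = volumes.grid.shape
    if nx != ny:
        raise ShapeError("in-plane grid must be square for the parallel projector")
    if nz < geometry.total_slices:
        raise ShapeError(
            f"volume has {nz} slices but geometry spans {geometry.total_slices}"
        )
    if projector is None:
        projector = ParallelProjector(nx, volumes.grid.spacing[0], config.angles, config.radial_bins)
    profile = axial_sensitivity(geometry.slices_per_bed)
    rng = np.random.default_rng(config.seed)

    nb, ns = geometry.n_beds, geometry.slices_per_bed
    na, nr = projector.n_angles, projector.n_radial
    expected = np.zeros((nb, ns, na, nr))
    att = np.ones((nb, ns, na, nr))
    slice_scale = np.zeros((nb, ns))

    elapsed = config.start_time_offset_min
    act_flat = volumes.activity.reshape(nx * ny, nz)
    mu_flat = volumes.attenuation.reshape(nx * ny, nz)
    for b in range(nb):
        t_sec = config.bed_time(b)
        decay = 2.0 ** (-elapsed / config.half_life_min) * mean_decay_factor(
            t_sec / 60.0, config.half_life_min
        )
        gslices = list(geometry.bed_slice_range(b))
        proj = (projector.matrix @ act_flat[:, gslices]).reshape(na, nr, ns)
        mu_line = (projector.matrix @ mu_flat[:, gslices]).reshape(na, nr, ns) * 0.1
        att_b = np.exp(-mu_line)
        blurred = radial_psf_blur(np.moveaxis(proj * att_b, 2, 0), config.psf_fwhm, projector.spacing)
        scale_b = config.calibration * t_sec * decay * profile.values
        expected[b] = blurred * scale_b[:, None, None]
        att[b] = np.moveaxis(att_b, 2, 0)
        slice_scale[b] = scale_b
        elapsed += t_sec / 60.0

    counts = rng.poisson(expected).astype(np.int64)
    return SinogramSet(
        counts=counts,
        expected=expected,
        attenuation_factors=att,
        slice_scale=slice_scale,
        geometry=geometry,
        sensitivity=profile,
        config=config,
        grid=volumes.grid,
    )


def bed_subset(sinos: SinogramSet, bed: int) -> SinogramSet:
    """View of a single bed as its own one-bed SinogramSet."""
    geometry = BedGeometry(sinos.geometry.slices_per_bed, sinos.geometry.overlap_slices, 1)
    return SinogramSet(
        counts=sinos.counts[bed : bed + 1],
        expected=sinos.expected[bed : bed + 1],
        attenuation_factors=sinos.attenuation_factors[bed : bed + 1],
        slice_scale=sinos.slice_scale[bed : bed + 1],
        geometry=geometry,
        sensitivity=sinos.sensitivity,
        config=sinos.config,
        grid=sinos.grid,
    )


def thin_counts(sinos: SinogramSet, new_time_per_bed, seed: int) -> SinogramSet:
    """Binomial-thin a stored acquisition to shorter per-bed scan times.

    Emulates retro-reconstruction from list mode: each recorded count is
    kept with probability t_new/t_orig, giving exactly the Poisson law of
    a direct shorter acquisition with matched expected counts.
    """
    if np.isscalar(new_time_per_bed):
        new_times = tuple(float(new_time_per_bed) for _ in range(sinos.n_beds))
    else:
        new_times = tuple(float(t) for t in new_time_per_bed)
    rng = np.random.default_rng(seed)
    counts = np.empty_like(sinos.counts)
    expected = np.empty_like(sinos.expected)
    slice_scale = np.empty_like(sinos.slice_scale)
    for b in range(sinos.n_beds):
        t_orig = sinos.config.bed_time(b)
        p = new_times[b] / t_orig
        if not (0 < p <= 1):
            raise ConfigurationError("thinned time must be in (0, original time]")
        if p == 1.0:
            counts[b] = sinos.counts[b]
        else:
            counts[b] = rng.binomial(sinos.counts[b], p)
        expected[b] = sinos.expected[b] * p
        slice_scale[b] = sinos.slice_scale[b] * p
    new_config = replace(sinos.config, time_per_bed=new_times, seed=seed)
    return SinogramSet(
        counts=counts,
        expected=expected,
        attenuation_factors=sinos.attenuation_factors,
        slice_scale=slice_scale,
        geometry=sinos.geometry,
        sensitivity=sinos.sensitivity,
        config=new_config,
        grid=sinos.grid,
    )
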