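"""Digital phantoms: geometric specifications and voxelization.

The module defines the two image-quality phantoms used throughout the
pipeline (a NU2-style torso phantom with six hot spheres around a cold
cylindrical lung insert, and a micro hollow-sphere phantom with five
small spheres), plus an elongated patient-like phantom spanning several
bed positions.  Phantoms are described analytically (:class:`PhantomSpec`)
and rasterized onto a :class:`VoxelGrid` with sub-voxel supersampling so
that partial-volume fractions at compartment boundaries are correct.

Conventions
-----------
* World coordinates are millimetres; volume arrays are ordered
  ``(x, y, slice)``.
* Activity concentrations are kBq/ml; attenuation is 1/cm at 511 keV.
* Region labels: 0 = outside, 1 = background, 2 = lung insert,
  ``10 + i`` = sphere ``i`` (in listed order).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, PlacementError, UndefinedRatioError

# -- physical and geometric constants ----------------------------------------

#: Linear attenuation coefficient of water at 511 keV, 1/cm.
MU_WATER_511 = 0.096
#: Lung-insert attenuation relative to water (polystyrene-bead surrogate).
LUNG_DENSITY_FACTOR = 0.3

#: Inner diameters of the six torso-phantom spheres, mm.
NEMA_SPHERE_DIAMETERS = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)
#: Inner diameters of the five micro-phantom spheres, mm.
MICRO_SPHERE_DIAMETERS = (10.0, 8.0, 6.0, 5.0, 4.0)
#: Radius of the ring on which the torso-phantom spheres sit, mm.
NEMA_RING_RADIUS = 57.2
#: Radius of the ring of the four outer micro-phantom spheres, mm
#: (chosen so no two spheres overlap; the phantom drawing gives no number).
MICRO_RING_RADIUS = 20.0
#: Lung-insert diameter, mm.
LUNG_INSERT_DIAMETER = 50.0

#: Start-of-measurement (sphere, background) concentrations in kBq/ml for
#: the three fill cases.
FILL_CONCENTRATIONS = {
    "10:1": (10.0, 1.0),
    "4:1": (6.5, 1.6),
    "2:1": (4.8, 2.6),
}
#: Scan duration per fill case, minutes.
SCAN_MINUTES = {"10:1": 5.0, "4:1": 7.0 + 10.0 / 60.0, "2:1": 10.0}

#: Axial field of view of the emulated scanner, mm, and derived slice pitch.
AXIAL_FOV_MM = 157.0
DEFAULT_SLICES_PER_BED = 47
DEFAULT_DZ = AXIAL_FOV_MM / DEFAULT_SLICES_PER_BED

LABEL_OUTSIDE = 0
LABEL_BACKGROUND = 1
LABEL_LUNG = 2
LABEL_SPHERE_BASE = 10


def _normalize_ratio_case(ratio_case) -> str:
    """Map user spellings ('10:1', '10-to-1', 10) onto canonical keys."""
    if isinstance(ratio_case, (int, float)):
        key = f"{int(ratio_case)}:1"
    else:
        key = str(ratio_case).strip().lower().replace("-to-", ":").rstrip("1").rstrip(":") + ":1"
    if key not in FILL_CONCENTRATIONS:
        raise ConfigurationError(
            f"unknown ratio case {ratio_case!r}; expected one of {sorted(FILL_CONCENTRATIONS)}"
        )
    return key


# -- specification types -----------------------------------------------------


@dataclass(frozen=True)
class SphereSpec:
    """A hot (or cold) sphere: position, inner diameter, fill concentration."""

    center: tuple  # (x, y, z) mm
    inner_diameter: float  # mm
    activity_concentration: float  # kBq/ml

    def __post_init__(self):
        if self.inner_diameter <= 0:
            raise ConfigurationError("sphere inner_diameter must be > 0")
        if self.activity_concentration < 0:
            raise ConfigurationError("sphere activity_concentration must be >= 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def volume_ml(self) -> float:
        """Analytic sphere volume in millilitres."""
        return (4.0 / 3.0) * math.pi * self.radius**3 / 1000.0


@dataclass(frozen=True)
class LungInsertSpec:
    """Cylindrical low-density insert running the axial length of its section."""

    center: tuple = (0.0, 0.0)  # (x, y) mm
    diameter: float = LUNG_INSERT_DIAMETER
    activity_concentration: float = 0.0
    density_class: str = "lung"  # 'lung' or 'water'

    def __post_init__(self):
        if self.density_class not in ("lung", "water"):
            raise ConfigurationError("density_class must be 'lung' or 'water'")


@dataclass(frozen=True)
class BodyOutline:
    """2-D closed body cross-section: an ellipse or a rounded rectangle."""

    kind: str  # 'ellipse' | 'rounded_rect'
    width: float  # full extent along x, mm
    height: float  # full extent along y, mm
    corner_radius: float = 0.0  # rounded_rect only

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "ellipse":
            return (2 * x / self.width) ** 2 + (2 * y / self.height) ** 2 <= 1.0
        if self.kind == "rounded_rect":
            r = self.corner_radius
            inside = (np.abs(x) <= self.width / 2) & (np.abs(y) <= self.height / 2)
            dx = np.abs(x) - (self.width / 2 - r)
            dy = np.abs(y) - (self.height / 2 - r)
            corner_out = (dx > 0) & (dy > 0) & (dx**2 + dy**2 > r**2)
            return inside & ~corner_out
        raise ConfigurationError(f"unknown outline kind {self.kind!r}")


#: Rounded-rectangle stand-in for the NU2 torso cross-section (mm).
NEMA_BODY_OUTLINE = BodyOutline("rounded_rect", width=300.0, height=230.0, corner_radius=77.0)
#: Small cylindrical body of the micro phantom (mm).
MICRO_BODY_OUTLINE = BodyOutline("ellipse", width=120.0, height=120.0)


@dataclass(frozen=True)
class BodySection:
    """An axial span [z_min, z_max) sharing one in-plane outline."""

    z_min: float
    z_max: float
    outline: BodyOutline

    def __post_init__(self):
        if self.z_max <= self.z_min:
            raise ConfigurationError("body section must have z_max > z_min")


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of a phantom: body sections, spheres, lung insert."""

    sections: tuple  # tuple[BodySection, ...]
    spheres: tuple = ()  # tuple[SphereSpec, ...]
    lung_insert: Optional[LungInsertSpec] = None
    background_concentration: float = 0.0
    name: str = "phantom"

    def __post_init__(self):
        object.__setattr__(self, "sections", tuple(self.sections))
        object.__setattr__(self, "spheres", tuple(self.spheres))
        if not self.sections:
            raise ConfigurationError("phantom needs at least one body section")
        for sph in self.spheres:
            sec = self.section_at(sph.center[2])
            if sec is None:
                raise PlacementError(f"sphere at z={sph.center[2]} outside axial extent")
            # in-plane containment with the sphere radius as margin
            x, y = sph.center[0], sph.center[1]
            r = sph.radius
            probe_x = np.array([x - r, x + r, x, x])
            probe_y = np.array([y, y, y - r, y + r])
            if not np.all(sec.outline.contains(probe_x, probe_y)):
                raise PlacementError(
                    f"sphere (d={sph.inner_diameter} mm) at ({x:.1f}, {y:.1f}) "
                    "extends outside the body outline"
                )

    @property
    def z_min(self) -> float:
        return min(s.z_min for s in self.sections)

    @property
    def z_max(self) -> float:
        return max(s.z_max for s in self.sections)

    @property
    def axial_length(self) -> float:
        return self.z_max - self.z_min

    def section_at(self, z: float):
        for sec in self.sections:
            if sec.z_min <= z < sec.z_max or (z == self.z_max and sec.z_max == z):
                return sec
        return None


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice: shape ``(nx, ny, nz)``, spacing and origin in mm.

    ``origin`` is the world coordinate of the *center* of voxel (0, 0, 0).
    """

    shape: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(n <= 0 for n in self.shape):
            raise ConfigurationError("grid shape entries must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("grid spacing entries must be positive")

    @classmethod
    def centered(cls, shape, spacing, z_start: float = 0.0) -> "VoxelGrid":
        """Grid centered at x = y = 0 with slice 0 centered at ``z_start + dz/2``."""
        nx, ny, nz = shape
        dx, dy, dz = spacing
        return cls(
            shape=(nx, ny, nz),
            spacing=(dx, dy, dz),
            origin=(-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, z_start + dz / 2),
        )

    def axes(self):
        """Per-axis arrays of voxel-center world coordinates."""
        return tuple(
            self.origin[i] + np.arange(self.shape[i]) * self.spacing[i] for i in range(3)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class LabelledVolumes:
    """Rasterized phantom: activity, attenuation and region-label volumes."""

    activity: np.ndarray  # kBq/ml, (nx, ny, nz)
    attenuation: np.ndarray  # 1/cm, (nx, ny, nz)
    region_labels: np.ndarray  # int, (nx, ny, nz)
    grid: VoxelGrid
    sphere_volumes_mm3: tuple = ()  # per-sphere rasterized volume (fractional)

    def sphere_mask(self, index: int) -> np.ndarray:
        return self.region_labels == LABEL_SPHERE_BASE + index

    @property
    def background_mask(self) -> np.ndarray:
        return self.region_labels == LABEL_BACKGROUND

    @property
    def lung_mask(self) -> np.ndarray:
        return self.region_labels == LABEL_LUNG


# -- builders ----------------------------------------------------------------


def build_nema_iq(ratio_case, z_center: Optional[float] = None,
                  axial_length: float = 180.0) -> PhantomSpec:
    """Torso image-quality phantom for one of the three fill cases.

    Six spheres (10-37 mm) sit on a 57.2 mm ring around a 50 mm cold lung
    insert; sphere and background concentrations follow the printed
    start-of-measurement fills (e.g. 10 and 1 kBq/ml for the 10:1 case).
    ``z_center`` places the sphere plane; it defaults to mid-phantom.
    """
    key = _normalize_ratio_case(ratio_case)
    c_sphere, c_bkg = FILL_CONCENTRATIONS[key]
    if z_center is None:
        z_center = axial_length / 2.0
    spheres = []
    for i, d in enumerate(NEMA_SPHERE_DIAMETERS):
        ang = math.radians(60.0 * i)
        spheres.append(
            SphereSpec(
                center=(NEMA_RING_RADIUS * math.cos(ang), NEMA_RING_RADIUS * math.sin(ang), z_center),
                inner_diameter=d,
                activity_concentration=c_sphere,
            )
        )
    return PhantomSpec(
        sections=(BodySection(0.0, axial_length, NEMA_BODY_OUTLINE),),
        spheres=tuple(spheres),
        lung_insert=LungInsertSpec(),
        background_concentration=c_bkg,
        name=f"nema_iq_{key.replace(':', 'to')}",
    )


def build_micro_sphere(ratio_case, z_center: Optional[float] = None,
                       axial_length: float = 100.0) -> PhantomSpec:
    """Micro hollow-sphere phantom with an extra central 10 mm sphere.

    The four smaller spheres (4, 5, 6, 8 mm) are placed equiradially
    (90 degrees apart) around the central 10 mm sphere.
    """
    key = _normalize_ratio_case(ratio_case)
    c_sphere, c_bkg = FILL_CONCENTRATIONS[key]
    if z_center is None:
        z_center = axial_length / 2.0
    spheres = [
        SphereSpec(center=(0.0, 0.0, z_center), inner_diameter=10.0,
                   activity_concentration=c_sphere)
    ]
    for i, d in enumerate((8.0, 6.0, 5.0, 4.0)):
        ang = math.radians(90.0 * i + 45.0)
        spheres.append(
            SphereSpec(
                center=(MICRO_RING_RADIUS * math.cos(ang), MICRO_RING_RADIUS * math.sin(ang), z_center),
                inner_diameter=d,
                activity_concentration=c_sphere,
            )
        )
    return PhantomSpec(
        sections=(BodySection(0.0, axial_length, MICRO_BODY_OUTLINE),),
        spheres=tuple(spheres),
        lung_insert=None,
        background_concentration=c_bkg,
        name=f"micro_{key.replace(':', 'to')}",
    )


#: Body cross-sections for the patient-like phantom, mm.
TORSO_OUTLINE = BodyOutline("ellipse", width=280.0, height=200.0)


def build_patient_like(
    n_beds: int,
    lesion_specs: Sequence[SphereSpec] = (),
    section_scales: Optional[Sequence[float]] = None,
    background_concentration: float = 2.0,
    slices_per_bed: int = DEFAULT_SLICES_PER_BED,
    overlap_slices: int = 11,
    dz: float = DEFAULT_DZ,
) -> PhantomSpec:
    """Elongated multi-bed phantom with per-bed cross-section scaling.

    Each bed owns an axial section whose outline is the torso ellipse
    scaled by ``section_scales[b]``; scales < 1 emulate leg sections with
    shorter attenuation paths.  Default: legs for all but the last bed.
    """
    if n_beds < 2:
        raise ConfigurationError("patient-like phantom needs n_beds >= 2 (one overlap)")
    pitch = slices_per_bed - overlap_slices
    total_slices = pitch * (n_beds - 1) + slices_per_bed
    if section_scales is None:
        section_scales = [0.55] * (n_beds - 1) + [1.0]
    if len(section_scales) != n_beds:
        raise ConfigurationError("section_scales must have one entry per bed")
    # section boundaries at bed-pitch multiples; last section absorbs the tail
    sections = []
    for b in range(n_beds):
        z0 = b * pitch * dz
        z1 = (b + 1) * pitch * dz if b < n_beds - 1 else total_slices * dz
        s = float(section_scales[b])
        sections.append(
            BodySection(z0, z1, BodyOutline("ellipse", TORSO_OUTLINE.width * s, TORSO_OUTLINE.height * s))
        )
    return PhantomSpec(
        sections=tuple(sections),
        spheres=tuple(lesion_specs),
        lung_insert=None,
        background_concentration=background_concentration,
        name=f"patient_like_{n_beds}bed",
    )


# -- rasterization -----------------------------------------------------------


def _subsample_offsets(spacing: float, factor: int) -> np.ndarray:
    """Sub-voxel center offsets for one axis, mm."""
    return (np.arange(factor) + 0.5) / factor * spacing - spacing / 2.0


def _plane_fraction(outline_fn, xs, ys, dx, dy, factor) -> np.ndarray:
    """Fraction of each in-plane voxel inside ``outline_fn`` (supersampled)."""
    ox = _subsample_offsets(dx, factor)
    oy = _subsample_offsets(dy, factor)
    fx = (xs[:, None] + ox[None, :]).ravel()  # nx*factor
    fy = (ys[:, None] + oy[None, :]).ravel()
    fine = outline_fn(fx[:, None], fy[None, :])
    nx, ny = len(xs), len(ys)
    fine = fine.reshape(nx, factor, ny, factor)
    return fine.mean(axis=(1, 3)).astype(float)


def rasterize(phantom: PhantomSpec, grid: VoxelGrid, supersample: int = 2) -> LabelledVolumes:
    """Rasterize a phantom onto a grid with partial-volume-correct averaging.

    Each voxel's activity is the average concentration over ``supersample``
    sub-samples per axis; attenuation is assigned by density class.  Labels
    follow the majority sub-voxel occupancy.
    """
    if supersample < 1:
        raise ConfigurationError("supersample must be >= 1")
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.spacing
    xs, ys, zs = grid.axes()
    if supersample == 1:
        small = [s for s in phantom.spheres if s.inner_diameter < min(dx, dy, dz)]
        if small:
            warnings.warn(
                f"{len(small)} sphere(s) smaller than one voxel with supersample=1: "
                "volumes will be quantized", stacklevel=2,
            )

    activity = np.zeros(grid.shape, dtype=float)
    mu = np.zeros(grid.shape, dtype=float)
    labels = np.zeros(grid.shape, dtype=np.int16)

    # body fraction per section (z-independent in-plane shape)
    plane_cache = {}
    body_frac = np.zeros(grid.shape, dtype=float)
    for k, z in enumerate(zs):
        sec = phantom.section_at(z)
        if sec is None:
            continue
        if id(sec.outline) not in plane_cache:
            plane_cache[id(sec.outline)] = _plane_fraction(
                sec.outline.contains, xs, ys, dx, dy, supersample
            )
        body_frac[:, :, k] = plane_cache[id(sec.outline)]

    c_bkg = phantom.background_concentration
    activity += c_bkg * body_frac
    mu += MU_WATER_511 * body_frac
    labels[body_frac > 0.5] = LABEL_BACKGROUND

    # lung insert: cylinder through every slice of the phantom
    if phantom.lung_insert is not None:
        li = phantom.lung_insert
        lung_outline = BodyOutline("ellipse", li.diameter, li.diameter)

        def lung_fn(x, y, _li=li, _o=lung_outline):
            return _o.contains(x - _li.center[0], y - _li.center[1])

        lung_plane = _plane_fraction(lung_fn, xs, ys, dx, dy, supersample)
        lung_frac = lung_plane[:, :, None] * (body_frac > 0).astype(float)
        lung_frac = np.minimum(lung_frac, body_frac)
        activity += (li.activity_concentration - c_bkg) * lung_frac
        if li.density_class == "lung":
            mu += (MU_WATER_511 * LUNG_DENSITY_FACTOR - MU_WATER_511) * lung_frac
        labels[lung_frac > 0.5] = LABEL_LUNG

    # spheres: 3-D supersampled fractions within bounding boxes
    ox = _subsample_offsets(dx, supersample)
    oy = _subsample_offsets(dy, supersample)
    oz = _subsample_offsets(dz, supersample)
    sphere_volumes = []
    for i, sph in enumerate(phantom.spheres):
        cx, cy, cz = sph.center
        r = sph.radius
        ix = np.nonzero(np.abs(xs - cx) <= r + dx)[0]
        iy = np.nonzero(np.abs(ys - cy) <= r + dy)[0]
        iz = np.nonzero(np.abs(zs - cz) <= r + dz)[0]
        if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
            sphere_volumes.append(0.0)
            continue
        fx = xs[ix][:, None] + ox[None, :]  # (bx, s)
        fy = ys[iy][:, None] + oy[None, :]
        fz = zs[iz][:, None] + oz[None, :]
        d2 = (
            (fx[:, :, None, None, None, None] - cx) ** 2
            + (fy[None, None, :, :, None, None] - cy) ** 2
            + (fz[None, None, None, None, :, :] - cz) ** 2
        )
        frac = (d2 <= r * r).mean(axis=(1, 3, 5))
        vol = float(frac.sum()) * grid.voxel_volume_mm3
        sphere_volumes.append(vol)
        sub = np.ix_(ix, iy, iz)
        activity[sub] += (sph.activity_concentration - c_bkg) * frac
        lab = labels[sub]
        lab[frac > 0.5] = LABEL_SPHERE_BASE + i
        labels[sub] = lab

    np.maximum(activity, 0.0, out=activity)
    return LabelledVolumes(
        activity=activity,
        attenuation=mu,
        region_labels=labels,
        grid=grid,
        sphere_volumes_mm3=tuple(sphere_volumes),
    )


def sphere_to_background_ratio(phantom: PhantomSpec) -> float:
    """Quotient of the (common) sphere concentration over the background."""
    if phantom.background_concentration <= 0:
        raise UndefinedRatioError("background concentration must be > 0 for a ratio")
    if not phantom.spheres:
        raise ConfigurationError("phantom has no spheres")
    concs = {s.activity_concentration for s in phantom.spheres}
    if len(concs) > 1:
        raise ConfigurationError(f"spheres have differing concentrations: {sorted(concs)}")
    return concs.pop() / phantom.background_concentration
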