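"""Image-quality metrics: recovery coefficients, background variability,
residual lung error, per-slice COV profiles and the two model fits
(noise-vs-counts power law, contrast-ratio-vs-size exponential decay).

All statistics use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .acquisition import BedGeometry
from .errors import FitError, UndefinedRatioError
from .phantoms import LABEL_BACKGROUND, LABEL_SPHERE_BASE, SphereSpec, VoxelGrid


def sample_sd(x: np.ndarray) -> float:
    return float(np.std(np.asarray(x, dtype=float), ddof=1))


# -- recovery coefficients ----------------------------------------------------


@dataclass
class RecoveryEntry:
    diameter: float
    measured_mean: float
    true_concentration: float
    recovery_coefficient: float
    voi_voxel_count: int
    invisible: bool = False


def _grid_index(grid: VoxelGrid, center) -> tuple:
    return tuple(
        int(round((center[i] - grid.origin[i]) / grid.spacing[i])) for i in range(3)
    )


def voi50_recovery(
    values: np.ndarray,
    grid: VoxelGrid,
    sphere: SphereSpec,
    background_mean: float,
    invisible_margin: float = 0.1,
) -> RecoveryEntry:
    """Background-corrected 50%-isocontour recovery coefficient of one sphere.

    Within a box of 1.5x the sphere diameter around the known center, the
    VOI is the connected set of voxels >= background_mean + 0.5*(local max
    - background_mean) containing the hottest voxel.  The recovery
    coefficient is the VOI mean over the true fill concentration.  If the
    local max does not exceed background the sphere is invisible and the
    entry is flagged with the RC pinned at the background level; a VOI mean
    within ``invisible_margin`` of background is flagged as (almost)
    invisible too.
    """
    if sphere.activity_concentration <= 0:
        raise UndefinedRatioError("recovery undefined for zero true concentration")
    ci = _grid_index(grid, sphere.center)
    half = [
        max(1, int(np.ceil(0.75 * sphere.inner_diameter / grid.spacing[i])))
        for i in range(3)
    ]
    sl = tuple(
        slice(max(0, ci[i] - half[i]), min(values.shape[i], ci[i] + half[i] + 1))
        for i in range(3)
    )
    box = values[sl]
    local_max = float(box.max())
    if local_max <= background_mean:
        return RecoveryEntry(
            diameter=sphere.inner_diameter,
            measured_mean=background_mean,
            true_concentration=sphere.activity_concentration,
            recovery_coefficient=background_mean / sphere.activity_concentration,
            voi_voxel_count=0,
            invisible=True,
        )
    threshold = background_mean + 0.5 * (local_max - background_mean)
    mask = box >= threshold
    labels, _ = ndimage.label(mask)
    peak = np.unravel_index(int(np.argmax(box)), box.shape)
    voi = labels == labels[peak]
    measured = float(box[voi].mean())
    almost_background = measured <= background_mean * (1.0 + invisible_margin)
    return RecoveryEntry(
        diameter=sphere.inner_diameter,
        measured_mean=measured,
        true_concentration=sphere.activity_concentration,
        recovery_coefficient=measured / sphere.activity_concentration,
        voi_voxel_count=int(voi.sum()),
        invisible=almost_background,
    )


def recovery_table(
    values: np.ndarray,
    grid: VoxelGrid,
    spheres: Sequence[SphereSpec],
    background_mean: float,
) -> pd.DataFrame:
    rows = [voi50_recovery(values, grid, s, background_mean).__dict__ for s in spheres]
    return pd.DataFrame(rows).sort_values("diameter").reset_index(drop=True)


# -- background variability ---------------------------------------------------


def _disk_mask(grid: VoxelGrid, center_xy, diameter: float) -> np.ndarray:
    xs = grid.origin[0] + np.arange(grid.shape[0]) * grid.spacing[0]
    ys = grid.origin[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    r = diameter / 2.0
    return (xs[:, None] - center_xy[0]) ** 2 + (ys[None, :] - center_xy[1]) ** 2 <= r * r


def background_variability(
    values: np.ndarray,
    grid: VoxelGrid,
    sphere_diameters: Sequence[float],
    roi_centers_xy: Sequence[Tuple[float, float]],
    slice_indices: Sequence[int],
    region_labels: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """NU2-style background variability per sphere size.

    For each diameter, circular ROIs are drawn at every (center, slice)
    position and N% = 100 * SD(ROI means) / mean(ROI means).  ROIs whose
    footprint leaves the background region (when labels are given) are
    excluded with a warning.
    """
    rows = []
    for d in sphere_diameters:
        means = []
        n_excluded = 0
        for cx, cy in roi_centers_xy:
            disk = _disk_mask(grid, (cx, cy), d)
            if not disk.any():
                n_excluded += len(slice_indices)
                continue
            for k in slice_indices:
                if region_labels is not None:
                    if not np.all(region_labels[:, :, k][disk] == LABEL_BACKGROUND):
                        n_excluded += 1
                        continue
                means.append(float(values[:, :, k][disk].mean()))
        if n_excluded:
            warnings.warn(
                f"{n_excluded} background ROI(s) of {d} mm excluded (outside background)",
                stacklevel=2,
            )
        if len(means) < 2:
            rows.append({"diameter": d, "variability_pct": np.nan, "n_rois": len(means)})
            continue
        m = float(np.mean(means))
        rows.append(
            {
                "diameter": d,
                "variability_pct": 100.0 * sample_sd(means) / m if m != 0 else np.nan,
                "n_rois": len(means),
            }
        )
    return pd.DataFrame(rows)


# -- residual lung error ------------------------------------------------------


@dataclass
class LungErrorResult:
    residual_error_pct: float  # mean over slices
    sd_pct: float
    per_slice_pct: np.ndarray


def residual_lung_error(
    values: np.ndarray,
    grid: VoxelGrid,
    lung_center_xy: Tuple[float, float],
    background_mean: float,
    slice_indices: Sequence[int],
    roi_diameter: float = 30.0,
) -> LungErrorResult:
    """Apparent activity in the (cold) lung insert relative to background.

    Per evaluated slice: 100 * mean(lung ROI) / background_mean; the ROI is
    a 30 mm circle centered on the insert.
    """
    if background_mean <= 0:
        raise UndefinedRatioError("background mean must be > 0")
    disk = _disk_mask(grid, lung_center_xy, roi_diameter)
    per_slice = np.array(
        [100.0 * float(values[:, :, k][disk].mean()) / background_mean for k in slice_indices]
    )
    sd = sample_sd(per_slice) if len(per_slice) > 1 else 0.0
    return LungErrorResult(
        residual_error_pct=float(per_slice.mean()), sd_pct=sd, per_slice_pct=per_slice
    )


# -- per-slice COV profile ----------------------------------------------------


def cov_per_slice(
    values: np.ndarray,
    roi_mask: np.ndarray,
    geometry: Optional[BedGeometry] = None,
    slice_indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Slice-by-slice mean, sample SD and COV within an in-plane ROI.

    ``roi_mask`` is either a 2-D in-plane mask applied to every slice or a
    3-D per-slice mask.  Slices with an empty ROI or nonpositive mean are
    flagged and get NaN COV.  When a geometry is given, slices are
    annotated with overlap membership.
    """
    nz = values.shape[2]
    if slice_indices is None:
        slice_indices = range(nz)
    overlap = np.zeros(nz, dtype=bool)
    if geometry is not None:
        for reg in geometry.overlap_regions():
            overlap[reg.start : reg.stop] = True
    rows = []
    for k in slice_indices:
        mask = roi_mask if roi_mask.ndim == 2 else roi_mask[:, :, k]
        vals = values[:, :, k][mask]
        if vals.size < 2:
            rows.append({"slice": k, "mean": np.nan, "sd": np.nan, "cov": np.nan,
                         "flag": "empty_roi", "in_overlap": bool(overlap[k])})
            continue
        m = float(vals.mean())
        sd = sample_sd(vals)
        cov = sd / m if m > 0 else np.nan
        rows.append({"slice": k, "mean": m, "sd": sd, "cov": cov,
                     "flag": "" if m > 0 else "nonpositive_mean",
                     "in_overlap": bool(overlap[k])})
    return pd.DataFrame(rows)


# -- fits ---------------------------------------------------------------------


@dataclass
class NoiseCountsFit:
    coefficient: float  # a in COV = a * N^b
    exponent: float  # b
    r_squared: float
    points: tuple


def fit_noise_vs_counts(points: Sequence[Tuple[float, float]]) -> NoiseCountsFit:
    """Least-squares fit of log COV = log a + b log N.

    Poisson statistics predict b = -1/2; the result reports the fitted
    exponent so its deviation from -0.5 can be checked.
    """
    pts = [(float(n), float(c)) for n, c in points]
    if len(pts) < 3:
        raise FitError("need at least 3 points")
    N = np.array([p[0] for p in pts])
    C = np.array([p[1] for p in pts])
    if np.any(N <= 0) or np.any(C <= 0):
        raise FitError("counts and COV must be positive for a log-log fit")
    if len(np.unique(N)) < 2:
        raise FitError("degenerate fit: all points share one N")
    x, y = np.log(N), np.log(C)
    b, loga = np.polyfit(x, y, 1)
    resid = y - (loga + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return NoiseCountsFit(coefficient=float(np.exp(loga)), exponent=float(b),
                          r_squared=r2, points=tuple(pts))


def cross_calibrate_micro(
    rc_micro: Dict[float, float], rc_micro_10mm: float, rc_nema_10mm: float
) -> Dict[float, float]:
    """Rescale micro-phantom RCs so the shared 10 mm sphere matches the torso
    phantom's 10 mm result (attenuation cross-calibration)."""
    if rc_micro_10mm <= 0 or rc_nema_10mm <= 0:
        raise UndefinedRatioError("both 10 mm recovery coefficients must be > 0")
    factor = rc_nema_10mm / rc_micro_10mm
    return {d: rc * factor for d, rc in rc_micro.items()}


@dataclass
class SizeRatioFit:
    y_inf: float
    amplitude: float
    tau: float
    r_squared: float
    degenerate: bool = False


def fit_ratio_vs_size(points: Sequence[Tuple[float, float]]) -> SizeRatioFit:
    """Nonlinear fit of y(d) = y_inf + A * exp(-d / tau) to (diameter, ratio).

    Constant inputs are reported as degenerate (A ~ 0, undefined R^2).
    """
    pts = [(float(d), float(y)) for d, y in points]
    if len(pts) < 4:
        raise FitError("need at least 4 points")
    d = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(y) < 1e-12:
        return SizeRatioFit(y_inf=float(y.mean()), amplitude=0.0, tau=np.inf,
                            r_squared=np.nan, degenerate=True)

    def model(dd, y_inf, A, tau):
        return y_inf + A * np.exp(-dd / tau)

    span = max(np.ptp(d), 1.0)
    p0 = (max(float(y.min()), 1e-6), float(y.max() - y.min()), span / 3.0)
    try:
        popt, _ = optimize.curve_fit(
            model, d, y, p0=p0,
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"exponential fit failed to converge (p0={p0}): {exc}") from exc
    resid = y - model(d, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return SizeRatioFit(y_inf=float(popt[0]), amplitude=float(popt[1]),
                        tau=float(popt[2]), r_squared=r2)
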