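"""SUV normalization and VOI definition.

Masks are defined once (on a reference image, e.g. the full-count
reconstruction) and reused voxel-for-voxel on the test and retest halves —
never re-segmented per half, so the VOI geometry is identical across the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridImage

__all__ = [
    "SUVCalibration",
    "VOIMask",
    "to_suv",
    "sphere_mask",
    "auto_contour_tbr",
    "tumor_sphere_series",
    "mirrored_center",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SUVCalibration:
    """Injected dose (MBq) and body weight (kg) for SUV normalization."""

    injected_dose_mbq: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0 or self.body_weight_kg <= 0:
            raise ValueError("injected dose and body weight must be > 0")

    @property
    def dose_per_kg(self) -> float:
        return self.injected_dose_mbq / self.body_weight_kg


@dataclass
class VOIMask:
    """Boolean VOI aligned to a :class:`~radrep.grid.GridImage`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    label: str = "voi"
    nominal_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        """Realized volume: voxel count times voxel volume."""
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0

    def values_in(self, image: GridImage) -> np.ndarray:
        if image.shape != self.mask.shape:
            raise ValueError("mask grid does not match image grid")
        return np.asarray(image.values)[self.mask]


def to_suv(image: GridImage, cal: SUVCalibration) -> GridImage:
    """Normalize activity to SUV: tissue activity / (injected dose per kg)."""
    out = image.with_values(np.asarray(image.values, dtype=float) / cal.dose_per_kg, unit="SUV")
    return out


def sphere_mask(image: GridImage, center_mm, diameter_mm: float, label: str = "sphere") -> VOIMask:
    """Spherical VOI: voxels whose centers lie within diameter/2 of ``center_mm``.

    Voxel-center inclusion, no partial volumes; the realized volume converges
    to the analytic 4/3*pi*r^3 as spacing shrinks.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be > 0")
    radius = diameter_mm / 2.0
    axes = image.axis_coordinates()
    extent_lo = [axes[ax][0] for ax in range(3)]
    extent_hi = [axes[ax][-1] for ax in range(3)]
    if any(center_mm[ax] < extent_lo[ax] - radius or center_mm[ax] > extent_hi[ax] + radius for ax in range(3)):
        raise ValueError("sphere lies fully outside the grid")
    d2 = (
        (axes[0] - center_mm[0])[:, None, None] ** 2
        + (axes[1] - center_mm[1])[None, :, None] ** 2
        + (axes[2] - center_mm[2])[None, None, :] ** 2
    )
    mask = d2 <= radius**2
    if not mask.any():
        # sub-voxel sphere: take the voxel whose center is nearest
        mask = d2 == d2.min()
    return VOIMask(mask, image.spacing, label=label, nominal_diameter_mm=float(diameter_mm))


def auto_contour_tbr(image: GridImage, background: VOIMask, threshold: float = 1.6) -> VOIMask:
    """Threshold-based 3D auto-contour of the tumor.

    Candidate voxels have SUV >= threshold * (mean SUV in the background VOI);
    the returned contour is the 26-connected candidate component containing
    the global-maximum voxel.
    """
    vals = np.asarray(image.values, dtype=float)
    if background.mask.shape != vals.shape:
        raise ValueError("background mask grid does not match image")
    bg_mean = float(vals[background.mask].mean())
    if bg_mean <= 0:
        raise ValueError("background mean must be positive")
    candidates = vals >= threshold * bg_mean
    if not candidates.any():
        raise ValueError("no tumor detected: no voxel reaches the TBR threshold")
    peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
    if background.mask[peak]:
        warnings.warn("global maximum lies inside the background VOI")
    labels, _ = ndimage.label(candidates, structure=_CONNECTIVITY_26)
    peak_label = labels[peak]
    if peak_label == 0:
        # peak below threshold cannot happen (max >= threshold*mean implied by
        # candidates non-empty only if max is a candidate); guard anyway
        raise ValueError("no tumor detected: maximum voxel below threshold")
    return VOIMask(labels == peak_label, image.spacing, label="tumor_contour")


def tumor_sphere_series(image: GridImage, tumor: VOIMask, diameters_mm) -> list[VOIMask]:
    """Spherical VOIs of several diameters, all centered on the max-uptake voxel.

    The center is the argmax-SUV voxel inside the tumor mask; ties are broken
    deterministically at the lowest linear index (with a warning).
    """
    vals = np.asarray(image.values, dtype=float)
    if tumor.mask.shape != vals.shape:
        raise ValueError("tumor mask grid does not match image")
    in_tumor = np.where(tumor.mask.ravel())[0]
    tumor_vals = vals.ravel()[in_tumor]
    peak_val = tumor_vals.max()
    ties = in_tumor[tumor_vals == peak_val]
    if len(ties) > 1:
        warnings.warn(f"{len(ties)} voxels tie at the maximum; using lowest linear index")
    center_idx = np.unravel_index(int(ties[0]), vals.shape)
    axes = image.axis_coordinates()
    center_mm = tuple(float(axes[ax][center_idx[ax]]) for ax in range(3))
    return [
        sphere_mask(image, center_mm, d, label="tumor_sphere") for d in diameters_mm
    ]


def mirrored_center(image: GridImage, tumor_center_mm, axis: int = 0) -> tuple[float, float, float]:
    """Mirror a point across the grid midline along ``axis`` (background placement)."""
    axes = image.axis_coordinates()
    mid = 0.5 * (axes[axis][0] + axes[axis][-1])
    center = list(float(c) for c in tumor_center_mm)
    center[axis] = 2.0 * mid - center[axis]
    return tuple(center)
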