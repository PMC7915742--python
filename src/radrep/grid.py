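"""3D scalar grids with physical voxel geometry.

All images in this package live on a regular axis-aligned grid described by a
voxel ``spacing`` (mm per voxel edge) and an ``origin`` (physical position of
the center of voxel ``(0, 0, 0)`` in mm).  Array axis ``i`` maps to physical
axis ``i``; no orientation matrix beyond the diagonal affine is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["GridImage", "gaussian_smooth_mm", "fwhm_to_sigma"]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full-width-at-half-maximum to a standard deviation."""
    return float(fwhm) / _FWHM_PER_SIGMA


@dataclass
class GridImage:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : ndarray
        3D array of voxel values.
    spacing : tuple of float
        Voxel edge lengths in mm, one per array axis; all > 0.
    origin : tuple of float
        Physical coordinates (mm) of the center of voxel (0, 0, 0).
    unit : str
        Free-form unit tag (e.g. ``"activity"``, ``"SUV"``, ``"counts"``).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "arbitrary"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("grid must have at least one voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates (mm) along each axis."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax])
            for ax in range(3)
        )

    def same_grid(self, other: "GridImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "GridImage":
        """New image on the same grid with different voxel values."""
        if np.shape(values) != self.shape:
            raise ValueError("values shape does not match grid shape")
        return replace(self, values=np.asarray(values), unit=unit or self.unit, meta=dict(self.meta))

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, unit: str = "arbitrary") -> "GridImage":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return cls(np.asarray(img.get_fdata()), spacing=spacing, origin=origin, unit=unit)


def gaussian_smooth_mm(image: GridImage, fwhm_mm: float) -> GridImage:
    """Gaussian smoothing with an isotropic FWHM given in mm.

    A FWHM of 0 is the identity.  The kernel is expressed per axis in voxel
    units so anisotropic spacings are handled correctly.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return image.with_values(image.values.copy())
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in image.spacing]
    return image.with_values(ndimage.gaussian_filter(np.asarray(image.values, dtype=float), sigma_vox, mode="nearest"))
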