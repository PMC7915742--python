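"""Filtered image variants: single-level 3D wavelet decompositions and LoG scales.

Each source image yields exactly 14 variants: the original, the 8 axis
combinations of a single-level undecimated separable wavelet transform
(low/high pass per axis), and Laplacian-of-Gaussian responses at 5 sigmas.
All variants stay on the source grid so VOI masks remain valid unchanged.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import ndimage

from .grid import GridImage

__all__ = [
    "COIF1_DEC_LO",
    "COIF1_DEC_HI",
    "WAVELET_NAMES",
    "DEFAULT_LOG_SIGMAS_MM",
    "log_filter",
    "wavelet_decompositions",
    "image_variants",
    "variant_names",
]

# Coiflets-1 analysis filter bank (6 taps).  DC gain of the low-pass branch is
# sqrt(2); the high-pass branch has zero DC gain.
COIF1_DEC_LO = np.array(
    [
        -0.015655728135464787,
        -0.07273261951285,
        0.384864846864203,
        0.85257202021226,
        0.337897662457809,
        -0.07273261951285,
    ]
)
COIF1_DEC_HI = np.array(
    [
        0.07273261951285,
        0.337897662457809,
        -0.85257202021226,
        0.384864846864203,
        0.07273261951285,
        -0.015655728135464787,
    ]
)

#: DC gain of the low-pass kernel; the LLL variant of a constant image c is
#: c * LOWPASS_DC_GAIN ** 3.
LOWPASS_DC_GAIN = float(COIF1_DEC_LO.sum())

WAVELET_NAMES = tuple(
    "wavelet_" + "".join(combo) for combo in itertools.product("LH", repeat=3)
)

DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)


def log_filter(image: GridImage, sigma_mm: float) -> GridImage:
    """Scale-normalized Laplacian-of-Gaussian response at scale ``sigma_mm``.

    The kernel is expressed in physical units: sigma is converted per axis to
    voxels via the grid spacing, and the response is multiplied by sigma^2 so
    responses at different scales are comparable (scale-space normalization).
    Boundaries are handled by reflective padding.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    if sigma_mm < min(image.spacing) / 2.0:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is under-resolved for voxel spacing {image.spacing}"
        )
    sigma_vox = [sigma_mm / s for s in image.spacing]
    response = ndimage.gaussian_laplace(
        np.asarray(image.values, dtype=float), sigma=sigma_vox, mode="reflect"
    )
    out = image.with_values(sigma_mm**2 * response, unit=image.unit)
    return out


def _separable_filter(values: np.ndarray, kernels) -> np.ndarray:
    out = np.asarray(values, dtype=float)
    for axis, kernel in enumerate(kernels):
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="reflect")
    return out


def wavelet_decompositions(image: GridImage, wavelet: str = "coif1") -> dict[str, GridImage]:
    """All 8 single-level undecimated wavelet variants (LLL ... HHH).

    The transform is separable: per axis either the low-pass (L) or high-pass
    (H) analysis kernel is applied, undecimated, with reflective boundary
    handling, so every variant lives on the source grid.
    """
    if wavelet != "coif1":
        raise ValueError(f"unsupported wavelet {wavelet!r}; only 'coif1' is shipped")
    if min(image.shape) < len(COIF1_DEC_LO):
        raise ValueError("grid too small for one wavelet decomposition level")
    bank = {"L": COIF1_DEC_LO, "H": COIF1_DEC_HI}
    out: dict[str, GridImage] = {}
    for name in WAVELET_NAMES:
        letters = name.split("_")[1]
        kernels = [bank[c] for c in letters]
        out[name] = image.with_values(_separable_filter(image.values, kernels))
    return out


def variant_names(log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM) -> list[str]:
    """Canonical ordered variant names: original, 8 wavelet, then LoG scales."""
    return (
        ["original"]
        + list(WAVELET_NAMES)
        + [f"log_sigma_{_fmt_sigma(s)}_mm" for s in log_sigmas_mm]
    )


def _fmt_sigma(sigma: float) -> str:
    return f"{sigma:g}".replace(".", "_")


def image_variants(
    image: GridImage, log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM, wavelet: str = "coif1"
) -> dict[str, GridImage]:
    """The full variant set for one image: 1 original + 8 wavelet + len(sigmas) LoG."""
    out: dict[str, GridImage] = {"original": image}
    out.update(wavelet_decompositions(image, wavelet=wavelet))
    for sigma in log_sigmas_mm:
        out[f"log_sigma_{_fmt_sigma(sigma)}_mm"] = log_filter(image, sigma)
    return out
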