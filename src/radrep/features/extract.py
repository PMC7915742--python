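"""Feature extraction drivers: per-VOI, per-variant, and per test/retest pair.

Filtering runs on the full image grid *before* any cropping so filter kernels
see their spatial context; matrix computation then works on the VOI bounding
box for speed.  No voxel resampling is performed anywhere — features are
computed on the native grid.
"""

from __future__ import annotations

import numpy as np

from ..filters import DEFAULT_LOG_SIGMAS_MM, image_variants
from ..grid import GridImage
from ..segmentation import VOIMask
from .discretize import DEFAULT_BIN_WIDTH, discretize
from .firstorder import first_order_features
from .manifest import BASE_FEATURE_NAMES
from .texture import texture_features

__all__ = ["voi_features", "variant_feature_vector", "extract_pair"]


def _bounding_box(mask: np.ndarray, margin: int = 1):
    idx = np.where(mask)
    return tuple(
        slice(max(int(i.min()) - margin, 0), min(int(i.max()) + margin + 1, n))
        for i, n in zip(idx, mask.shape)
    )


def voi_features(
    image: GridImage, voi: VOIMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> dict[str, float]:
    """The 93-feature bank of one image (or image variant) over one VOI."""
    if voi.mask.shape != image.shape:
        raise ValueError("VOI grid does not match image grid")
    box = _bounding_box(voi.mask)
    vals = np.asarray(image.values, dtype=float)[box]
    mask = voi.mask[box]

    out: dict[str, float] = {}
    for name, value in first_order_features(vals[mask], image.voxel_volume_mm3, bin_width).items():
        out[f"firstorder_{name}"] = value
    disc = discretize(vals, mask, bin_width)
    out.update(texture_features(disc))
    assert tuple(out) == BASE_FEATURE_NAMES
    return out


def variant_feature_vector(
    image: GridImage,
    voi: VOIMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
    log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM,
    wavelet: str = "coif1",
    variants: dict[str, GridImage] | None = None,
) -> dict[str, float]:
    """The full 1,302-feature vector: 93 features on each of the 14 variants.

    Pass a precomputed ``variants`` dict to amortize filtering across several
    VOIs of the same image.
    """
    if variants is None:
        variants = image_variants(image, log_sigmas_mm=log_sigmas_mm, wavelet=wavelet)
    out: dict[str, float] = {}
    for vname, vimage in variants.items():
        for base, value in voi_features(vimage, voi, bin_width).items():
            out[f"{vname}_{base}"] = value
    return out


def extract_pair(
    test: GridImage,
    retest: GridImage,
    voi: VOIMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
    log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM,
    wavelet: str = "coif1",
    test_variants: dict[str, GridImage] | None = None,
    retest_variants: dict[str, GridImage] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Feature vectors for both halves of a test/retest pair on one shared VOI.

    The mask is applied voxel-for-voxel to both halves; feature name order is
    identical across halves and subjects.
    """
    if not test.same_grid(retest):
        raise ValueError("test and retest must share one grid")
    f_test = variant_feature_vector(
        test, voi, bin_width, log_sigmas_mm, wavelet, variants=test_variants
    )
    f_retest = variant_feature_vector(
        retest, voi, bin_width, log_sigmas_mm, wavelet, variants=retest_variants
    )
    return f_test, f_retest
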