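"""Fixed-bin-width gray-level discretization of VOI intensities.

The rule is anchored at the VOI minimum: ``level = floor((x - min)/w) + 1``.
Levels run from 1 to Ng where Ng is the highest assigned level.  A fixed bin
width (default 0.15, the recommended PET setting) governs; the realized bin
count is reported and a warning is logged when it differs from the nominal 64.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedVOI", "discretize", "DEFAULT_BIN_WIDTH", "NOMINAL_BIN_COUNT"]

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.15
NOMINAL_BIN_COUNT = 64

_warned_bin_count = False


@dataclass
class DiscretizedVOI:
    """Integer gray levels for the in-mask voxels of one VOI.

    ``levels`` is a 3D int array over the VOI bounding box with 0 outside the
    mask and values 1..Ng inside.  ``flat_levels`` is the 1D in-mask vector.
    """

    levels: np.ndarray
    mask: np.ndarray
    bin_width: float
    bin_edges: np.ndarray
    ng: int

    @property
    def flat_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(values: np.ndarray, mask: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedVOI:
    """Discretize the in-mask voxels of ``values`` with a fixed bin width.

    A constant VOI degenerates to a single level (Ng = 1), which is valid.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(values, dtype=float)
    if vals.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    in_vals = vals[mask]
    if not np.all(np.isfinite(in_vals)):
        raise ValueError("non-finite intensities in VOI")

    lo = float(in_vals.min())
    levels3d = np.zeros(mask.shape, dtype=np.int32)
    levels3d[mask] = np.floor((in_vals - lo) / bin_width).astype(np.int64) + 1
    ng = int(levels3d.max())
    edges = lo + bin_width * np.arange(ng + 1)
    if ng != NOMINAL_BIN_COUNT:
        # warn once per process, then demote to debug to avoid flooding cohort runs
        global _warned_bin_count
        if not _warned_bin_count:
            log.warning(
                "realized bin count %d differs from nominal %d "
                "(fixed bin width governs; further occurrences logged at DEBUG)",
                ng,
                NOMINAL_BIN_COUNT,
            )
            _warned_bin_count = True
        else:
            log.debug("realized bin count %d differs from nominal %d", ng, NOMINAL_BIN_COUNT)
    return DiscretizedVOI(levels=levels3d, mask=mask, bin_width=float(bin_width), bin_edges=edges, ng=ng)
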