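"""Gray-level texture matrices: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All builders consume a :class:`~radrep.features.discretize.DiscretizedVOI`
(levels 1..Ng inside the mask, 0 outside) and are fully vectorized; brute
force voxel/run/zone enumerators in the test suite serve as independent
oracles.

Conventions (matching the de-facto reference implementation's defaults):

* 13 unique 3D directions at Chebyshev distance 1; each GLCM is symmetric.
* GLRLM runs are maximal same-level segments along a direction within the
  mask; one matrix per direction.
* GLSZM zones are 26-connected same-level components (direction-free).
* GLDM dependence at distance 1, similarity tolerance alpha: the dependence
  of a voxel is 1 + the number of its 26-neighbors (in mask) whose level
  differs by at most alpha, i.e. the center voxel counts itself.
* NGTDM compares each voxel's level with the mean level of its in-mask
  26-neighborhood; voxels without any valid neighbor are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVOI

__all__ = [
    "DIRECTIONS_13",
    "NGTDMData",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_data",
]

# the 13 unique direction offsets (one per +/- pair) at Chebyshev distance 1
DIRECTIONS_13 = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)

_OFFSETS_26 = tuple(d for d in DIRECTIONS_13) + tuple(
    tuple(-x for x in d) for d in DIRECTIONS_13
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shift_slices(shape, offset):
    """Slice pairs (a, b) so arr[a] and arr[b] are voxel pairs v and v+offset."""
    sa, sb = [], []
    for ax, o in enumerate(offset):
        n = shape[ax]
        if o >= 0:
            sa.append(slice(0, n - o))
            sb.append(slice(o, n))
        else:
            sa.append(slice(-o, n))
            sb.append(slice(0, n + o))
    return tuple(sa), tuple(sb)


def glcm_matrices(disc: DiscretizedVOI) -> list[np.ndarray]:
    """One symmetric Ng x Ng co-occurrence count matrix per direction."""
    lv = disc.levels
    ng = disc.ng
    out = []
    for offset in DIRECTIONS_13:
        sa, sb = _shift_slices(lv.shape, offset)
        a, b = lv[sa], lv[sb]
        valid = (a > 0) & (b > 0)
        av, bv = a[valid], b[valid]
        mat = np.zeros((ng, ng), dtype=np.int64)
        np.add.at(mat, (av - 1, bv - 1), 1)
        out.append(mat + mat.T)
    return out


def glrlm_matrices(disc: DiscretizedVOI) -> list[np.ndarray]:
    """One Ng x max-run-length run-length count matrix per direction."""
    coords = np.argwhere(disc.mask)
    levels = disc.levels[disc.mask]
    ng = disc.ng
    max_len = int(max(disc.mask.shape))
    out = []
    for offset in DIRECTIONS_13:
        d = np.asarray(offset)
        primary = int(np.nonzero(d)[0][0])
        t = coords[:, primary] * int(np.sign(d[primary]))
        line_key = coords - t[:, None] * d  # constant along a line
        order = np.lexsort((t, line_key[:, 2], line_key[:, 1], line_key[:, 0]))
        ts, ks, lvs = t[order], line_key[order], levels[order]
        if len(lvs) == 1:
            breaks = np.zeros(0, dtype=bool)
        else:
            breaks = (
                np.any(np.diff(ks, axis=0) != 0, axis=1)
                | (np.diff(ts) != 1)
                | (np.diff(lvs) != 0)
            )
        starts = np.concatenate([[0], np.flatnonzero(breaks) + 1])
        ends = np.concatenate([np.flatnonzero(breaks), [len(lvs) - 1]])
        run_len = ends - starts + 1
        run_lvl = lvs[starts]
        mat = np.zeros((ng, max_len), dtype=np.int64)
        np.add.at(mat, (run_lvl - 1, run_len - 1), 1)
        out.append(mat[:, : max(int(run_len.max()), 1)])
    return out


def glszm_matrix(disc: DiscretizedVOI) -> np.ndarray:
    """Ng x max-zone-size size-zone count matrix (26-connected zones)."""
    lv = disc.levels
    ng = disc.ng
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for g in np.unique(disc.flat_levels):
        labeled, n = ndimage.label(lv == g, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        sizes_per_level.append((int(g), sizes))
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((ng, max_size), dtype=np.int64)
    for g, sizes in sizes_per_level:
        np.add.at(mat, (g - 1, sizes - 1), 1)
    return mat


def gldm_matrix(disc: DiscretizedVOI, alpha: int = 0) -> np.ndarray:
    """Ng x Nd dependence count matrix (distance 1, tolerance ``alpha``)."""
    lv = disc.levels
    ng = disc.ng
    dep = np.zeros(lv.shape, dtype=np.int64)
    for offset in DIRECTIONS_13:
        sa, sb = _shift_slices(lv.shape, offset)
        a, b = lv[sa], lv[sb]
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[sa][ok] += 1
        dep[sb][ok] += 1
    d = dep[disc.mask] + 1  # center voxel counts itself
    mat = np.zeros((ng, int(d.max())), dtype=np.int64)
    np.add.at(mat, (disc.flat_levels - 1, d - 1), 1)
    return mat


@dataclass
class NGTDMData:
    """Per-level voxel counts and summed absolute neighborhood differences."""

    n: np.ndarray  # (Ng,) voxel counts per level (valid voxels only)
    s: np.ndarray  # (Ng,) sum_{voxels of level i} |i - mean neighbor level|

    @property
    def n_valid_voxels(self) -> int:
        return int(self.n.sum())

    @property
    def p(self) -> np.ndarray:
        total = self.n.sum()
        return self.n / total if total > 0 else self.n.astype(float)


def ngtdm_data(disc: DiscretizedVOI) -> NGTDMData:
    lv = disc.levels.astype(float)
    inmask = disc.mask
    nsum = np.zeros(lv.shape)
    ncnt = np.zeros(lv.shape, dtype=np.int64)
    for offset in _OFFSETS_26:
        sa, sb = _shift_slices(lv.shape, offset)
        contrib = inmask[sb]
        nsum[sa] += np.where(contrib, lv[sb], 0.0)
        ncnt[sa] += contrib
    valid = inmask & (ncnt > 0)
    ng = disc.ng
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng)
    lv_v = disc.levels[valid]
    diff = np.abs(lv_v - nsum[valid] / ncnt[valid])
    np.add.at(n, lv_v - 1, 1)
    np.add.at(s, lv_v - 1, diff)
    return NGTDMData(n=n, s=s)
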