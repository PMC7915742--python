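"""Texture feature formulas for the five gray-level matrix families.

24 GLCM + 14 GLDM + 16 GLRLM + 16 GLSZM + 5 NGTDM = 75 features.  GLCM and
GLRLM features are computed per direction and averaged over the 13 unique 3D
directions.  Degenerate inputs (e.g. a single gray level where a formula
divides by zero) yield the documented fallbacks or NaN; NaN marks a feature
as undefined rather than silently repeatable.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedVOI
from .matrices import (
    NGTDMData,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_data,
)

__all__ = [
    "GLCM_NAMES",
    "GLDM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "texture_features",
]

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# --------------------------------------------------------------------------- GLCM
def _glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:
        return {name: float("nan") for name in GLCM_NAMES}
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # == py by symmetry
    ux = float(np.sum(i * px))
    sig2 = float(np.sum(px * (i - ux) ** 2))

    # difference and sum distributions
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())

    diff_avg = float(np.sum(k_diff * p_diff))
    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)

    # information measures of correlation
    outer = np.outer(px, px)
    valid = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[valid] * np.log2(outer[valid])))
    hxy2 = _entropy2(outer.ravel())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig2 > 0:
        corr = float((np.sum(p * ii * jj) - ux * ux) / sig2)
    else:
        corr = 1.0  # perfectly dependent degenerate case

    # maximal correlation coefficient via the transition matrix Q
    nz = px > 0
    if nz.sum() <= 1:
        mcc = 1.0
    else:
        psub = p[np.ix_(nz, nz)]
        pxs = px[nz]
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        eig = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, float(eig[-2]))))

    off = ii != jj
    inv_var = float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)) if off.any() else float("nan")

    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "ClusterProminence": float(np.sum(p * (ii + jj - 2 * ux) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - 2 * ux) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - 2 * ux) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": sig2,
    }


def glcm_features(disc: DiscretizedVOI) -> dict[str, float]:
    """GLCM features averaged over the 13 directions (directions with pairs)."""
    mats = [m for m in glcm_matrices(disc) if m.sum() > 0]
    if not mats:
        return {name: float("nan") for name in GLCM_NAMES}
    per_dir = [_glcm_features_single(m) for m in mats]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES
    }


# --------------------------------------------------------- run-length / size-zone
def _rl_sz_features(counts: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared formulas for GLRLM (kind='run') and GLSZM (kind='zone')."""
    total = counts.sum()
    if total == 0:
        names = GLRLM_NAMES if kind == "run" else GLSZM_NAMES
        return {name: float("nan") for name in names}
    p = counts / total
    ng, nl = p.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nl + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(i * pi))
    mu_j = float(np.sum(j * pj))

    vals = {
        "short": float(np.sum(pj / j**2)),
        "long": float(np.sum(pj * j**2)),
        "gln": float(np.sum(counts.sum(axis=1) ** 2) / total),
        "glnn": float(np.sum(pi**2)),
        "ln": float(np.sum(counts.sum(axis=0) ** 2) / total),
        "lnn": float(np.sum(pj**2)),
        "pct": float(total / n_voxels),
        "glv": float(np.sum(p * (ii - mu_i) ** 2)),
        "lv": float(np.sum(p * (jj - mu_j) ** 2)),
        "entropy": _entropy2(p.ravel()),
        "lgl": float(np.sum(pi / i**2)),
        "hgl": float(np.sum(pi * i**2)),
        "slgl": float(np.sum(p / (ii**2 * jj**2))),
        "shgl": float(np.sum(p * ii**2 / jj**2)),
        "llgl": float(np.sum(p * jj**2 / ii**2)),
        "lhgl": float(np.sum(p * ii**2 * jj**2)),
    }
    if kind == "run":
        return {
            "GrayLevelNonUniformity": vals["gln"],
            "GrayLevelNonUniformityNormalized": vals["glnn"],
            "GrayLevelVariance": vals["glv"],
            "HighGrayLevelRunEmphasis": vals["hgl"],
            "LongRunEmphasis": vals["long"],
            "LongRunHighGrayLevelEmphasis": vals["lhgl"],
            "LongRunLowGrayLevelEmphasis": vals["llgl"],
            "LowGrayLevelRunEmphasis": vals["lgl"],
            "RunEntropy": vals["entropy"],
            "RunLengthNonUniformity": vals["ln"],
            "RunLengthNonUniformityNormalized": vals["lnn"],
            "RunPercentage": vals["pct"],
            "RunVariance": vals["lv"],
            "ShortRunEmphasis": vals["short"],
            "ShortRunHighGrayLevelEmphasis": vals["shgl"],
            "ShortRunLowGrayLevelEmphasis": vals["slgl"],
        }
    return {
        "GrayLevelNonUniformity": vals["gln"],
        "GrayLevelNonUniformityNormalized": vals["glnn"],
        "GrayLevelVariance": vals["glv"],
        "HighGrayLevelZoneEmphasis": vals["hgl"],
        "LargeAreaEmphasis": vals["long"],
        "LargeAreaHighGrayLevelEmphasis": vals["lhgl"],
        "LargeAreaLowGrayLevelEmphasis": vals["llgl"],
        "LowGrayLevelZoneEmphasis": vals["lgl"],
        "SizeZoneNonUniformity": vals["ln"],
        "SizeZoneNonUniformityNormalized": vals["lnn"],
        "SmallAreaEmphasis": vals["short"],
        "SmallAreaHighGrayLevelEmphasis": vals["shgl"],
        "SmallAreaLowGrayLevelEmphasis": vals["slgl"],
        "ZoneEntropy": vals["entropy"],
        "ZonePercentage": vals["pct"],
        "ZoneVariance": vals["lv"],
    }


def glrlm_features(disc: DiscretizedVOI) -> dict[str, float]:
    """GLRLM features averaged over the 13 directions."""
    per_dir = [
        _rl_sz_features(m, disc.n_voxels, "run") for m in glrlm_matrices(disc)
    ]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES
    }


def glszm_features(disc: DiscretizedVOI) -> dict[str, float]:
    return _rl_sz_features(glszm_matrix(disc), disc.n_voxels, "zone")


# --------------------------------------------------------------------------- GLDM
def gldm_features(disc: DiscretizedVOI, alpha: int = 0) -> dict[str, float]:
    counts = gldm_matrix(disc, alpha=alpha)
    total = counts.sum()  # == n_voxels
    p = counts / total
    ng, nd = p.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nd + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(i * pi))
    mu_j = float(np.sum(j * pj))
    return {
        "DependenceEntropy": _entropy2(p.ravel()),
        "DependenceNonUniformity": float(np.sum(counts.sum(axis=0) ** 2) / total),
        "DependenceNonUniformityNormalized": float(np.sum(pj**2)),
        "DependenceVariance": float(np.sum(p * (jj - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(counts.sum(axis=1) ** 2) / total),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(pi * i**2)),
        "LargeDependenceEmphasis": float(np.sum(pj * j**2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * ii**2 * jj**2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * jj**2 / ii**2)),
        "LowGrayLevelEmphasis": float(np.sum(pi / i**2)),
        "SmallDependenceEmphasis": float(np.sum(pj / j**2)),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * ii**2 / jj**2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (ii**2 * jj**2))),
    }


# -------------------------------------------------------------------------- NGTDM
def ngtdm_features(disc: DiscretizedVOI) -> dict[str, float]:
    data: NGTDMData = ngtdm_data(disc)
    nvp = data.n_valid_voxels
    if nvp == 0:
        return {name: float("nan") for name in NGTDM_NAMES}
    p = data.p
    s = data.s
    ng = len(p)
    i = np.arange(1, ng + 1, dtype=float)
    nz = p > 0
    ngp = int(nz.sum())

    iv, jv = np.meshgrid(i[nz], i[nz], indexing="ij")
    pv, qv = np.meshgrid(p[nz], p[nz], indexing="ij")
    sv, tv = np.meshgrid(s[nz], s[nz], indexing="ij")

    ps = float(np.sum(p * s))
    coarseness = 1.0 / ps if ps > 0 else 1e6  # documented degenerate cap

    if ngp > 1:
        contrast = (
            float(np.sum(pv * qv * (iv - jv) ** 2)) / (ngp * (ngp - 1))
        ) * (float(s.sum()) / nvp)
    else:
        contrast = 0.0

    busy_den = float(np.sum(np.abs(iv * pv - jv * qv)))
    busyness = ps / busy_den if busy_den > 0 else 0.0

    complexity = float(
        np.sum(np.abs(iv - jv) * (pv * sv + qv * tv) / (pv + qv))
    ) / nvp

    s_sum = float(s.sum())
    strength = float(np.sum((pv + qv) * (iv - jv) ** 2)) / s_sum if s_sum > 0 else 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def texture_features(disc: DiscretizedVOI, gldm_alpha: int = 0) -> dict[str, float]:
    """All 75 texture features of one discretized VOI, keyed ``family_Name``."""
    out: dict[str, float] = {}
    for name, value in glcm_features(disc).items():
        out[f"glcm_{name}"] = value
    for name, value in gldm_features(disc, alpha=gldm_alpha).items():
        out[f"gldm_{name}"] = value
    for name, value in glrlm_features(disc).items():
        out[f"glrlm_{name}"] = value
    for name, value in glszm_features(disc).items():
        out[f"glszm_{name}"] = value
    for name, value in ngtdm_features(disc).items():
        out[f"ngtdm_{name}"] = value
    return out
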