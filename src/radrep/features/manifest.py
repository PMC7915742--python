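"""The pinned 93-feature manifest and feature-name parsing helpers.

Per image variant the bank emits 18 first-order + 24 GLCM + 14 GLDM +
16 GLRLM + 16 GLSZM + 5 NGTDM = 93 features; over the 14 variants
(original, 8 wavelet, 5 LoG) that is 1,302 named columns.  Shape features
are deliberately absent: VOI geometry is identical across a test/retest
pair by construction.
"""

from __future__ import annotations

from .firstorder import FIRSTORDER_NAMES
from .texture import GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES

__all__ = [
    "FAMILIES",
    "FAMILY_SIZES",
    "BASE_FEATURE_NAMES",
    "feature_names",
    "parse_feature_name",
]

FAMILIES = ("firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm")

_FAMILY_MEMBERS = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

FAMILY_SIZES = {family: len(names) for family, names in _FAMILY_MEMBERS.items()}

#: the 93 per-variant feature names, ``<family>_<FeatureName>``, in fixed order
BASE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{name}" for family in FAMILIES for name in _FAMILY_MEMBERS[family]
)


def feature_names(variants: list[str]) -> list[str]:
    """Full column list ``<variant>_<family>_<FeatureName>`` for given variants."""
    return [f"{variant}_{base}" for variant in variants for base in BASE_FEATURE_NAMES]


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split a full feature name into (variant, family, feature)."""
    for family in FAMILIES:
        token = f"_{family}_"
        if token in name:
            variant, feature = name.split(token, 1)
            return variant, family, feature
    raise ValueError(f"cannot parse feature name {name!r}")
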