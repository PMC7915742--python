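"""Test-retest repeatability scoring.

Per feature, an n-subjects x 2-measurements matrix is scored with the
two-way absolute-agreement single-measure intraclass correlation

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C and MS_E are the row (subject), column (measurement) and
error mean squares of the two-way ANOVA.  The 95% confidence interval uses
the exact F-based construction for this ICC form.  Each feature is then
assigned one of three repeatability labels from where its CI falls:

* ``repeatable``       — lower and upper CI limits both within [0.91, 1.00]
* ``moderate``         — upper limit within [0.91, 1.00] and lower within [0.75, 1.00]
* ``not_repeatable``   — everything else (conservative fallback for CIs
  matching no band)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features.manifest import parse_feature_name

__all__ = [
    "ICCResult",
    "icc_anova",
    "icc_a1",
    "icc_ci",
    "classify",
    "icc_table",
    "label_percentages",
    "repeatability_report",
    "LABELS",
]

LABELS = ("repeatable", "moderate", "not_repeatable")

MIN_SUBJECTS_DEFAULT = 5


@dataclass
class ICCResult:
    """Point estimate, CI, ANOVA mean squares and repeatability label."""

    icc: float
    ci_low: float
    ci_high: float
    ms_r: float
    ms_c: float
    ms_e: float
    n: int
    k: int
    label: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.icc)


def _validate(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("rating matrix must be 2D (subjects x measurements)")
    n, k = m.shape
    if n < 2:
        raise ValueError("ICC needs at least 2 subjects")
    if k < 2:
        raise ValueError("ICC needs at least 2 measurements")
    if not np.all(np.isfinite(m)):
        raise ValueError("rating matrix contains non-finite entries")
    return m


def icc_anova(matrix: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (MS_R, MS_C, MS_E) of a subjects x raters matrix."""
    m = _validate(matrix)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_r = k * float(np.sum((row_means - grand) ** 2))
    ss_c = n * float(np.sum((col_means - grand) ** 2))
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_e = float(np.sum(resid**2))
    return ss_r / (n - 1), ss_c / (k - 1), ss_e / ((n - 1) * (k - 1))


def icc_a1(matrix: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way absolute-agreement single-measure ICC with a 95% CI and label.

    A matrix with zero total variance (all entries identical) has no defined
    ICC; the result carries NaNs and the ``not_repeatable`` label and is
    excluded from summary denominators downstream.
    """
    m = _validate(matrix)
    n, k = m.shape
    ms_r, ms_c, ms_e = icc_anova(m)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if np.ptp(m) == 0 or denom == 0:
        return ICCResult(
            icc=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            ms_r=ms_r,
            ms_c=ms_c,
            ms_e=ms_e,
            n=n,
            k=k,
            label="not_repeatable",
        )
    icc = (ms_r - ms_e) / denom
    lo, hi = icc_ci(m, alpha=alpha)
    return ICCResult(
        icc=float(icc),
        ci_low=lo,
        ci_high=hi,
        ms_r=ms_r,
        ms_c=ms_c,
        ms_e=ms_e,
        n=n,
        k=k,
        label=classify(lo, hi),
    )


def icc_ci(matrix: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Exact F-based confidence interval for the absolute-agreement single-measure ICC."""
    m = _validate(matrix)
    n, k = m.shape
    ms_r, ms_c, ms_e = icc_anova(m)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if np.ptp(m) == 0 or denom == 0:
        return float("nan"), float("nan")
    icc = (ms_r - ms_e) / denom

    if ms_e == 0 and ms_c == 0:
        return 1.0, 1.0  # perfect agreement: interval collapses

    # Satterthwaite degrees of freedom for the linear combination a*MSC + b*MSE
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return 1.0, 1.0
    num = (a * ms_c + b * ms_e) ** 2
    den = (a * ms_c) ** 2 / (k - 1.0) + (b * ms_e) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num / den if den > 0 else (n - 1.0) * (k - 1.0)

    f_lower = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_upper = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lo = (n * (ms_r - f_lower * ms_e)) / (
        f_lower * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r
    )
    hi = (n * (f_upper * ms_r - ms_e)) / (
        k * ms_c + (k * n - k - n) * ms_e + n * f_upper * ms_r
    )
    return float(lo), float(hi)


def classify(ci_low: float, ci_high: float) -> str:
    """Repeatability label from the 95% CI bands (precedence: repeatable > moderate)."""
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        return "not_repeatable"
    hi = min(ci_high, 1.0)  # exact-agreement CIs may touch 1.0
    lo = ci_low
    if 0.91 <= lo <= 1.0 and 0.91 <= hi <= 1.0:
        return "repeatable"
    if 0.91 <= hi <= 1.0 and 0.75 <= lo <= 1.0:
        return "moderate"
    return "not_repeatable"


# ------------------------------------------------------------------ table-level API
def icc_table(
    test: pd.DataFrame,
    retest: pd.DataFrame,
    alpha: float = 0.05,
    min_subjects: int = MIN_SUBJECTS_DEFAULT,
) -> pd.DataFrame:
    """Per-feature ICC over two aligned subjects x features tables.

    Subjects with a flagged-undefined (NaN) value for a feature are dropped
    pairwise for that feature; features retaining fewer than ``min_subjects``
    subjects are reported as undefined.
    """
    if list(test.columns) != list(retest.columns):
        raise ValueError("test and retest tables must share identical feature columns")
    if list(test.index) != list(retest.index):
        raise ValueError("test and retest tables must share identical subjects")
    rows = []
    for feature in test.columns:
        a = test[feature].to_numpy(dtype=float)
        b = retest[feature].to_numpy(dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        n_dropped = int((~keep).sum())
        if keep.sum() >= max(min_subjects, 2):
            res = icc_a1(np.column_stack([a[keep], b[keep]]), alpha=alpha)
        else:
            res = ICCResult(
                float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"), float("nan"),
                int(keep.sum()), 2, "not_repeatable",
            )
        rows.append(
            {
                "feature": feature,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ms_r": res.ms_r,
                "ms_c": res.ms_c,
                "ms_e": res.ms_e,
                "n": res.n,
                "n_dropped": n_dropped,
                "label": res.label,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def label_percentages(table: pd.DataFrame) -> dict[str, float]:
    """Percentage of features per repeatability label, over defined features only."""
    defined = table[table["defined"]]
    total = len(defined)
    if total == 0:
        return {}
    return {
        label: 100.0 * float((defined["label"] == label).sum()) / total
        for label in LABELS
    }


def repeatability_report(
    table: pd.DataFrame, top_n: int = 10
) -> dict[str, object]:
    """Summaries of an ICC table: per family, per variant, and ranked features."""
    parsed = [parse_feature_name(name) for name in table.index]
    work = table.copy()
    work["variant"] = [p[0] for p in parsed]
    work["family"] = [p[1] for p in parsed]
    work["filter_group"] = [
        "original" if v == "original" else ("wavelet" if v.startswith("wavelet") else "log")
        for v in work["variant"]
    ]

    def by(column: str) -> dict[str, dict[str, float]]:
        return {
            str(key): label_percentages(group)
            for key, group in work.groupby(column)
        }

    ranked = work[work["defined"]].sort_values("icc", ascending=False)
    return {
        "overall": label_percentages(work),
        "n_features": int(len(work)),
        "n_defined": int(work["defined"].sum()),
        "n_repeatable": int((work["label"] == "repeatable").sum()),
        "by_family": by("family"),
        "by_variant": by("variant"),
        "by_filter_group": by("filter_group"),
        "top_features": list(ranked.head(top_n).index),
        "bottom_features": list(ranked.tail(top_n).index),
    }
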