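"""Hierarchical clustering of subjects on the repeatable-feature subset.

Feature columns are z-score normalized, subjects are agglomerated under
Ward's minimum-variance criterion (squared-Euclidean geometry), and the tree
is cut into a fixed number of clusters.  Cluster/genotype composition is
quantified by per-cluster majority purity, with a permutation null available
for significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "ClusterResult",
    "zscore_features",
    "ward_cluster",
    "genotype_composition",
    "purity_permutation_null",
    "select_repeatable_features",
]

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Ward merge tree plus a flat cut."""

    linkage: np.ndarray
    assignments: pd.Series  # subject -> cluster id (1..n_clusters)
    n_clusters: int

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def zscore_features(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature column to mean 0, SD 1 (population SD).

    Zero-variance columns carry no clustering information and are dropped
    with a log warning.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 subjects")
    values = table.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(table.columns[~keep])
        log.warning("dropping %d constant feature column(s): %s", len(dropped), dropped[:5])
    out = (values[:, keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(out, index=table.index, columns=table.columns[keep])


def ward_cluster(table: pd.DataFrame, n_clusters: int = 2) -> ClusterResult:
    """Agglomerate subjects (rows) under Ward's criterion and cut into clusters.

    Deterministic for a fixed row order; scipy's linkage breaks distance ties
    by cluster index order.
    """
    if len(table) < n_clusters:
        raise ValueError("need at least n_clusters subjects")
    x = table.to_numpy(dtype=float)
    linkage = hierarchy.linkage(x, method="ward")
    flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        linkage=linkage,
        assignments=pd.Series(flat, index=table.index, name="cluster"),
        n_clusters=n_clusters,
    )


def genotype_composition(result: ClusterResult, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster genotype counts and majority purity (percent).

    ``labels`` maps every subject in the clustering to a genotype string.
    """
    missing = set(result.assignments.index) - set(labels.index)
    if missing:
        raise ValueError(f"unlabeled subjects: {sorted(missing)[:5]}")
    rows = []
    for cluster_id, members in result.assignments.groupby(result.assignments):
        lab = labels.loc[members.index]
        counts = lab.value_counts()
        rows.append(
            {
                "cluster": int(cluster_id),
                "n": int(len(lab)),
                "majority_genotype": counts.idxmax(),
                "majority_count": int(counts.max()),
                "purity_pct": 100.0 * float(counts.max()) / len(lab),
                **{f"n_{g}": int(c) for g, c in counts.items()},
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def _overall_purity(assignments: np.ndarray, labels: np.ndarray) -> float:
    """Subject-weighted mean majority purity over clusters, in [0, 1]."""
    total = 0
    for c in np.unique(assignments):
        lab = labels[assignments == c]
        _, counts = np.unique(lab, return_counts=True)
        total += counts.max()
    return total / len(labels)


def purity_permutation_null(
    result: ClusterResult,
    labels: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Observed overall purity against a label-permutation null.

    The clustering is held fixed; genotype labels are shuffled.  Returns the
    observed purity, the null's 95th percentile, and a permutation p-value.
    """
    assignments = result.assignments.to_numpy()
    lab = labels.loc[result.assignments.index].to_numpy()
    observed = _overall_purity(assignments, lab)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _overall_purity(assignments, rng.permutation(lab))
    p_value = (1.0 + float((null >= observed).sum())) / (n_permutations + 1.0)
    return {
        "observed_purity": float(observed),
        "null_p95": float(np.percentile(null, 95)),
        "null_mean": float(null.mean()),
        "p_value": float(p_value),
    }


def select_repeatable_features(
    feature_table: pd.DataFrame, icc_table: pd.DataFrame
) -> pd.DataFrame:
    """Subset a subjects x features table to the features labeled repeatable."""
    repeatable = icc_table.index[icc_table["label"] == "repeatable"]
    cols = [c for c in feature_table.columns if c in set(repeatable)]
    if not cols:
        raise ValueError("no repeatable features to cluster on")
    return feature_table[cols]
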